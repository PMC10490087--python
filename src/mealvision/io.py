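"""On-disk formats: 16-bit depth PNGs, indexed mask PNGs, JSON sidecars.

Depth rasters are single-channel 16-bit PNGs whose value is millimetres
(0 = invalid).  Disparity maps use the same container at x256 fixed point.
Masks are 8-bit indexed PNGs (0 = background, k = item k).  Camera models,
card detections and correspondences travel as JSON sidecars.  All floats
in reports are serialised at 6 significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import CameraModel, DepthMap

__all__ = [
    "write_depth_png", "read_depth_png", "write_mask_png", "read_mask_png",
    "write_gray_png", "read_gray_png", "write_disparity_png",
    "read_disparity_png", "write_camera_json", "read_camera_json",
    "round_floats", "write_json",
]

_DISP_FIXED_POINT = 256.0


def write_depth_png(path: str | Path, depth: DepthMap) -> None:
    mm = np.where(depth.valid, np.clip(np.round(depth.values), 1, 65535), 0)
    Image.fromarray(mm.astype(np.uint16)).save(str(path))


def read_depth_png(path: str | Path) -> DepthMap:
    arr = np.asarray(Image.open(str(path)), dtype=float)
    valid = arr > 0
    return DepthMap(np.where(valid, arr, 0.0), valid)


def write_disparity_png(path: str | Path, values: np.ndarray,
                        valid: np.ndarray) -> None:
    fixed = np.where(valid, np.clip(np.round(values * _DISP_FIXED_POINT),
                                    1, 65535), 0)
    Image.fromarray(fixed.astype(np.uint16)).save(str(path))


def read_disparity_png(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(Image.open(str(path)), dtype=float)
    valid = arr > 0
    return np.where(valid, arr / _DISP_FIXED_POINT, 0.0), valid


def write_mask_png(path: str | Path, index: np.ndarray) -> None:
    idx = np.asarray(index)
    if idx.max() > 255:
        raise ValueError("more than 255 items in one image")
    Image.fromarray(idx.astype(np.uint8), mode="L").save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)), dtype=np.int32)


def write_gray_png(path: str | Path, intensity: np.ndarray) -> None:
    """Intensity in [0, 1] to 16-bit grayscale (keeps the card band exact
    enough for detection round trips)."""
    arr = np.clip(np.round(np.asarray(intensity) * 65535), 0, 65535)
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def read_gray_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)), dtype=float) / 65535.0


def write_camera_json(path: str | Path, camera: CameraModel) -> None:
    Path(path).write_text(json.dumps(camera.to_dict(), indent=1))


def read_camera_json(path: str | Path) -> CameraModel:
    return CameraModel.from_dict(json.loads(Path(path).read_text()))


def round_floats(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits for
    reproducible JSON diffs."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(path: str | Path, obj, sig: int = 6) -> None:
    Path(path).write_text(json.dumps(round_floats(obj, sig), indent=1,
                                     sort_keys=True))
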
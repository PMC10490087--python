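"""Pinhole-camera geometry shared by the renderer, card pose and volume engines.

Conventions used throughout the package:

* World frame: the table plane is ``z = 0`` with ``+z`` pointing up; units are
  millimetres everywhere.
* Camera frame: ``+z`` along the optical axis (into the scene), ``+x`` to the
  right, ``+y`` down — the usual computer-vision convention.
* Pixels: integer pixel ``(u, v)`` addresses the *centre* of its cell, 0-based,
  ``u`` rightward and ``v`` downward.  Depth is the distance along the optical
  axis (the camera-frame ``z`` coordinate), not the ray length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraModel", "DepthMap", "rotation_is_rigid"]


def rotation_is_rigid(R: np.ndarray, atol: float = 1e-8) -> bool:
    """True if ``R`` is orthonormal with determinant +1."""
    R = np.asarray(R, dtype=float)
    return (
        R.shape == (3, 3)
        and np.allclose(R @ R.T, np.eye(3), atol=atol)
        and np.isclose(np.linalg.det(R), 1.0, atol=atol)
    )


@dataclass
class CameraModel:
    """A calibrated pinhole camera with a rigid world-to-camera pose.

    ``x_cam = R @ x_world + t`` maps world points (mm) into the camera frame.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    elevation_deg: float = 90.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")
        if not rotation_is_rigid(self.R, atol=1e-6):
            raise ValueError("camera pose rotation is not rigid")

    # -- constructors ------------------------------------------------------

    @classmethod
    def looking_at(
        cls,
        position: np.ndarray,
        target: np.ndarray,
        fx: float = 800.0,
        fy: float | None = None,
        width: int = 640,
        height: int = 480,
        elevation_deg: float | None = None,
    ) -> "CameraModel":
        """Camera at ``position`` with the optical axis through ``target``.

        The camera ``x`` axis is kept horizontal (parallel to the world
        ``xy`` plane), which matches a phone held level above a table.
        """
        position = np.asarray(position, dtype=float)
        target = np.asarray(target, dtype=float)
        fwd = target - position
        dist = np.linalg.norm(fwd)
        if dist <= 0:
            raise ValueError("camera position coincides with target")
        fwd = fwd / dist
        up_hint = np.array([0.0, 1.0, 0.0])
        right = np.cross(fwd, up_hint)
        if np.linalg.norm(right) < 1e-9:  # looking along world y: fall back
            right = np.array([1.0, 0.0, 0.0])
        right = right / np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.stack([right, down, fwd])
        if np.linalg.det(R) < 0:
            R = np.stack([-right, down, fwd])
        t = -R @ position
        if elevation_deg is None:
            horiz = np.linalg.norm(fwd[:2])
            elevation_deg = float(np.degrees(np.arctan2(-fwd[2], horiz)))
        if fy is None:
            fy = fx
        return cls(fx, fy, width / 2.0, height / 2.0, width, height,
                   R=R, t=t, elevation_deg=elevation_deg)

    @classmethod
    def overhead_arc(
        cls,
        centre: np.ndarray,
        distance_mm: float,
        elevation_deg: float,
        fx: float = 800.0,
        width: int = 640,
        height: int = 480,
    ) -> "CameraModel":
        """Camera on a vertical arc over ``centre`` at a given elevation.

        At 90° the camera is straight above the scene centre; lower
        elevations rotate the camera about the world ``x`` axis through the
        centre, preserving the distance to the centre.  This is how the
        second view of a two-angle capture is modelled.
        """
        centre = np.asarray(centre, dtype=float)
        e = np.radians(elevation_deg)
        position = centre + distance_mm * np.array([0.0, -np.cos(e), np.sin(e)])
        return cls.looking_at(position, centre, fx=fx, width=width,
                              height=height, elevation_deg=elevation_deg)

    # -- geometry ----------------------------------------------------------

    @property
    def K(self) -> np.ndarray:
        return np.array([
            [self.fx, 0.0, self.cx],
            [0.0, self.fy, self.cy],
            [0.0, 0.0, 1.0],
        ])

    @property
    def centre_world(self) -> np.ndarray:
        """Camera centre expressed in the world frame."""
        return -self.R.T @ self.t

    def world_to_camera(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.R.T + self.t

    def camera_to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.t) @ self.R

    def project(self, pts_world: np.ndarray) -> np.ndarray:
        """Project world points to pixel coordinates ``(u, v)``."""
        pc = self.world_to_camera(pts_world)
        z = pc[:, 2]
        if np.any(z <= 0):
            raise ValueError("point behind the camera")
        u = self.fx * pc[:, 0] / z + self.cx
        v = self.fy * pc[:, 1] / z + self.cy
        return np.stack([u, v], axis=1)

    def pixel_rays(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame ray origin and one direction per pixel.

        Directions are normalised so that their camera-frame ``z`` component
        is 1: the ray parameter then *is* the depth along the optical axis.
        Returns ``(origin (3,), dirs (H, W, 3))``.
        """
        u = np.arange(self.width, dtype=float)
        v = np.arange(self.height, dtype=float)
        uu, vv = np.meshgrid(u, v)
        d_cam = np.stack([
            (uu - self.cx) / self.fx,
            (vv - self.cy) / self.fy,
            np.ones_like(uu),
        ], axis=-1)
        dirs = d_cam @ self.R  # == R.T applied to each direction
        return self.centre_world, dirs

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
            "R": self.R.tolist(), "t": self.t.tolist(),
            "elevation_deg": self.elevation_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(d["fx"], d["fy"], d["cx"], d["cy"], d["width"], d["height"],
                   R=np.array(d["R"]), t=np.array(d["t"]),
                   elevation_deg=d.get("elevation_deg", 90.0))


@dataclass
class DepthMap:
    """Metric depth raster: per-pixel distance along the optical axis, in mm.

    Invalid pixels carry a sentinel (0 in serialised form) and are excluded
    from every statistic; ``valid`` is the authoritative mask.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must share a shape")
        vals = self.values[self.valid]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValueError("valid depth entries must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "DepthMap":
        return DepthMap(self.values.copy(), self.valid.copy())

    @classmethod
    def from_array(cls, values: np.ndarray) -> "DepthMap":
        values = np.asarray(values, dtype=float)
        valid = np.isfinite(values) & (values > 0)
        vals = np.where(valid, values, 0.0)
        return cls(vals, valid)
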
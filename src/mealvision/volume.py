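"""Per-item food volume from an aligned depth map and segmentation masks.

A single downward-looking depth view observes only the *top* surface of
each food item, so the faithful volume model is a 2.5-D height field over
the card (table) plane: back-project the masked depth pixels, rotate into
the card frame (card plane at ``z = 0``, ``+z`` toward the camera), clean
statistical outliers, apply height plausibility rules, and integrate
``cell_area x median_height`` over a regular plan-view grid.

Plausibility rules, all configurable through :class:`VolumeRules`:

* the bottom of an item may sit at most 5 mm below the card plane — points
  deeper than that are discarded and remaining negative heights clip to 0;
* nothing rises more than 5 cm above the card plane;
* no single item exceeds 2.5 cups (600 mL with the 240 mL label cup) — the
  final volume is capped there;
* if the card is missing/undetected, or too little geometry survives, the
  item falls back to its standard serving volume from the nutrient table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .card import CardPose
from .errors import EmptyAfterRules, EmptyItem, InsufficientPoints, MissingServing
from .geometry import DepthMap

__all__ = [
    "PointCloud", "VolumeRules", "FoodItemEstimate",
    "backproject", "to_card_frame", "remove_statistical_outliers",
    "apply_height_rules", "integrate_volume", "cap_volume",
    "estimate_item_volume", "estimate_volume_from_cloud",
]


@dataclass
class PointCloud:
    """N x 3 coordinates in mm; ``frame`` is 'camera' or 'card'.

    In the card frame the card plane is ``z = 0`` with ``+z`` toward the
    camera side.
    """
    points: np.ndarray
    frame: str = "camera"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class VolumeRules:
    bottom_tol_mm: float = 5.0
    top_max_mm: float = 50.0
    cup_mL: float = 240.0
    max_cups: float = 2.5
    grid_cell_mm: float = 2.0
    # measurement slack at the top cutoff: a surface genuinely at the 50 mm
    # limit must not vanish because the metric scale is off by a fraction
    # of a percent; points inside the slack are kept but clipped to the band
    boundary_tol_mm: float = 0.5

    def __post_init__(self):
        for name in ("bottom_tol_mm", "top_max_mm", "cup_mL", "max_cups",
                     "grid_cell_mm", "boundary_tol_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cap_mL(self) -> float:
        return self.cup_mL * self.max_cups


@dataclass
class FoodItemEstimate:
    fine_category: str
    volume_mL: float
    card_found: bool = True
    capped: bool = False
    fallback_serving: bool = False
    outliers_removed_count: int = 0


# ---------------------------------------------------------------------------
# stages


def backproject(depth: DepthMap, mask: np.ndarray,
                intrinsics: np.ndarray) -> PointCloud:
    """Masked valid depth pixels to camera-frame 3-D points.

    ``X = (u - cx) Z / fx``, ``Y = (v - cy) Z / fy``, ``Z = depth``.
    """
    K = np.asarray(intrinsics, dtype=float)
    sel = np.asarray(mask, dtype=bool) & depth.valid
    if not np.any(sel):
        raise EmptyItem("mask selects no valid depth pixel")
    vs, us = np.nonzero(sel)
    Z = depth.values[vs, us]
    X = (us - K[0, 2]) * Z / K[0, 0]
    Y = (vs - K[1, 2]) * Z / K[1, 1]
    return PointCloud(np.column_stack([X, Y, Z]), frame="camera")


def to_card_frame(cloud: PointCloud, pose: CardPose) -> PointCloud:
    """Rigid transform into the card frame (plane ``z = 0``, ``+z`` up)."""
    if cloud.frame != "camera":
        raise ValueError("expected a camera-frame cloud")
    n = pose.plane_normal            # unit, facing the camera
    # orthonormal basis with z' = n
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    x_ax = np.cross(a, n)
    x_ax /= np.linalg.norm(x_ax)
    y_ax = np.cross(n, x_ax)
    B = np.stack([x_ax, y_ax, n], axis=1)   # columns: card axes in camera frame
    pts = (cloud.points - pose.plane_point) @ B
    return PointCloud(pts, frame="card")


def remove_statistical_outliers(cloud: PointCloud, k_neighbours: int = 20,
                                std_ratio: float = 2.0
                                ) -> tuple[PointCloud, int]:
    """Drop points whose mean k-NN distance is anomalously large.

    A point survives if its mean distance to the ``k`` nearest neighbours
    is within ``mean + std_ratio * std`` of that statistic's global
    distribution.  Clouds with at most ``k_neighbours`` points are returned
    unchanged — the statistic is meaningless there.
    """
    pts = cloud.points
    if len(pts) <= k_neighbours:
        return cloud, 0
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_neighbours + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= thresh
    return PointCloud(pts[keep], frame=cloud.frame), int((~keep).sum())


def apply_height_rules(cloud: PointCloud, rules: VolumeRules) -> PointCloud:
    """Enforce the height plausibility band around the card plane.

    Points below ``-bottom_tol_mm`` (implausibly under the table) or more
    than ``boundary_tol_mm`` above ``top_max_mm`` are discarded; surviving
    heights are clipped into ``[0, top_max_mm]`` so nothing outside the
    band ever contributes volume.
    """
    if cloud.frame != "card":
        raise ValueError("height rules operate in the card frame")
    z = cloud.points[:, 2]
    keep = (z >= -rules.bottom_tol_mm) & (z <= rules.top_max_mm
                                          + rules.boundary_tol_mm)
    if not np.any(keep):
        raise EmptyAfterRules("no points inside the height band")
    pts = cloud.points[keep].copy()
    pts[:, 2] = np.clip(pts[:, 2], 0.0, rules.top_max_mm)
    return PointCloud(pts, frame="card")


def integrate_volume(cloud: PointCloud, rules: VolumeRules) -> float:
    """Height-field integration over the card plane.

    The plan-view bounding box is partitioned into ``grid_cell_mm``
    squares; each cell contributes ``cell_area x median(z)`` of the points
    falling in it, and empty cells contribute nothing (no inpainting).
    """
    if cloud.frame != "card":
        raise ValueError("integration operates in the card frame")
    pts = cloud.points
    if len(pts) < 10:
        raise InsufficientPoints(f"only {len(pts)} points after cleaning")
    cell = rules.grid_cell_mm
    ix = np.floor((pts[:, 0] - pts[:, 0].min()) / cell).astype(np.int64)
    iy = np.floor((pts[:, 1] - pts[:, 1].min()) / cell).astype(np.int64)
    key = ix * (iy.max() + 1) + iy
    order = np.argsort(key, kind="stable")
    ks = key[order]
    zs = pts[order, 2]
    starts = np.flatnonzero(np.r_[True, ks[1:] != ks[:-1]])
    bounds = np.r_[starts, len(ks)]
    heights = np.array([np.median(zs[b0:b1])
                        for b0, b1 in zip(bounds[:-1], bounds[1:])])
    volume_mm3 = float(np.sum(heights) * cell * cell)
    return volume_mm3 / 1000.0


def cap_volume(v: float, rules: VolumeRules) -> tuple[float, bool]:
    """Clip at the 2.5-cup plausibility cap; flags when clipping occurred."""
    if v < 0:
        raise ValueError("volume must be non-negative")
    if v > rules.cap_mL:
        return rules.cap_mL, True
    return float(v), False


# ---------------------------------------------------------------------------
# orchestration


def _serving_fallback(category: str, serving_table, card_found: bool
                      ) -> FoodItemEstimate:
    try:
        record = serving_table[category]
    except KeyError:
        raise MissingServing(
            f"no standard-serving entry for category {category!r}") from None
    return FoodItemEstimate(category, float(record.serving_volume_mL),
                            card_found=card_found, fallback_serving=True)


def estimate_volume_from_cloud(cloud: PointCloud, pose: CardPose,
                               category: str, serving_table,
                               rules: VolumeRules = VolumeRules(),
                               k_neighbours: int = 20, std_ratio: float = 2.0
                               ) -> FoodItemEstimate:
    """Volume pipeline from an existing camera-frame cloud (shared by the
    single-image and stereo back-ends)."""
    try:
        card_cloud = to_card_frame(cloud, pose)
        card_cloud, removed = remove_statistical_outliers(
            card_cloud, k_neighbours, std_ratio)
        card_cloud = apply_height_rules(card_cloud, rules)
        raw = integrate_volume(card_cloud, rules)
    except (EmptyAfterRules, InsufficientPoints):
        return _serving_fallback(category, serving_table, card_found=True)
    vol, capped = cap_volume(raw, rules)
    return FoodItemEstimate(category, vol, card_found=True, capped=capped,
                            fallback_serving=False,
                            outliers_removed_count=removed)


def estimate_item_volume(depth: DepthMap, mask: np.ndarray, card_result,
                         category: str, serving_table,
                         rules: VolumeRules = VolumeRules(),
                         intrinsics: np.ndarray | None = None
                         ) -> FoodItemEstimate:
    """Full single-item pipeline with the standard-serving safety net.

    ``card_result`` is a :class:`CardPose` or ``None`` (card absent or
    undetected).  Any degenerate stage — empty mask, all-invalid depth,
    everything outside the height band, too few points — degrades to the
    serving-table volume rather than raising.
    """
    if card_result is None:
        return _serving_fallback(category, serving_table, card_found=False)
    if intrinsics is None:
        raise ValueError("intrinsics are required when a card pose is given")
    try:
        cloud = backproject(depth, mask, intrinsics)
    except EmptyItem:
        return _serving_fallback(category, serving_table, card_found=True)
    return estimate_volume_from_cloud(cloud, card_result, category,
                                      serving_table, rules)
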
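"""Geometry-based depth: rectification, block matching, disparity-to-depth.

The two-view back-end mirrors the classic stereo pipeline: estimate the
epipolar geometry from point correspondences (normalised 8-point), derive
row-aligning rectifying homographies, match horizontally with a
sum-of-absolute-differences block matcher, and convert disparity ``d`` into
metric depth ``Z = f B / d``.  The baseline ``B`` is not assumed known: it
is recovered from the reference-card poses seen in both views, which is the
only metric information a phone capture carries.

Rectification is calibrated: the fundamental matrix estimated from the
correspondences is upgraded to an essential matrix with the intrinsics and
decomposed into a relative rotation and translation direction, from which
row-aligning rotations are built (Fusiello-style).  This keeps the
disparity-to-depth relation an exact closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter

from .card import CardPose, CardSpec
from .errors import RectificationFailed
from .geometry import DepthMap

__all__ = [
    "RectifiedPair", "DisparityMap",
    "fundamental_8point", "rectify_pair", "compute_disparity",
    "disparity_to_depth", "baseline_from_card_poses",
    "rectified_points_in_view_a", "roi_for_masks",
]


# ---------------------------------------------------------------------------
# epipolar geometry


def _normalise_points(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = p.mean(axis=0)
    scale = np.sqrt(2) / max(np.mean(np.linalg.norm(p - c, axis=1)), 1e-12)
    T = np.array([[scale, 0, -scale * c[0]],
                  [0, scale, -scale * c[1]],
                  [0, 0, 1.0]])
    return (p - c) * scale, T


def fundamental_8point(uv_a: np.ndarray, uv_b: np.ndarray) -> np.ndarray:
    """Normalised 8-point fundamental matrix: ``x_b^T F x_a = 0``."""
    uv_a = np.asarray(uv_a, dtype=float)
    uv_b = np.asarray(uv_b, dtype=float)
    if len(uv_a) != len(uv_b):
        raise ValueError("correspondence lists differ in length")
    if len(uv_a) < 8:
        raise RectificationFailed(f"need >= 8 correspondences, got {len(uv_a)}")
    pa, Ta = _normalise_points(uv_a)
    pb, Tb = _normalise_points(uv_b)
    xa, ya = pa[:, 0], pa[:, 1]
    xb, yb = pb[:, 0], pb[:, 1]
    A = np.column_stack([xb * xa, xb * ya, xb, yb * xa, yb * ya, yb,
                         xa, ya, np.ones_like(xa)])
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-8 * s[0]:
        raise RectificationFailed("degenerate correspondence configuration")
    F = Vt[-1].reshape(3, 3)
    U, S, Vt2 = np.linalg.svd(F)
    F = U @ np.diag([S[0], S[1], 0.0]) @ Vt2   # enforce rank 2
    F = Tb.T @ F @ Ta
    return F / np.linalg.norm(F)


def _triangulate(uv_a, uv_b, P_a, P_b) -> np.ndarray:
    pts = []
    for (ua, va), (ub, vb) in zip(uv_a, uv_b):
        A = np.stack([
            ua * P_a[2] - P_a[0], va * P_a[2] - P_a[1],
            ub * P_b[2] - P_b[0], vb * P_b[2] - P_b[1],
        ])
        _, _, Vt = np.linalg.svd(A)
        X = Vt[-1]
        pts.append(X[:3] / X[3])
    return np.asarray(pts)


def _decompose_essential(E: np.ndarray, uv_a, uv_b, K_a, K_b
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pick the (R, t) with the most triangulated points in front of both
    cameras (cheirality).  ``x_b = R x_a + t`` with ``t`` a unit vector."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    best = None
    P_a = K_a @ np.hstack([np.eye(3), np.zeros((3, 1))])
    sub = slice(0, min(len(uv_a), 20))
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for t in (U[:, 2], -U[:, 2]):
            P_b = K_b @ np.hstack([R, t.reshape(3, 1)])
            X = _triangulate(uv_a[sub], uv_b[sub], P_a, P_b)
            z_a = X[:, 2]
            z_b = (X @ R.T + t)[:, 2]
            score = int(np.sum((z_a > 0) & (z_b > 0)))
            if best is None or score > best[0]:
                best = (score, R, t)
    _, R, t = best
    return R, t


# ---------------------------------------------------------------------------
# rectification


@dataclass
class RectifiedPair:
    homography_a: np.ndarray
    homography_b: np.ndarray
    rect_a: np.ndarray
    rect_b: np.ndarray
    row_epsilon_px: float
    K_new: np.ndarray      # shared intrinsics of the rectified cameras
    R_rect: np.ndarray     # view-a camera frame -> rectified frame
    R_ab: np.ndarray       # x_b = R_ab x_a + s * t_unit
    t_unit: np.ndarray


def _warp_image(img: np.ndarray, H: np.ndarray, out_shape) -> np.ndarray:
    h, w = out_shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    Hinv = np.linalg.inv(H)
    denom = Hinv[2, 0] * uu + Hinv[2, 1] * vv + Hinv[2, 2]
    su = (Hinv[0, 0] * uu + Hinv[0, 1] * vv + Hinv[0, 2]) / denom
    sv = (Hinv[1, 0] * uu + Hinv[1, 1] * vv + Hinv[1, 2]) / denom
    return map_coordinates(img, [sv, su], order=1, mode="constant", cval=0.0)


def _apply_h(H: np.ndarray, uv: np.ndarray) -> np.ndarray:
    p = np.column_stack([uv, np.ones(len(uv))]) @ H.T
    return p[:, :2] / p[:, 2:3]


def rectify_pair(image_a: np.ndarray, image_b: np.ndarray,
                 uv_a: np.ndarray, uv_b: np.ndarray,
                 K_a: np.ndarray, K_b: np.ndarray) -> RectifiedPair:
    """Estimate epipolar geometry from correspondences and rectify.

    After warping, corresponding points share an image row up to
    ``row_epsilon_px`` (reported from the correspondences themselves).
    Raises :class:`RectificationFailed` for < 8 or degenerate
    correspondences.
    """
    uv_a = np.asarray(uv_a, dtype=float)
    uv_b = np.asarray(uv_b, dtype=float)
    K_a = np.asarray(K_a, dtype=float)
    K_b = np.asarray(K_b, dtype=float)
    F = fundamental_8point(uv_a, uv_b)
    E = K_b.T @ F @ K_a
    # balance the two non-zero singular values of E
    U, S, Vt = np.linalg.svd(E)
    E = U @ np.diag([1.0, 1.0, 0.0]) @ Vt
    R, t = _decompose_essential(E, uv_a, uv_b, K_a, K_b)

    C_b = -R.T @ t                      # camera-b centre, a-frame, unit scale
    nb = np.linalg.norm(C_b)
    if nb < 1e-12:
        raise RectificationFailed("zero baseline")
    e1 = C_b / nb                       # new x-axis along the baseline
    e2 = np.cross([0.0, 0.0, 1.0], e1)
    n2 = np.linalg.norm(e2)
    if n2 < 1e-9:
        raise RectificationFailed("baseline parallel to the optical axis")
    e2 = e2 / n2
    e3 = np.cross(e1, e2)
    R_rect = np.stack([e1, e2, e3])

    f_new = 0.5 * (K_a[0, 0] + K_a[1, 1])
    K0 = np.array([[f_new, 0, 0], [0, f_new, 0], [0, 0, 1.0]])
    Ha0 = K0 @ R_rect @ np.linalg.inv(K_a)
    Hb0 = K0 @ R_rect @ R.T @ np.linalg.inv(K_b)

    def img_corners(img):
        h, w = img.shape
        return np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)

    wa = _apply_h(Ha0, img_corners(image_a))
    wb = _apply_h(Hb0, img_corners(image_b))
    allc = np.vstack([wa, wb])
    lo = np.floor(allc.min(axis=0))
    hi = np.ceil(allc.max(axis=0))
    out_w = int(min(hi[0] - lo[0] + 1, 2.0 * max(image_a.shape)))
    out_h = int(min(hi[1] - lo[1] + 1, 2.0 * max(image_a.shape)))
    K_new = K0.copy()
    K_new[0, 2] = -lo[0]
    K_new[1, 2] = -lo[1]
    H_a = K_new @ R_rect @ np.linalg.inv(K_a)
    H_b = K_new @ R_rect @ R.T @ np.linalg.inv(K_b)

    rect_a = _warp_image(image_a, H_a, (out_h, out_w))
    rect_b = _warp_image(image_b, H_b, (out_h, out_w))
    ra = _apply_h(H_a, uv_a)
    rb = _apply_h(H_b, uv_b)
    row_eps = float(np.max(np.abs(ra[:, 1] - rb[:, 1]))) if len(ra) else 0.0
    return RectifiedPair(H_a, H_b, rect_a, rect_b, row_eps,
                         K_new, R_rect, R, t)


# ---------------------------------------------------------------------------
# block matching


@dataclass
class DisparityMap:
    """Horizontal offset (px) per rectified-left pixel; ``x_left - x_right``
    is non-negative for points in front of the cameras."""
    values: np.ndarray
    valid: np.ndarray


def compute_disparity(pair: RectifiedPair, block_px: int = 11,
                      max_disp: int | None = None,
                      margin_frac: float = 0.05,
                      subpixel: bool = False,
                      min_disp: int = 0,
                      roi: tuple[int, int, int, int] | None = None
                      ) -> DisparityMap:
    """SAD block matching along rectified rows.

    Per pixel the disparity minimises the sum of absolute differences over
    a ``block_px`` square.  Pixels whose best and second-best costs
    (excluding immediate disparity neighbours) differ by no more than the
    uniqueness margin are marked invalid — low-texture regions match
    ambiguously and would poison the depth.  The margin scales with the
    image contrast, so perfectly uniform images are wholly invalid.

    ``roi = (row0, row1, col0, col1)`` restricts matching to a window of
    the rectified left frame (the output keeps the full frame shape);
    ``min_disp``/``max_disp`` window the search range.  Both cut the cost
    volume to what the scene geometry can actually produce.
    """
    if block_px < 3 or block_px % 2 == 0:
        raise ValueError("block_px must be odd and >= 3")
    left, right = pair.rect_a, pair.rect_b
    full_h, full_w = left.shape
    if max_disp is None:
        max_disp = max(full_w // 4, 1)
    if max_disp < 1:
        raise ValueError("max_disp must be >= 1")
    if not (0 <= min_disp <= max_disp):
        raise ValueError("min_disp must lie in [0, max_disp]")
    pad = block_px // 2
    margin = margin_frac * (block_px ** 2) * float(np.std(left))

    if roi is None:
        row0, row1, col0, col1 = 0, full_h, 0, full_w
    else:
        row0 = max(int(roi[0]), 0)
        row1 = min(int(roi[1]), full_h)
        col0 = max(int(roi[2]), 0)
        col1 = min(int(roi[3]), full_w)
        if row0 >= row1 or col0 >= col1:
            raise ValueError("empty roi")
    # the right-image columns a disparity d references sit d to the left
    ccol0 = max(col0 - max_disp - pad, 0)
    left_w = left[:, ccol0:col1]
    right_w = right[:, ccol0:col1]
    H, W = row1 - row0, col1 - ccol0
    off = col0 - ccol0
    n_d = max_disp + 1 - min_disp

    out_values = np.zeros((full_h, full_w))
    out_valid = np.zeros((full_h, full_w), dtype=bool)
    # the cost volume is processed in row bands to bound memory
    band = max(1, int(4e7 // max(n_d * W, 1)))
    d_idx = np.arange(n_d).reshape(-1, 1, 1)
    for r0 in range(row0, row1, band):
        r1 = min(r0 + band, row1)
        rlo, rhi = max(r0 - pad, 0), min(r1 + pad, full_h)
        Lb, Rb = left_w[rlo:rhi], right_w[rlo:rhi]
        cost = np.full((n_d, r1 - r0, W), np.inf, dtype=np.float32)
        sl = slice(r0 - rlo, r0 - rlo + (r1 - r0))
        for j, d in enumerate(range(min_disp, min(max_disp + 1, W))):
            diff = np.abs(Lb[:, d:] - Rb[:, : W - d]).astype(np.float32)
            c = uniform_filter(diff, size=block_px, mode="nearest")
            cost[j][:, d:] = c[sl] * (block_px ** 2)

        best_d = np.argmin(cost, axis=0)
        best = np.take_along_axis(cost, best_d[None], axis=0)[0]
        # second best outside +-1 of the winner (uniqueness check)
        masked = np.where(np.abs(d_idx - best_d[None]) <= 1, np.inf, cost)
        second = masked.min(axis=0)
        # a pixel whose alternative disparities could not even be
        # evaluated (image border) cannot demonstrate uniqueness
        with np.errstate(invalid="ignore"):
            ok = (np.isfinite(best) & np.isfinite(second)
                  & ((second - best) > margin))

        vals = best_d.astype(float) + min_disp
        if subpixel:
            # parabola fit through the three costs around the winner
            with np.errstate(invalid="ignore"):
                d0 = np.clip(best_d, 1, n_d - 2)
                cm = np.take_along_axis(cost, (d0 - 1)[None], axis=0)[0]
                c0 = np.take_along_axis(cost, d0[None], axis=0)[0]
                cp = np.take_along_axis(cost, (d0 + 1)[None], axis=0)[0]
                fin = np.isfinite(cm) & np.isfinite(c0) & np.isfinite(cp)
                denom = np.where(fin, np.nan_to_num(cm - 2 * c0 + cp,
                                                    posinf=0.0), 1.0)
                fit = fin & (denom > 1e-12) & (best_d == d0)
                num = np.nan_to_num(cm - cp, posinf=0.0, neginf=0.0)
                delta = np.where(fit, 0.5 * num / np.where(fit, denom, 1.0),
                                 0.0)
            vals = vals + np.clip(delta, -0.5, 0.5)
        out_values[r0:r1, col0:col1] = np.where(ok, vals, 0.0)[:, off:]
        out_valid[r0:r1, col0:col1] = ok[:, off:]
    return DisparityMap(out_values, out_valid)


def roi_for_masks(pair: RectifiedPair, masks, margin_px: int = 16
                  ) -> tuple[int, int, int, int]:
    """Rectified-frame window covering the given view-a masks.

    The rectifying homography of view a is a pure rotation about the
    camera centre, so it maps view-a pixels to rectified pixels exactly at
    any depth — the mask bounds transfer without knowing the geometry.
    """
    vs, us = np.nonzero(np.any(np.asarray(masks, dtype=bool), axis=0))
    if vs.size == 0:
        raise ValueError("masks are empty")
    corners = np.array([[us.min(), vs.min()], [us.max(), vs.min()],
                        [us.max(), vs.max()], [us.min(), vs.max()]], float)
    warped = _apply_h(pair.homography_a, corners)
    h, w = pair.rect_a.shape
    return (int(warped[:, 1].min()) - margin_px,
            int(warped[:, 1].max()) + margin_px,
            int(warped[:, 0].min()) - margin_px,
            int(warped[:, 0].max()) + margin_px)


def disparity_to_depth(disp: DisparityMap, focal_px: float,
                       baseline_mm: float) -> DepthMap:
    """``Z = f B / d`` for valid positive disparities; ``d <= 0`` is invalid."""
    if focal_px <= 0 or baseline_mm <= 0:
        raise ValueError("focal_px and baseline_mm must be positive")
    ok = disp.valid & (disp.values > 0)
    with np.errstate(divide="ignore"):
        z = np.where(ok, focal_px * baseline_mm / np.where(ok, disp.values, 1.0), 0.0)
    return DepthMap(z, ok)


# ---------------------------------------------------------------------------
# metric scale and back-projection


def baseline_from_card_poses(pose_a: CardPose, pose_b: CardPose,
                             spec: CardSpec, R_ab: np.ndarray,
                             t_unit: np.ndarray) -> float:
    """Camera-to-camera distance from the card pose seen in both views.

    A phone's true stereo baseline is unknown; the card anchors it.  With
    the card centre ``X_a``/``X_b`` in each camera frame and the relative
    pose ``x_b = R x_a + s t``, the least-squares scale is the projection
    of the residual onto ``t``.  The centre (not the corners) is used so
    the result is independent of how each view's detector ordered the
    corners of the symmetric rectangle.
    """
    del spec  # the centre alone fixes the scale
    s = float((pose_b.plane_point - R_ab @ pose_a.plane_point) @ t_unit)
    return abs(s)


def rectified_points_in_view_a(pair: RectifiedPair, disp: DisparityMap,
                               baseline_mm: float, K_a: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Back-project matched rectified pixels into the view-a camera frame.

    Returns ``(points (N, 3) in the a-camera frame, (N, 2) pixel
    coordinates of each point in the original view-a image)`` so point
    clouds can be assigned to the per-item masks of view a.
    """
    f = pair.K_new[0, 0]
    ok = disp.valid & (disp.values > 0)
    vs, us = np.nonzero(ok)
    d = disp.values[vs, us]
    Z = f * baseline_mm / d
    Kinv = np.linalg.inv(pair.K_new)
    homo = np.column_stack([us, vs, np.ones_like(us, dtype=float)])
    rays = homo @ Kinv.T
    pts_rect = rays * Z[:, None]
    pts_a = pts_rect @ pair.R_rect            # R_rect.T applied per point
    z = pts_a[:, 2]
    front = z > 1e-6
    pts_a = pts_a[front]
    K_a = np.asarray(K_a, dtype=float)
    uv = np.column_stack([
        K_a[0, 0] * pts_a[:, 0] / pts_a[:, 2] + K_a[0, 2],
        K_a[1, 1] * pts_a[:, 1] / pts_a[:, 2] + K_a[1, 2],
    ])
    return pts_a, uv
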
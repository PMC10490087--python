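"""Reference-card detection, planar pose recovery and metric alignment.

A flat card of known physical size placed beside the meal is the single
metric anchor of the whole system: its projected corners fix the scale of
any depth map, whether that depth came from a single-image provider (which
may be metric only up to scale) or from stereo.  Pose recovery solves the
card-rectangle-to-image homography and decomposes it with the camera
intrinsics; alignment rescales depth so that the median depth over the card
region equals the recovered camera-to-card-centre distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _fill_polygon

from .errors import AlignmentImpossible, CardNotFound, PoseUnsolvable
from .geometry import DepthMap

__all__ = ["CardSpec", "CardDetection", "CardPose",
           "detect_card", "estimate_pose", "metric_align", "homography_dlt",
           "fit_plane_to_points", "refine_pose_with_depth"]

_CARD_INTENSITY_THRESHOLD = 0.8
_MIN_CARD_AREA_PX = 100.0


@dataclass(frozen=True)
class CardSpec:
    """Physical card dimensions in mm, landscape ordering (width >= height).

    Default is the ID-1 credit-card format, 85.6 x 54.0 mm.
    """
    width_mm: float = 85.6
    height_mm: float = 54.0

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("card dimensions must be positive")
        if self.width_mm < self.height_mm:
            raise ValueError("landscape ordering required (width >= height)")

    def metric_corners(self) -> np.ndarray:
        """Corner coordinates in the card's own frame (z = 0, centre at
        origin), ordered TL, TR, BR, BL with x along the width."""
        w, h = self.width_mm, self.height_mm
        return np.array([[-w / 2, -h / 2, 0.0], [w / 2, -h / 2, 0.0],
                         [w / 2, h / 2, 0.0], [-w / 2, h / 2, 0.0]])


@dataclass
class CardDetection:
    corners_px: np.ndarray   # (4, 2) ordered TL, TR, BR, BL in the card frame
    confidence: float        # rectangularity score in [0, 1]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = _fill_polygon(self.corners_px[:, 1], self.corners_px[:, 0],
                               shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out


@dataclass
class CardPose:
    plane_normal: np.ndarray       # unit, camera frame, facing the camera
    plane_point: np.ndarray        # card centre, camera frame, mm
    centre_distance_mm: float
    R: np.ndarray                  # card-frame -> camera-frame rotation

    def __post_init__(self):
        n = np.linalg.norm(self.plane_normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("plane normal must be unit length")
        if self.centre_distance_mm <= 0:
            raise ValueError("centre distance must be positive")

    @property
    def centre_depth_mm(self) -> float:
        """Depth of the card centre along the optical axis.

        Depth maps store distance along the optical axis, so alignment must
        compare like with like: for a card placed off-axis the Euclidean
        centre distance exceeds this value and would inflate the scale.
        """
        return float(self.plane_point[2])


# ---------------------------------------------------------------------------
# detection


def _quad_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _order_corners(quad: np.ndarray) -> np.ndarray:
    """Canonical ordering: clockwise in image coordinates starting so the
    first edge is a long (width) edge, resolving the 4-fold ambiguity by
    aspect ratio.  The residual 2-fold ambiguity is irrelevant for a plain
    rectangle's pose."""
    c = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - c[1], quad[:, 0] - c[0])
    quad = quad[np.argsort(ang)]  # counter-clockwise in (u, v up)=clockwise on screen
    e0 = np.linalg.norm(quad[1] - quad[0])
    e1 = np.linalg.norm(quad[2] - quad[1])
    if e1 > e0:  # rotate so a long edge comes first
        quad = np.roll(quad, -1, axis=0)
    return quad


def _dilate_quad(quad: np.ndarray, px: float = 0.5) -> np.ndarray:
    """Push each quad edge outward by ``px``.

    The hull of thresholded pixels lies on *pixel centres* inside the card,
    which understates the card by half a pixel per side; moving the edges
    out by 0.5 px removes that systematic bias (the residual edge-phase
    error is zero-mean).
    """
    centre = quad.mean(axis=0)
    lines = []
    for i in range(4):
        p0, p1 = quad[i], quad[(i + 1) % 4]
        e = p1 - p0
        n = np.array([-e[1], e[0]])
        n = n / np.linalg.norm(n)
        if n @ (centre - p0) > 0:
            n = -n                      # outward normal
        lines.append((p0 + px * n, e))
    out = []
    for i in range(4):
        (q0, d0) = lines[(i - 1) % 4]
        (q1, d1) = lines[i]
        s = np.linalg.solve(np.column_stack([d0, -d1]), q1 - q0)
        out.append(q0 + s[0] * d0)
    return np.asarray(out)


def detect_card(intensity_image: np.ndarray,
                threshold: float = _CARD_INTENSITY_THRESHOLD) -> CardDetection:
    """Detect the card as the brightest quadrilateral region.

    The baseline detector targets the synthetic renderer's card appearance:
    a distinct high-intensity band.  Connected bright components are
    reduced to quadrilaterals via their convex hull (best 4-subset by
    area); among candidates the one maximising rectangularity x area wins.
    Raises :class:`CardNotFound` when nothing plausible exists — callers
    degrade to the standard-serving fallback, never crash.
    """
    from scipy import ndimage

    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    bright = img >= threshold
    labels, n = ndimage.label(bright)
    best = None
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if xs.size < _MIN_CARD_AREA_PX:
            continue
        pts = np.column_stack([xs, ys]).astype(float)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            continue
        hp = pts[hull.vertices]
        if len(hp) < 4:
            continue
        # best-area 4-subset of the hull vertices approximates the quad
        quad = max(combinations(range(len(hp)), 4),
                   key=lambda idx: _quad_area(hp[list(idx)]))
        quad = hp[list(quad)]
        area = _quad_area(quad)
        if area < _MIN_CARD_AREA_PX:
            continue
        rectangularity = min(xs.size / area, 1.0) if area > 0 else 0.0
        score = rectangularity * area
        if best is None or score > best[0]:
            best = (score, quad, rectangularity)
    if best is None:
        raise CardNotFound("no plausible card quadrilateral in the image")
    _, quad, rectangularity = best
    quad = _dilate_quad(_order_corners(quad))
    return CardDetection(_order_corners(quad), float(rectangularity))


# ---------------------------------------------------------------------------
# planar pose


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform homography mapping ``src`` (N,2) to ``dst``."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 4:
        raise ValueError("homography needs at least 4 points")

    def normalise(p):
        c = p.mean(axis=0)
        s = np.sqrt(2) / max(np.mean(np.linalg.norm(p - c, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        return (p - c) * s, T

    sp, Ts = normalise(src)
    dp, Td = normalise(dst)
    A = []
    for (x, y), (u, v) in zip(sp, dp):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(A)
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-10:
        raise PoseUnsolvable("degenerate point configuration")
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def estimate_pose(detection: CardDetection, spec: CardSpec,
                  intrinsics: np.ndarray) -> CardPose:
    """Recover the card plane from its four projected corners.

    Solves the metric-rectangle-to-image homography and decomposes it with
    the intrinsics (H ~ K [r1 r2 t]); of the two algebraic solutions the
    one with the card in front of the camera and its normal facing the
    camera is returned.
    """
    K = np.asarray(intrinsics, dtype=float)
    corners = np.asarray(detection.corners_px, dtype=float)
    if corners.shape != (4, 2):
        raise PoseUnsolvable("need exactly four corners")
    # collinearity check
    d = corners - corners.mean(axis=0)
    if np.linalg.matrix_rank(d, tol=1e-6) < 2:
        raise PoseUnsolvable("corners are collinear")
    metric = spec.metric_corners()[:, :2]
    try:
        H = homography_dlt(metric, corners)
    except PoseUnsolvable:
        raise
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = (Kinv @ H).T
    lam = 1.0 / ((np.linalg.norm(h1) + np.linalg.norm(h2)) / 2.0)
    r1, r2, t = lam * h1, lam * h2, lam * h3
    if t[2] < 0:  # the other algebraic solution: card behind the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.stack([r1, r2, r3], axis=1)
    U, _, Vt = np.linalg.svd(R)        # nearest rotation
    R = U @ np.diag([1, 1, np.linalg.det(U @ Vt)]) @ Vt
    normal = R[:, 2]
    if normal @ t > 0:  # orient the normal toward the camera
        normal = -normal
    dist = float(np.linalg.norm(t))
    if dist <= 0 or not np.isfinite(dist):
        raise PoseUnsolvable("non-finite pose translation")
    return CardPose(plane_normal=normal, plane_point=t,
                    centre_distance_mm=dist, R=R)


def fit_plane_to_points(points: np.ndarray,
                        fallback: CardPose | None = None) -> CardPose | None:
    """Least-squares card plane from 3-D points on the card surface.

    Four projected corners constrain the plane normal only weakly (the
    perspective foreshortening of a small card is a fraction of a pixel),
    but the depth values over the whole card region pin it down.  Returns
    ``fallback`` when fewer than 20 points are available.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 20:
        return fallback
    centroid = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = Vt[-1]
    if normal @ centroid > 0:       # orient toward the camera at the origin
        normal = -normal
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    x_ax = np.cross(a, normal)
    x_ax /= np.linalg.norm(x_ax)
    y_ax = np.cross(normal, x_ax)
    R = np.stack([x_ax, y_ax, normal], axis=1)
    return CardPose(plane_normal=normal, plane_point=centroid,
                    centre_distance_mm=float(np.linalg.norm(centroid)), R=R)


def refine_pose_with_depth(depth: DepthMap, card_region_mask: np.ndarray,
                           intrinsics: np.ndarray, pose: CardPose) -> CardPose:
    """Replace a homography pose's plane by a depth-based plane fit.

    Expects *aligned* (metric) depth; the homography pose still provides
    the scale anchor, this sharpens the plane the heights are measured
    from.  Falls back to ``pose`` when the card region has too little
    valid depth.
    """
    K = np.asarray(intrinsics, dtype=float)
    sel = np.asarray(card_region_mask, dtype=bool) & depth.valid
    vs, us = np.nonzero(sel)
    Z = depth.values[vs, us]
    X = (us - K[0, 2]) * Z / K[0, 0]
    Y = (vs - K[1, 2]) * Z / K[1, 1]
    fitted = fit_plane_to_points(np.column_stack([X, Y, Z]), fallback=pose)
    return fitted if fitted is not None else pose


# ---------------------------------------------------------------------------
# metric alignment


def metric_align(depth: DepthMap, pose: CardPose,
                 card_region_mask: np.ndarray) -> tuple[float, DepthMap]:
    """Rescale a depth map so the card region sits at its known distance.

    ``scale = card centre depth (from the pose) / median(depth over the
    card region)``; the median (rather than the mean) keeps speckle
    outliers from biasing the scale.  Providers that are already metric
    get ``scale ~ 1`` — still applied, which makes the operation
    idempotent.
    """
    mask = np.asarray(card_region_mask, dtype=bool)
    sel = mask & depth.valid
    if not np.any(sel):
        raise AlignmentImpossible("no valid depth under the card region")
    med = float(np.median(depth.values[sel]))
    if med <= 0:
        raise AlignmentImpossible("non-positive card-region depth")
    scale = pose.centre_depth_mm / med
    aligned = DepthMap(np.where(depth.valid, depth.values * scale, 0.0),
                       depth.valid.copy())
    return scale, aligned
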
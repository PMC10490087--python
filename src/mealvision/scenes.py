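"""Synthetic tabletop scenes with analytic ground-truth volumes.

Real meal photographs come with no volume ground truth, which makes every
stage of an image-based dietary assessment pipeline hard to validate.  This
module renders parametric tabletop worlds instead: a planar table, a
rectangular reference card lying flat on it, and food stand-ins built from
solids whose volumes have closed forms (cuboid, cylinder, spherical cap,
conical frustum).  A pinhole camera ray-caster produces exact depth maps,
per-item masks, card corner projections and a procedurally textured
grayscale image whose texture is a function of the 3-D hit point — so the
same surface patch looks the same from both views of a stereo pair, which
is what block matching needs.

All lengths are millimetres; volumes are reported in millilitres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CardOutOfView, SceneError
from .geometry import CameraModel, DepthMap

__all__ = [
    "SolidSpec", "SceneSpec", "Scene", "RenderOutput", "SyntheticStudy",
    "make_scene", "render_depth", "render_stereo", "add_depth_noise",
    "generate_study", "default_catalogue",
]

_EPS = 1e-9
_TEXTURE_CELL_MM = 3.0


# ---------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class SolidSpec:
    """One food stand-in: a parametric solid resting on the table plane.

    ``params`` by kind (mm):
      cuboid        width, depth, height
      cylinder      radius, height
      spherical_cap sphere_radius, height   (height <= 2 * sphere_radius)
      frustum       radius_bottom, radius_top, height
    """

    kind: str
    params: dict
    centre_xy: tuple[float, float]
    fine_category: str


@dataclass(frozen=True)
class SceneSpec:
    # the default card centre deliberately avoids placing card edges
    # exactly on pixel centres of the reference cameras, which would make
    # boundary pixels tie-break unstably under floating-point rescaling
    card_centre_xy: tuple[float, float] = (-95.3, -69.6)
    card_yaw_deg: float = 0.0
    card_size_mm: tuple[float, float] = (85.6, 54.0)
    solids: tuple[SolidSpec, ...] = ()
    table_extent_mm: float = 500.0

    def to_dict(self) -> dict:
        return {
            "card_centre_xy": list(self.card_centre_xy),
            "card_yaw_deg": self.card_yaw_deg,
            "card_size_mm": list(self.card_size_mm),
            "table_extent_mm": self.table_extent_mm,
            "solids": [
                {"kind": s.kind, "params": dict(s.params),
                 "centre_xy": list(s.centre_xy),
                 "fine_category": s.fine_category}
                for s in self.solids
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            card_centre_xy=tuple(d["card_centre_xy"]),
            card_yaw_deg=d.get("card_yaw_deg", 0.0),
            card_size_mm=tuple(d["card_size_mm"]),
            table_extent_mm=d.get("table_extent_mm", 500.0),
            solids=tuple(
                SolidSpec(s["kind"], dict(s["params"]), tuple(s["centre_xy"]),
                          s["fine_category"])
                for s in d.get("solids", [])
            ),
        )


# ---------------------------------------------------------------------------
# solids: closed-form volume, exact ray intersection, surface distance


class _Solid:
    def __init__(self, spec: SolidSpec):
        self.spec = spec
        self.cx, self.cy = spec.centre_xy

    def volume_mm3(self) -> float:
        raise NotImplementedError

    def intersect(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Smallest positive ray parameter per ray, inf on miss.

        Rays are ``p = origin + t * dirs``; ``dirs`` need not be unit —
        the caller normalises them so ``t`` equals depth along the optical
        axis.
        """
        raise NotImplementedError

    def surface_distance(self, pts: np.ndarray) -> np.ndarray:
        """Unsigned distance from points to the solid's visible surface."""
        raise NotImplementedError

    def plan_bbox(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) footprint on the table plane."""
        raise NotImplementedError

    def top_keypoints(self) -> np.ndarray:
        """A handful of exact surface points visible from above (stereo GT)."""
        raise NotImplementedError


def _pick_min_positive(candidates: list[tuple[np.ndarray, np.ndarray]],
                       n: int) -> np.ndarray:
    """Combine (t, valid) candidate hits into the nearest positive hit."""
    best = np.full(n, np.inf)
    for t, ok in candidates:
        t = np.where(ok & (t > _EPS), t, np.inf)
        best = np.minimum(best, t)
    return best


class _Cuboid(_Solid):
    def __init__(self, spec: SolidSpec):
        super().__init__(spec)
        p = spec.params
        self.w, self.d, self.h = float(p["width"]), float(p["depth"]), float(p["height"])
        if min(self.w, self.d, self.h) <= 0:
            raise SceneError(f"cuboid '{spec.fine_category}': non-positive dimension")
        self.lo = np.array([self.cx - self.w / 2, self.cy - self.d / 2, 0.0])
        self.hi = np.array([self.cx + self.w / 2, self.cy + self.d / 2, self.h])

    def volume_mm3(self) -> float:
        return self.w * self.d * self.h

    def intersect(self, origin, dirs):
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / dirs
            t1 = (self.lo - origin) * inv
            t2 = (self.hi - origin) * inv
        tmin = np.nanmax(np.minimum(t1, t2), axis=-1)
        tmax = np.nanmin(np.maximum(t1, t2), axis=-1)
        hit = (tmax >= np.maximum(tmin, _EPS))
        return np.where(hit & (tmin > _EPS), tmin, np.inf)

    def surface_distance(self, pts):
        c = np.array([self.cx, self.cy, self.h / 2])
        half = np.array([self.w / 2, self.d / 2, self.h / 2])
        q = np.abs(pts - c) - half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(np.max(q, axis=-1), 0.0)
        return np.abs(outside + inside)

    def plan_bbox(self):
        return self.lo[0], self.hi[0], self.lo[1], self.hi[1]

    def top_keypoints(self):
        fx = np.array([-0.35, 0.0, 0.35])
        pts = [(self.cx + a * self.w, self.cy + b * self.d, self.h)
               for a in fx for b in fx]
        return np.array(pts)


class _Cylinder(_Solid):
    def __init__(self, spec: SolidSpec):
        super().__init__(spec)
        p = spec.params
        self.r, self.h = float(p["radius"]), float(p["height"])
        if self.r <= 0 or self.h <= 0:
            raise SceneError(f"cylinder '{spec.fine_category}': non-positive parameter")

    def volume_mm3(self) -> float:
        return math.pi * self.r ** 2 * self.h

    def intersect(self, origin, dirs):
        n = dirs.shape[0]
        ox, oy = origin[0] - self.cx, origin[1] - self.cy
        dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        a = dx ** 2 + dy ** 2
        b = 2 * (ox * dx + oy * dy)
        c = ox ** 2 + oy ** 2 - self.r ** 2
        disc = b ** 2 - 4 * a * c
        cands = []
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            for sgn in (-1.0, 1.0):
                t = (-b + sgn * sq) / (2 * a)
                z = origin[2] + t * dz
                cands.append((t, (disc >= 0) & (a > _EPS) & (z >= -_EPS) & (z <= self.h + _EPS)))
            # top disk
            t_top = (self.h - origin[2]) / dz
            px = origin[0] + t_top * dx - self.cx
            py = origin[1] + t_top * dy - self.cy
            cands.append((t_top, (np.abs(dz) > _EPS) & (px ** 2 + py ** 2 <= self.r ** 2)))
        return _pick_min_positive(cands, n)

    def surface_distance(self, pts):
        dr = np.hypot(pts[:, 0] - self.cx, pts[:, 1] - self.cy) - self.r
        dz = np.abs(pts[:, 2] - self.h / 2) - self.h / 2
        outside = np.hypot(np.maximum(dr, 0), np.maximum(dz, 0))
        inside = np.minimum(np.maximum(dr, dz), 0.0)
        return np.abs(outside + inside)

    def plan_bbox(self):
        return self.cx - self.r, self.cx + self.r, self.cy - self.r, self.cy + self.r

    def top_keypoints(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.stack([self.cx + 0.7 * self.r * np.cos(ang),
                         self.cy + 0.7 * self.r * np.sin(ang),
                         np.full(8, self.h)], axis=1)
        return np.vstack([ring, [[self.cx, self.cy, self.h]]])


class _SphericalCap(_Solid):
    def __init__(self, spec: SolidSpec):
        super().__init__(spec)
        p = spec.params
        self.R, self.h = float(p["sphere_radius"]), float(p["height"])
        if self.R <= 0 or self.h <= 0:
            raise SceneError(f"spherical_cap '{spec.fine_category}': non-positive parameter")
        if self.h > 2 * self.R + _EPS:
            raise SceneError(f"spherical_cap '{spec.fine_category}': height exceeds sphere diameter")
        self.centre3 = np.array([self.cx, self.cy, self.h - self.R])
        # plan footprint radius: base circle, or the equator if the cap
        # is taller than the sphere radius
        self.a = math.sqrt(self.h * (2 * self.R - self.h)) if self.h < self.R else self.R

    def volume_mm3(self) -> float:
        return math.pi * self.h ** 2 * (3 * self.R - self.h) / 3.0

    def intersect(self, origin, dirs):
        n = dirs.shape[0]
        o = origin - self.centre3
        b = 2 * np.einsum("j,ij->i", o, dirs)
        a = np.einsum("ij,ij->i", dirs, dirs)
        c = o @ o - self.R ** 2
        disc = b ** 2 - 4 * a * c
        cands = []
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            for sgn in (-1.0, 1.0):
                t = (-b + sgn * sq) / (2 * a)
                z = origin[2] + t * dirs[:, 2]
                cands.append((t, (disc >= 0) & (z >= -_EPS) & (z <= self.h + _EPS)))
        return _pick_min_positive(cands, n)

    def surface_distance(self, pts):
        return np.abs(np.linalg.norm(pts - self.centre3, axis=-1) - self.R)

    def plan_bbox(self):
        return self.cx - self.a, self.cx + self.a, self.cy - self.a, self.cy + self.a

    def top_keypoints(self):
        # points on the sphere at several polar angles below the apex
        top = np.array([[self.cx, self.cy, self.h]])
        pts = [top[0]]
        for frac in (0.35, 0.6):
            zz = self.h - frac * self.h
            rr_sq = self.R ** 2 - (zz - (self.h - self.R)) ** 2
            if rr_sq <= 0:
                continue
            rr = math.sqrt(rr_sq)
            for ang in np.linspace(0, 2 * np.pi, 4, endpoint=False):
                pts.append([self.cx + rr * math.cos(ang),
                            self.cy + rr * math.sin(ang), zz])
        return np.array(pts)


class _Frustum(_Solid):
    def __init__(self, spec: SolidSpec):
        super().__init__(spec)
        p = spec.params
        self.r1 = float(p["radius_bottom"])
        self.r2 = float(p["radius_top"])
        self.h = float(p["height"])
        if min(self.r1, self.r2, self.h) <= 0:
            raise SceneError(f"frustum '{spec.fine_category}': non-positive parameter")
        self.k = (self.r2 - self.r1) / self.h

    def volume_mm3(self) -> float:
        return math.pi * self.h * (self.r1 ** 2 + self.r1 * self.r2 + self.r2 ** 2) / 3.0

    def intersect(self, origin, dirs):
        n = dirs.shape[0]
        ox, oy, oz = origin[0] - self.cx, origin[1] - self.cy, origin[2]
        dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        k, r1 = self.k, self.r1
        A = dx ** 2 + dy ** 2 - (k * dz) ** 2
        B = 2 * (ox * dx + oy * dy - k * dz * (r1 + k * oz))
        C = ox ** 2 + oy ** 2 - (r1 + k * oz) ** 2
        disc = B ** 2 - 4 * A * C
        cands = []
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            for sgn in (-1.0, 1.0):
                t = (-B + sgn * sq) / (2 * A)
                z = oz + t * dz
                cands.append((t, (disc >= 0) & (np.abs(A) > _EPS)
                              & (z >= -_EPS) & (z <= self.h + _EPS)))
            t_top = (self.h - oz) / dz
            px = ox + t_top * dx
            py = oy + t_top * dy
            cands.append((t_top, (np.abs(dz) > _EPS) & (px ** 2 + py ** 2 <= self.r2 ** 2)))
        return _pick_min_positive(cands, n)

    def surface_distance(self, pts):
        rho = np.hypot(pts[:, 0] - self.cx, pts[:, 1] - self.cy)
        z = pts[:, 2]
        # distance to the lateral segment (r1,0)-(r2,h) in the (rho, z) half-plane
        ax, az = self.r1, 0.0
        bx, bz = self.r2, self.h
        vx, vz = bx - ax, bz - az
        tt = np.clip(((rho - ax) * vx + (z - az) * vz) / (vx ** 2 + vz ** 2), 0, 1)
        d_lat = np.hypot(rho - (ax + tt * vx), z - (az + tt * vz))
        d_top = np.where(rho <= self.r2, np.abs(z - self.h),
                         np.hypot(rho - self.r2, z - self.h))
        return np.minimum(d_lat, d_top)

    def plan_bbox(self):
        r = max(self.r1, self.r2)
        return self.cx - r, self.cx + r, self.cy - r, self.cy + r

    def top_keypoints(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.stack([self.cx + 0.7 * self.r2 * np.cos(ang),
                         self.cy + 0.7 * self.r2 * np.sin(ang),
                         np.full(8, self.h)], axis=1)
        return np.vstack([ring, [[self.cx, self.cy, self.h]]])


_SOLID_CLASSES = {
    "cuboid": _Cuboid,
    "cylinder": _Cylinder,
    "spherical_cap": _SphericalCap,
    "frustum": _Frustum,
}


def build_solid(spec: SolidSpec) -> _Solid:
    try:
        cls = _SOLID_CLASSES[spec.kind]
    except KeyError:
        raise SceneError(f"unknown shape kind {spec.kind!r} "
                         f"for solid '{spec.fine_category}'") from None
    return cls(spec)


# ---------------------------------------------------------------------------
# scene assembly


def _card_corners_world(spec: SceneSpec) -> np.ndarray:
    """Card corners on the table plane, ordered TL, TR, BR, BL in the card
    frame (x along the width, y along the height, landscape ordering)."""
    w, h = spec.card_size_mm
    yaw = math.radians(spec.card_yaw_deg)
    rot = np.array([[math.cos(yaw), -math.sin(yaw)],
                    [math.sin(yaw), math.cos(yaw)]])
    local = np.array([[-w / 2, -h / 2], [w / 2, -h / 2],
                      [w / 2, h / 2], [-w / 2, h / 2]])
    xy = local @ rot.T + np.asarray(spec.card_centre_xy)
    return np.column_stack([xy, np.zeros(4)])


@dataclass
class Scene:
    spec: SceneSpec
    solids: list
    analytic_volume_mL: list[float]
    card_corner_world: np.ndarray

    @property
    def categories(self) -> list[str]:
        return [s.spec.fine_category for s in self.solids]

    @property
    def centre(self) -> np.ndarray:
        return np.zeros(3)


def make_scene(spec: SceneSpec) -> Scene:
    """Validate a scene specification and compute closed-form volumes.

    Volumes (mL): cuboid w*d*h; cylinder pi r^2 h; spherical cap
    pi h^2 (3R - h) / 3; frustum pi h (r1^2 + r1 r2 + r2^2) / 3 — all in
    mm^3 then divided by 1000.
    """
    w, h = spec.card_size_mm
    if w <= 0 or h <= 0:
        raise SceneError("card dimensions must be positive")
    solids = [build_solid(s) for s in spec.solids]
    card_xy = _card_corners_world(spec)[:, :2]
    cb = (card_xy[:, 0].min(), card_xy[:, 0].max(),
          card_xy[:, 1].min(), card_xy[:, 1].max())
    for solid in solids:
        sb = solid.plan_bbox()
        if not (sb[1] < cb[0] or sb[0] > cb[1] or sb[3] < cb[2] or sb[2] > cb[3]):
            raise SceneError(
                f"solid '{solid.spec.fine_category}' overlaps the card in plan view")
    vols = [s.volume_mm3() / 1000.0 for s in solids]
    return Scene(spec, solids, vols, _card_corners_world(spec))


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderOutput:
    depth: DepthMap
    item_masks: np.ndarray          # (n_items, H, W) bool, pairwise disjoint
    card_mask: np.ndarray           # (H, W) bool
    card_corners_px: np.ndarray     # (4, 2), exact pinhole projections
    intensity: np.ndarray           # (H, W) float in [0, 1]
    index: np.ndarray               # (H, W) int: 0 background, k = item k
    camera: CameraModel


def _texture(points: np.ndarray, cell_mm: float = _TEXTURE_CELL_MM) -> np.ndarray:
    """Deterministic view-consistent texture: a hash of the quantised 3-D
    surface point, so both stereo views see identical surface intensity."""
    q = np.floor(points / cell_mm)
    s = np.sin(q[..., 0] * 12.9898 + q[..., 1] * 78.233 + q[..., 2] * 37.719)
    s = s * 43758.5453
    return s - np.floor(s)


def render_depth(scene: Scene, camera: CameraModel) -> RenderOutput:
    """Exact ray-cast depth, masks and textured intensity for one view."""
    if camera.width < 64 or camera.height < 64:
        raise SceneError("image size must be at least 64x64")
    corners_px = _project_card_or_raise(scene, camera)

    origin, dirs = camera.pixel_rays()
    H, W = camera.height, camera.width
    flat_dirs = dirs.reshape(-1, 3)
    n = flat_dirs.shape[0]

    # table plane z = 0
    dz = flat_dirs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_plane = -origin[2] / dz
    plane_pt = origin + t_plane[:, None] * flat_dirs
    ext = scene.spec.table_extent_mm / 2.0
    on_table = ((np.abs(dz) > _EPS) & (t_plane > _EPS)
                & (np.abs(plane_pt[:, 0]) <= ext) & (np.abs(plane_pt[:, 1]) <= ext))
    t_plane = np.where(on_table, t_plane, np.inf)

    hits = [t_plane] + [s.intersect(origin, flat_dirs) for s in scene.solids]
    all_t = np.stack(hits, axis=0)                      # (1 + n_items, N)
    owner = np.argmin(all_t, axis=0)
    t_best = np.min(all_t, axis=0)
    valid = np.isfinite(t_best)

    depth_vals = np.where(valid, t_best, 0.0)
    depth = DepthMap(depth_vals.reshape(H, W), valid.reshape(H, W))

    index = np.where(valid, owner, 0).reshape(H, W).astype(np.int32)
    item_masks = np.stack(
        [(index == i + 1) for i in range(len(scene.solids))], axis=0
    ) if scene.solids else np.zeros((0, H, W), dtype=bool)

    # card mask: table-owned pixels whose hit point lies inside the card rect
    hit_pts = origin + np.where(valid, t_best, 1.0)[:, None] * flat_dirs
    yaw = math.radians(scene.spec.card_yaw_deg)
    rot = np.array([[math.cos(yaw), math.sin(yaw)],
                    [-math.sin(yaw), math.cos(yaw)]])
    rel = (hit_pts[:, :2] - np.asarray(scene.spec.card_centre_xy)) @ rot.T
    cw, ch = scene.spec.card_size_mm
    in_card = (np.abs(rel[:, 0]) <= cw / 2) & (np.abs(rel[:, 1]) <= ch / 2)
    card_mask = (valid & (owner == 0) & in_card).reshape(H, W)

    # card pixels occupy a distinct bright band so a threshold detector
    # can find the card; everything else stays well below it
    tex = _texture(hit_pts)
    flat_int = np.where(valid, 0.15 + 0.5 * tex, 0.0)
    cm = card_mask.reshape(-1)
    flat_int[cm] = 0.88 + 0.12 * tex[cm]
    intensity = flat_int.reshape(H, W)

    return RenderOutput(depth, item_masks, card_mask, corners_px,
                        intensity, index, camera)


def _project_card_or_raise(scene: Scene, camera: CameraModel) -> np.ndarray:
    pc = camera.world_to_camera(scene.card_corner_world)
    if np.any(pc[:, 2] <= 0):
        raise CardOutOfView("card behind the camera")
    corners = camera.project(scene.card_corner_world)
    if (np.any(corners[:, 0] < 0) or np.any(corners[:, 0] > camera.width - 1)
            or np.any(corners[:, 1] < 0) or np.any(corners[:, 1] > camera.height - 1)):
        raise CardOutOfView("card not fully inside the image")
    return corners


@dataclass
class Correspondences:
    """Exact ground-truth pixel correspondences between two views."""
    uv_a: np.ndarray      # (N, 2)
    uv_b: np.ndarray      # (N, 2)
    world: np.ndarray     # (N, 3)
    labels: list[str]


def scene_keypoints_world(scene: Scene) -> tuple[np.ndarray, list[str]]:
    pts = [scene.card_corner_world]
    labels = [f"card_corner_{i}" for i in range(4)]
    for i, s in enumerate(scene.solids):
        kp = s.top_keypoints()
        pts.append(kp)
        labels += [f"item{i}_kp{j}" for j in range(len(kp))]
    return np.vstack(pts), labels


def render_stereo(scene: Scene, cam_a: CameraModel,
                  cam_b: CameraModel | None = None
                  ) -> tuple[RenderOutput, RenderOutput, Correspondences]:
    """Render a two-view pair (default second elevation 75°) plus exact
    correspondences for the card corners and solid surface keypoints."""
    if cam_b is None:
        dist = float(np.linalg.norm(cam_a.centre_world))
        cam_b = CameraModel.overhead_arc(
            scene.centre, dist, 75.0, fx=cam_a.fx,
            width=cam_a.width, height=cam_a.height)
    out_a = render_depth(scene, cam_a)
    out_b = render_depth(scene, cam_b)
    world, labels = scene_keypoints_world(scene)
    uv_a = cam_a.project(world)
    uv_b = cam_b.project(world)
    keep = ((uv_a[:, 0] >= 0) & (uv_a[:, 0] <= cam_a.width - 1)
            & (uv_a[:, 1] >= 0) & (uv_a[:, 1] <= cam_a.height - 1)
            & (uv_b[:, 0] >= 0) & (uv_b[:, 0] <= cam_b.width - 1)
            & (uv_b[:, 1] >= 0) & (uv_b[:, 1] <= cam_b.height - 1))
    corr = Correspondences(uv_a[keep], uv_b[keep], world[keep],
                           [l for l, k in zip(labels, keep) if k])
    return out_a, out_b, corr


# ---------------------------------------------------------------------------
# degradation


def add_depth_noise(depth: DepthMap, sigma_mm: float, outlier_frac: float,
                    seed: int) -> DepthMap:
    """Gaussian per-pixel perturbation plus gross uniform outliers.

    The outlier count is ``round(outlier_frac * n_valid)`` — deterministic
    given the seed.  ``sigma_mm = 0`` and ``outlier_frac = 0`` return a
    bit-identical copy.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if not (0 <= outlier_frac < 1):
        raise ValueError("outlier_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = depth.values.copy()
    valid = depth.valid.copy()
    idx = np.flatnonzero(valid.ravel())
    if sigma_mm > 0 and idx.size:
        noise = rng.normal(0.0, sigma_mm, size=idx.size)
        flat = vals.ravel()
        flat[idx] = np.maximum(flat[idx] + noise, 1.0)
        vals = flat.reshape(vals.shape)
    n_out = int(round(outlier_frac * idx.size))
    if n_out > 0:
        med = float(np.median(vals.ravel()[idx]))
        pick = rng.choice(idx, size=n_out, replace=False)
        flat = vals.ravel()
        flat[pick] = rng.uniform(0.25 * med, 2.5 * med, size=n_out)
        vals = flat.reshape(vals.shape)
    return DepthMap(vals, valid)


# ---------------------------------------------------------------------------
# synthetic feeding study


@dataclass
class Participant:
    participant_id: str
    meals: list[SceneSpec]
    true_daily: dict          # kcal, cho_g, protein_g, fat_g


@dataclass
class SyntheticStudy:
    participants: list[Participant]
    reference_daily: dict[str, dict]
    seed: int
    noise_cv: float

    def truth_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"participant_id": p.participant_id, **p.true_daily}
            for p in self.participants
        ])

    def reference_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"participant_id": pid, **vals}
            for pid, vals in self.reference_daily.items()
        ])


def default_catalogue() -> list[SceneSpec]:
    """A small catalogue of meal scenes built from the bundled categories.

    Shapes approximate typical portions: slabs of meat, domed rice or
    mash, cylindrical drinks, wedge-like frustum portions.
    """
    def solo(kind, params, category, centre=(30.0, 0.0)):
        return SceneSpec(solids=(SolidSpec(kind, params, centre, category),))

    meals = [
        # steak and potatoes
        SceneSpec(solids=(
            SolidSpec("cuboid", {"width": 110, "depth": 70, "height": 22},
                      (20.0, 45.0), "beef steak"),
            SolidSpec("spherical_cap", {"sphere_radius": 70, "height": 35},
                      (40.0, -50.0), "mashed potatoes"),
        )),
        # chicken with fries
        SceneSpec(solids=(
            SolidSpec("cuboid", {"width": 90, "depth": 60, "height": 25},
                      (15.0, 50.0), "chicken breast"),
            SolidSpec("frustum", {"radius_bottom": 50, "radius_top": 38, "height": 35},
                      (40.0, -45.0), "french fries"),
        )),
        # meatballs and bread
        SceneSpec(solids=(
            SolidSpec("spherical_cap", {"sphere_radius": 32, "height": 30},
                      (0.0, 45.0), "meatball"),
            SolidSpec("cuboid", {"width": 95, "depth": 55, "height": 18},
                      (35.0, -50.0), "white bread"),
        )),
        # a glass of milk and cake
        SceneSpec(solids=(
            SolidSpec("cylinder", {"radius": 30, "height": 48},
                      (-5.0, 50.0), "whole milk"),
            SolidSpec("cuboid", {"width": 70, "depth": 55, "height": 35},
                      (40.0, -50.0), "chocolate cake"),
        )),
        solo("cylinder", {"radius": 33, "height": 45}, "orange juice"),
        solo("cylinder", {"radius": 33, "height": 50}, "tap water"),
        solo("spherical_cap", {"sphere_radius": 45, "height": 40}, "apple"),
        solo("frustum", {"radius_bottom": 45, "radius_top": 30, "height": 30},
             "boiled potatoes"),
    ]
    return meals


def generate_study(n_participants: int, meals_per_day: int = 3,
                   noise_cv: float = 0.10, seed: int = 0,
                   catalogue: list[SceneSpec] | None = None,
                   nutrient_table=None) -> SyntheticStudy:
    """Simulate a multi-participant one-day recording study.

    Each participant's meals are drawn from a scene catalogue; true daily
    totals come from the closed-form volumes and the bundled nutrient
    table.  The "dietitian recall" reference is truth times multiplicative
    log-normal noise of coefficient of variation ``noise_cv`` (mean 1), per
    nutrient and participant — recall error is proportional, not additive.
    """
    from . import nutrition

    if n_participants < 1:
        raise ValueError("need at least one participant")
    if catalogue is None:
        catalogue = default_catalogue()
    if not catalogue:
        raise ValueError("scene catalogue is empty")
    if nutrient_table is None:
        nutrient_table = nutrition.load_nutrient_table(nutrition.bundled_table_path())

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        mu = -sigma ** 2 / 2.0
    nutrients = ("kcal", "cho_g", "protein_g", "fat_g")

    participants = []
    reference = {}
    # an all-drink day with zero energy would break percentage errors
    # downstream; days are redrawn around a guaranteed energy-bearing meal
    energetic = [
        i for i, spec in enumerate(catalogue)
        if any(nutrient_table[s.fine_category].kcal_per_100g > 0
               for s in spec.solids)
    ]
    if not energetic:
        raise ValueError("catalogue contains no energy-bearing meal")

    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        picks = rng.integers(0, len(catalogue), size=meals_per_day)
        if not set(picks) & set(energetic):
            picks[0] = energetic[int(rng.integers(0, len(energetic)))]
        meals = [catalogue[j] for j in picks]
        totals = dict.fromkeys(nutrients, 0.0)
        for mspec in meals:
            scene = make_scene(mspec)
            for solid, vol in zip(scene.solids, scene.analytic_volume_mL):
                rec = nutrient_table[solid.spec.fine_category]
                _, kcal, cho, prot, fat = nutrition.item_nutrition(vol, rec)
                totals["kcal"] += kcal
                totals["cho_g"] += cho
                totals["protein_g"] += prot
                totals["fat_g"] += fat
        participants.append(Participant(pid, meals, totals))
        if noise_cv > 0:
            mult = np.exp(rng.normal(mu, sigma, size=len(nutrients)))
        else:
            mult = np.ones(len(nutrients))
        reference[pid] = {k: totals[k] * m for k, m in zip(nutrients, mult)}
    return SyntheticStudy(participants, reference, seed, noise_cv)
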
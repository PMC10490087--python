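"""Shared fixtures: small rendered scenes, tables, and a voxel oracle.

Unit tests render at 320x240 (fx = 400) to stay fast; the acceptance tests
use the full 640x480 geometry.  The voxel oracle integrates solid
membership functions written here from the shape definitions directly, so
it is independent of the package's closed forms and ray caster.
"""

from __future__ import annotations

import numpy as np
import pytest

from mealvision import nutrition, perception, scenes
from mealvision.geometry import CameraModel


def small_camera(elevation_deg: float = 90.0,
                 distance: float = 400.0) -> CameraModel:
    return CameraModel.overhead_arc(np.zeros(3), distance, elevation_deg,
                                    fx=400.0, width=320, height=240)


def full_camera(elevation_deg: float = 90.0,
                distance: float = 400.0) -> CameraModel:
    return CameraModel.overhead_arc(np.zeros(3), distance, elevation_deg,
                                    fx=800.0, width=640, height=480)


CUBOID_SPEC = scenes.SceneSpec(solids=(
    scenes.SolidSpec("cuboid", {"width": 100, "depth": 80, "height": 30},
                     (30.0, 0.0), "beef steak"),
))


@pytest.fixture(scope="session")
def cuboid_scene():
    return scenes.make_scene(CUBOID_SPEC)


@pytest.fixture(scope="session")
def cuboid_render(cuboid_scene):
    return scenes.render_depth(cuboid_scene, small_camera())


@pytest.fixture(scope="session")
def empty_scene():
    return scenes.make_scene(scenes.SceneSpec())


@pytest.fixture(scope="session")
def primary_table():
    return nutrition.load_nutrient_table(nutrition.bundled_table_path())


@pytest.fixture(scope="session")
def secondary_table():
    return nutrition.load_nutrient_table(nutrition.bundled_secondary_path())


@pytest.fixture(scope="session")
def taxonomy():
    return perception.load_taxonomy()


# ---------------------------------------------------------------------------
# independent voxel-integration oracle


def voxel_volume_mL(kind: str, params: dict, step: float = 0.5) -> float:
    """Numeric volume by midpoint voxel integration of the membership
    function, written from the shape definitions (not the package code)."""
    if kind == "cuboid":
        w, d, h = params["width"], params["depth"], params["height"]
        bx, by, bz = w / 2, d / 2, h

        def member(x, y, z):
            return (np.abs(x) <= w / 2) & (np.abs(y) <= d / 2) & (z <= h)
    elif kind == "cylinder":
        r, h = params["radius"], params["height"]
        bx = by = r
        bz = h

        def member(x, y, z):
            return (x ** 2 + y ** 2 <= r ** 2) & (z <= h)
    elif kind == "spherical_cap":
        R, h = params["sphere_radius"], params["height"]
        a = np.sqrt(h * (2 * R - h)) if h < R else R
        bx = by = a
        bz = h

        def member(x, y, z):
            return (x ** 2 + y ** 2 + (z - (h - R)) ** 2 <= R ** 2) & (z <= h)
    elif kind == "frustum":
        r1, r2, h = (params["radius_bottom"], params["radius_top"],
                     params["height"])
        bx = by = max(r1, r2)
        bz = h

        def member(x, y, z):
            return (np.hypot(x, y) <= r1 + (r2 - r1) * z / h) & (z <= h)
    else:
        raise ValueError(kind)

    xs = np.arange(-bx, bx + step, step) + step / 2
    ys = np.arange(-by, by + step, step) + step / 2
    zs = np.arange(0, bz + step, step) + step / 2
    zs = zs[zs <= bz]
    xx, yy = np.meshgrid(xs, ys)
    total = 0
    for z in zs:
        total += int(member(xx, yy, z).sum())
    return total * step ** 3 / 1000.0
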
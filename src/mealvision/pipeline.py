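"""Orchestration of the two meal-processing variants.

``process_provider`` consumes a single view plus a metric-up-to-scale depth
map from any pluggable depth provider; ``process_stereo`` consumes a
two-view pair and derives depth itself.  Both share the same tail: card
pose -> metric alignment -> per-item volume -> nutrient lookup -> meal
report.  Card failures never abort — they degrade every item to its
standard serving volume, and each cap/fallback/secondary-table event emits
exactly one structured log line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import card as card_mod
from . import nutrition, stereo, volume
from .card import CardPose, CardSpec
from .errors import AlignmentImpossible, CardNotFound, PoseUnsolvable
from .geometry import DepthMap
from .nutrition import MealItem, MealReport, NutrientRecord

log = logging.getLogger("mealvision")

__all__ = ["CardResult", "locate_card", "process_provider", "process_stereo",
           "choose_labels"]


@dataclass
class CardResult:
    found: bool
    pose: CardPose | None = None
    detection: object = None
    scale: float = 1.0


def locate_card(intensity: np.ndarray, spec: CardSpec,
                intrinsics: np.ndarray) -> CardResult:
    """Detect the card and solve its pose; a miss is a result, not an error."""
    try:
        det = card_mod.detect_card(intensity)
        pose = card_mod.estimate_pose(det, spec, intrinsics)
    except (CardNotFound, PoseUnsolvable) as exc:
        log.info("event=card_missing reason=%s", type(exc).__name__)
        return CardResult(found=False)
    return CardResult(found=True, pose=pose, detection=det)


def choose_labels(predictions, gt_labels):
    """Apply the top-5 user-selection rule when ranked predictions are
    available; otherwise the ground-truth labels are used directly."""
    from .perception import top5_select

    if predictions is None:
        return list(gt_labels)
    return [top5_select(p, gt) for p, gt in zip(predictions, gt_labels)]


def _item_report(est: volume.FoodItemEstimate, record: NutrientRecord,
                 provenance: str) -> MealItem:
    flags = {
        "card_found": est.card_found,
        "capped": est.capped,
        "fallback_serving": est.fallback_serving,
        "outliers_removed_count": est.outliers_removed_count,
        "nutrient_table": provenance,
    }
    if est.capped:
        log.info("event=capped category=%s", est.fine_category)
    if est.fallback_serving:
        log.info("event=fallback_serving category=%s", est.fine_category)
    if provenance == "secondary":
        log.info("event=secondary_table category=%s", est.fine_category)
    return MealItem.from_volume(est.fine_category, est.volume_mL, record, flags)


def _serving_lookup(primary, secondary):
    """Merged view used only for standard-serving fallback volumes."""
    merged = dict(secondary or {})
    merged.update(primary)
    return merged


def process_provider(intensity: np.ndarray, depth: DepthMap,
                     masks: list[np.ndarray], categories: list[str],
                     intrinsics: np.ndarray,
                     card_spec: CardSpec = CardSpec(),
                     rules: volume.VolumeRules = volume.VolumeRules(),
                     primary=None, secondary=None,
                     meal_label: str = "lunch") -> MealReport:
    """Single-image pipeline: card -> align -> per-item volume -> nutrients."""
    if primary is None:
        primary = nutrition.load_nutrient_table(nutrition.bundled_table_path())
    serving = _serving_lookup(primary, secondary)
    result = locate_card(intensity, card_spec, intrinsics)
    aligned = depth
    if result.found:
        try:
            card_mask = result.detection.mask(depth.shape)
            result.scale, aligned = card_mod.metric_align(depth, result.pose,
                                                          card_mask)
            # the depth under the card pins the plane down far better
            # than four projected corners can
            result.pose = card_mod.refine_pose_with_depth(
                aligned, card_mask, intrinsics, result.pose)
        except AlignmentImpossible:
            log.info("event=card_missing reason=AlignmentImpossible")
            result = CardResult(found=False)
    items = []
    for mask, category in zip(masks, categories):
        est = volume.estimate_item_volume(
            aligned, mask, result.pose if result.found else None, category,
            serving, rules, intrinsics=intrinsics)
        record, provenance = nutrition.lookup(category, primary, secondary)
        items.append(_item_report(est, record, provenance))
    return nutrition.aggregate(items, meal_label)


def process_stereo(intensity_a: np.ndarray, intensity_b: np.ndarray,
                   uv_a: np.ndarray, uv_b: np.ndarray,
                   masks_a: list[np.ndarray], categories: list[str],
                   K_a: np.ndarray, K_b: np.ndarray,
                   card_spec: CardSpec = CardSpec(),
                   rules: volume.VolumeRules = volume.VolumeRules(),
                   primary=None, secondary=None,
                   meal_label: str = "lunch",
                   block_px: int = 11, subpixel: bool = True) -> MealReport:
    """Two-view pipeline: rectify -> block match -> depth -> volumes.

    The stereo baseline is recovered from the card pose seen in both
    views; without a card in both, every item falls back to its standard
    serving.
    """
    if primary is None:
        primary = nutrition.load_nutrient_table(nutrition.bundled_table_path())
    serving = _serving_lookup(primary, secondary)
    res_a = locate_card(intensity_a, card_spec, K_a)
    res_b = locate_card(intensity_b, card_spec, K_b)
    if not (res_a.found and res_b.found):
        items = []
        for category in categories:
            est = volume.estimate_item_volume(
                None, None, None, category, serving, rules)
            record, provenance = nutrition.lookup(category, primary, secondary)
            items.append(_item_report(est, record, provenance))
        return nutrition.aggregate(items, meal_label)

    pair = stereo.rectify_pair(intensity_a, intensity_b, uv_a, uv_b, K_a, K_b)
    baseline = stereo.baseline_from_card_poses(res_a.pose, res_b.pose,
                                               card_spec, pair.R_ab,
                                               pair.t_unit)
    # search only the disparity window and image region the scene can
    # produce: depths within ~2/3 .. 1.5x of the card distance, columns
    # and rows covering the item masks
    f_new = pair.K_new[0, 0]
    depth0 = res_a.pose.centre_depth_mm
    max_disp = int(math.ceil(1.5 * f_new * baseline / depth0))
    min_disp = int(0.65 * f_new * baseline / depth0)
    h, w = intensity_a.shape
    card_mask_a = res_a.detection.mask((h, w))
    roi = stereo.roi_for_masks(pair, list(masks_a) + [card_mask_a]) \
        if masks_a else None
    disp = stereo.compute_disparity(pair, block_px=block_px,
                                    max_disp=max_disp, min_disp=min_disp,
                                    subpixel=subpixel, roi=roi)
    pts_a, uv = stereo.rectified_points_in_view_a(pair, disp, baseline, K_a)
    ui = np.round(uv).astype(int)
    inside = (ui[:, 0] >= 0) & (ui[:, 0] < w) & (ui[:, 1] >= 0) & (ui[:, 1] < h)
    pts_a, ui = pts_a[inside], ui[inside]

    # sharpen the card plane with the triangulated card-region points
    on_card = card_mask_a[ui[:, 1], ui[:, 0]]
    pose_a = card_mod.fit_plane_to_points(pts_a[on_card],
                                          fallback=res_a.pose)

    items = []
    for mask, category in zip(masks_a, categories):
        sel = np.asarray(mask, dtype=bool)[ui[:, 1], ui[:, 0]]
        record, provenance = nutrition.lookup(category, primary, secondary)
        if sel.sum() < 10:
            est = volume.estimate_item_volume(None, None, None, category,
                                              serving, rules)
        else:
            cloud = volume.PointCloud(pts_a[sel], frame="camera")
            est = volume.estimate_volume_from_cloud(cloud, pose_a,
                                                    category, serving, rules)
        items.append(_item_report(est, record, provenance))
    return nutrition.aggregate(items, meal_label)
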
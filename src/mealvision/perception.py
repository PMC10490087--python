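"""Food taxonomy, recognition contracts, and segmentation/recognition metrics.

Real deployments plug GPU-trained segmentation and recognition networks
into the pipeline; those models are external to this package.  What lives
here is everything around them: the three-level food taxonomy
(coarse/middle/fine, e.g. meat / red meat / meatball), the ranked-
prediction contract, the "user picks the true class if it appears in the
top five" selection rule, IoU and top-k accuracy metrics, a trivial
index-channel segmenter for synthetic renders, and an oracle classifier
that places the true label at a configurable rank for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import UnknownCategory

__all__ = [
    "FoodTaxonomy", "Prediction", "load_taxonomy", "bundled_taxonomy_path",
    "roll_up", "baseline_segment", "top5_select", "iou", "top_k_accuracy",
    "OracleClassifier",
]


@dataclass
class FoodTaxonomy:
    """A tree of food labels: every fine label has exactly one middle and
    one coarse ancestor."""
    fine_to_middle: dict[str, str]
    middle_to_coarse: dict[str, str]

    @property
    def fine_labels(self) -> list[str]:
        return sorted(self.fine_to_middle)

    @property
    def middle_labels(self) -> list[str]:
        return sorted(set(self.fine_to_middle.values()))

    @property
    def coarse_labels(self) -> list[str]:
        return sorted(set(self.middle_to_coarse.values()))

    def level_sizes(self) -> tuple[int, int, int]:
        """(coarse, middle, fine) label counts; the full production
        instance uses 18/34/301, the bundled miniature 5/8/20."""
        return (len(self.coarse_labels), len(self.middle_labels),
                len(self.fine_labels))

    def ancestor(self, fine_label: str, level: str) -> str:
        if level == "fine":
            if fine_label not in self.fine_to_middle:
                raise UnknownCategory(fine_label)
            return fine_label
        mid, coarse = roll_up(fine_label, self)
        return {"middle": mid, "coarse": coarse}[level]


def bundled_taxonomy_path() -> str:
    return str(resources.files("mealvision.data") / "taxonomy_mini.tsv")


def load_taxonomy(path: str | None = None) -> FoodTaxonomy:
    """Load a 3-column TSV (fine, middle, coarse) taxonomy.

    Rejects a fine label mapped to more than one ancestor chain, which
    would make roll-up one-to-many.
    """
    if path is None:
        path = bundled_taxonomy_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"fine", "middle", "coarse"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxonomy file must have columns {sorted(required)}")
    if df["fine"].duplicated().any():
        dup = df.loc[df["fine"].duplicated(), "fine"].iloc[0]
        raise ValueError(f"fine label {dup!r} appears more than once")
    mid_coarse: dict[str, str] = {}
    for _, row in df.iterrows():
        prev = mid_coarse.get(row["middle"])
        if prev is not None and prev != row["coarse"]:
            raise ValueError(
                f"middle label {row['middle']!r} has two coarse parents")
        mid_coarse[row["middle"]] = row["coarse"]
    return FoodTaxonomy(dict(zip(df["fine"], df["middle"])), mid_coarse)


def roll_up(fine_label: str, taxonomy: FoodTaxonomy) -> tuple[str, str]:
    """Unique (middle, coarse) ancestor chain of a fine label."""
    try:
        middle = taxonomy.fine_to_middle[fine_label]
    except KeyError:
        raise UnknownCategory(f"unknown fine label {fine_label!r}") from None
    return middle, taxonomy.middle_to_coarse[middle]


# ---------------------------------------------------------------------------
# predictions


@dataclass
class Prediction:
    """Descending ranked (fine label, score) pairs, no duplicate labels."""
    ranked_fine: list[tuple[str, float]]

    def __post_init__(self):
        labels = [l for l, _ in self.ranked_fine]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in ranking")
        scores = [s for _, s in self.ranked_fine]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in self.ranked_fine]


class OracleClassifier:
    """Test-double recogniser: the true label appears at a fixed rank.

    Distractor labels are drawn deterministically from the taxonomy, so
    end-to-end runs are reproducible without any trained network.
    """

    def __init__(self, taxonomy: FoodTaxonomy, gt_rank: int = 1,
                 n_ranked: int = 5):
        if gt_rank < 1:
            raise ValueError("gt_rank must be >= 1")
        self.taxonomy = taxonomy
        self.gt_rank = gt_rank
        self.n_ranked = max(n_ranked, gt_rank)

    def predict(self, true_fine: str) -> Prediction:
        if true_fine not in self.taxonomy.fine_to_middle:
            raise UnknownCategory(true_fine)
        others = [l for l in self.taxonomy.fine_labels if l != true_fine]
        ranked = others[: self.n_ranked - 1]
        ranked.insert(self.gt_rank - 1, true_fine)
        scores = np.linspace(1.0, 0.5, len(ranked))
        return Prediction(list(zip(ranked, scores)))


def top5_select(pred: Prediction, gt_fine: str) -> str:
    """User-in-the-loop selection: the true class is chosen whenever it is
    shown among the top five suggestions, otherwise the top-1 stands."""
    if not pred.ranked_fine:
        raise ValueError("empty ranking")
    if gt_fine in pred.labels[:5]:
        return gt_fine
    return pred.labels[0]


# ---------------------------------------------------------------------------
# metrics


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 when both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def top_k_accuracy(predictions: list[Prediction], gt_labels: list[str],
                   k: int, level: str, taxonomy: FoodTaxonomy) -> float:
    """Percentage of items whose true label (rolled up to ``level``) is
    among the first ``k`` *distinct* rolled-up predicted labels.

    Fine predictions sharing an ancestor collapse to one slot before
    counting ``k``, so coarse/middle accuracy reflects distinct candidate
    categories shown, not raw ranking length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(predictions) != len(gt_labels):
        raise ValueError("prediction and label lists differ in length")
    if not predictions:
        raise ValueError("empty evaluation set")
    hits = 0
    for pred, gt in zip(predictions, gt_labels):
        gt_up = taxonomy.ancestor(gt, level)
        seen: list[str] = []
        for lab in pred.labels:
            up = taxonomy.ancestor(lab, level)
            if up not in seen:
                seen.append(up)
            if len(seen) >= k:
                break
        hits += gt_up in seen[:k]
    return 100.0 * hits / len(predictions)


# ---------------------------------------------------------------------------
# baseline segmentation


def baseline_segment(index_image: np.ndarray) -> list[np.ndarray]:
    """Masks from a synthetic render's item-index channel.

    Connected-component labelling runs per index value, so touching items
    with distinct indices stay separated.  Returns one boolean mask per
    item index (1..max), pairwise disjoint.
    """
    from scipy import ndimage

    idx = np.asarray(index_image)
    masks = []
    for value in range(1, int(idx.max()) + 1):
        region = idx == value
        if not region.any():
            continue
        labels, n = ndimage.label(region)
        # keep all components of this item as one mask
        masks.append(labels > 0)
    return masks
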
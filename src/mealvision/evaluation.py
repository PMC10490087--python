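"""Study-level agreement statistics: MAPE, Bland–Altman, method comparison.

Daily intake estimates are compared against per-participant reference
intakes (in the original study, dietitian 24 h recalls).  Because the
reference covers the whole day, the unit of analysis is the participant-
day: per participant an absolute percentage error per nutrient, summarised
by its mean and sample standard deviation; agreement is assessed the
Bland–Altman way (difference vs mean, limits of agreement at
mean ± 1.96 sd); two methods are compared by Welch's unpaired t-test on
their per-participant APE lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ParticipantDay", "AgreementStats", "mape", "bland_altman",
           "compare_methods", "NUTRIENTS"]

NUTRIENTS = ("kcal", "cho_g", "protein_g", "fat_g")


@dataclass(frozen=True)
class ParticipantDay:
    participant_id: str
    estimated: dict    # kcal, cho_g, protein_g, fat_g
    reference: dict


@dataclass(frozen=True)
class AgreementStats:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: tuple      # (mean of pair, difference) per participant

    def __post_init__(self):
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean")


def _ape_list(days: list[ParticipantDay], nutrient: str) -> np.ndarray:
    apes = []
    for d in days:
        ref = float(d.reference[nutrient])
        if ref <= 0:
            raise ValueError(
                f"participant {d.participant_id}: non-positive reference "
                f"{nutrient} cannot enter a percentage error")
        apes.append(100.0 * abs(float(d.estimated[nutrient]) - ref) / ref)
    return np.asarray(apes)


def mape(days: list[ParticipantDay], nutrient: str) -> tuple[float, float]:
    """Mean and sample sd of per-participant absolute percentage errors.

    A single participant has no dispersion: sd is reported as 0 with a
    warning rather than NaN so tiny fixtures stay runnable.
    """
    if not days:
        raise ValueError("need at least one participant")
    apes = _ape_list(days, nutrient)
    if len(apes) == 1:
        warnings.warn("single participant: sd reported as 0", stacklevel=2)
        return float(apes[0]), 0.0
    return float(apes.mean()), float(apes.std(ddof=1))


def bland_altman(days: list[ParticipantDay], nutrient: str) -> AgreementStats:
    """Agreement between estimate and reference for one nutrient.

    Differences are estimate − reference; limits of agreement are
    mean ± 1.96 sample sd (the 95% convention).
    """
    if len(days) < 2:
        raise ValueError("Bland–Altman needs at least two participants")
    est = np.array([float(d.estimated[nutrient]) for d in days])
    ref = np.array([float(d.reference[nutrient]) for d in days])
    diff = est - ref
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pts = tuple(zip(((est + ref) / 2.0).tolist(), diff.tolist()))
    return AgreementStats(mean_diff, sd, mean_diff - 1.96 * sd,
                          mean_diff + 1.96 * sd, pts)


def compare_methods(ape_a: list[float], ape_b: list[float]
                    ) -> tuple[float, float]:
    """Welch two-sample t-test on two methods' per-participant APEs.

    Degenerate input (both samples constant and equal) is reported as
    ``t = 0, p = 1`` instead of NaN.
    """
    a = np.asarray(ape_a, dtype=float)
    b = np.asarray(ape_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bland_altman_plot(stats_by_method: dict[str, AgreementStats],
                      nutrient: str, out_path: str) -> None:
    """Difference-vs-mean plot with limits of agreement, one colour per
    method; written to ``out_path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colours = ["tab:blue", "tab:green", "tab:orange"]
    for (name, st), col in zip(stats_by_method.items(), colours):
        xs = [p[0] for p in st.points]
        ys = [p[1] for p in st.points]
        ax.scatter(xs, ys, s=18, color=col, label=name, alpha=0.7)
        ax.axhline(st.mean_diff, color=col, lw=1.5)
        ax.axhline(st.loa_low, color=col, lw=1, ls="--")
        ax.axhline(st.loa_high, color=col, lw=1, ls="--")
    ax.axhline(0.0, color="red", lw=1, ls="--")
    ax.set_xlabel(f"mean of estimate and reference ({nutrient})")
    ax.set_ylabel("estimate − reference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
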
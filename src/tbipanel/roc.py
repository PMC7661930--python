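"""Empirical ROC curves, partial AUC over a sensitivity band, and bootstrap CIs.

For outcome prognostication the clinically relevant corner of the ROC plane
is the high-sensitivity region: a rule-out tool must miss almost no patient
with an unfavorable outcome.  The summary used throughout this package is
therefore the *partial* area under the empirical ROC curve restricted to the
90-100% sensitivity band, expressed as a fraction of the unit square (so its
ceiling is 0.10, printed as 10%).  Specificity is integrated as a function of
sensitivity with trapezoidal (linear) interpolation between attained
operating points and exact partial trapezoids where the band boundary cuts a
segment; no McClish normalisation is applied.

Closed-form anchors: a perfect classifier attains pAUC = band width (0.10 on
the 90-100% band); the uninformative limit (diagonal ROC) is
``∫_0.9^1 (1-s) ds = 0.005``.

Confidence intervals are percentile intervals from a stratified bootstrap
(resampling within outcome classes, so every replicate keeps both classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._formatting import round_half_up

__all__ = [
    "DIRECTIONS",
    "RocCurve",
    "BandStatistic",
    "build_roc",
    "pauc_sensitivity_band",
    "operating_point_at_sensitivity",
    "sens_spec_from_counts",
    "bootstrap_ci",
]

DIRECTIONS = ("positive_if_greater", "positive_if_less")


class DegenerateCohortError(ValueError):
    """Raised when a cohort contains only one outcome class."""


@dataclass(frozen=True)
class RocCurve:
    """An empirical ROC curve as ordered operating points.

    Points are ordered by non-decreasing sensitivity (hence non-increasing
    specificity) and always include the trivial endpoints (sens 0, spec 1)
    and (sens 1, spec 0).  Every attained sensitivity is k/n_pos and every
    specificity j/n_neg for integers k, j.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float, float]]:
        """(threshold, sensitivity, specificity) triples."""
        return list(zip(self.thresholds, self.sensitivity, self.specificity))


@dataclass(frozen=True)
class BandStatistic:
    """A statistic evaluated on a sensitivity band, with its bootstrap CI."""

    value: float
    ci_low: float
    ci_high: float
    band: tuple[float, float] = (0.90, 1.00)


def build_roc(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "positive_if_greater",
) -> RocCurve:
    """Construct the empirical ROC of a score against binary outcome labels.

    Parameters
    ----------
    scores : array-like of float
        Marker values; must be finite.
    labels : array-like of {0, 1}
        1 = positive class (here: unfavorable outcome).
    direction : str
        ``"positive_if_greater"`` predicts positive when score > threshold
        (strict); ``"positive_if_less"`` mirrors the comparison, for markers
        whose *low* values mark the positive class (e.g. IL-10 in panels).

    Tied scores collapse to a single operating point.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateCohortError(
            f"degenerate cohort: need both classes, got {n_pos} positive / {n_neg} negative"
        )

    # Orient so that larger oriented score = more positive; positive iff
    # oriented score strictly exceeds the oriented threshold.
    oriented = s if direction == "positive_if_greater" else -s
    order = np.argsort(-oriented, kind="stable")
    ys = y[order]
    os_ = oriented[order]
    block_starts = np.concatenate(([True], np.diff(os_) != 0))
    block_ends = np.nonzero(np.concatenate((block_starts[1:], [True])))[0]
    # With strict ">", threshold = a block's value classifies positive
    # exactly the strictly larger blocks: pair each distinct value with the
    # cumulative counts of the blocks before it, and close with -inf
    # (everyone positive).
    cum_pos = np.cumsum(ys == 1)
    cum_neg = np.cumsum(ys == 0)
    tp = np.concatenate(([0], cum_pos[block_ends]))
    fp = np.concatenate(([0], cum_neg[block_ends]))
    thr_oriented = np.concatenate((os_[np.nonzero(block_starts)[0]], [-np.inf]))
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    thresholds = thr_oriented if direction == "positive_if_greater" else -thr_oriented
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def pauc_sensitivity_band(
    curve: RocCurve, band: tuple[float, float] = (0.90, 1.00)
) -> float:
    """Integrate specificity over a sensitivity band of the empirical ROC.

    Trapezoidal interpolation between adjacent operating points, with exact
    partial trapezoids where the band edges cut a segment.  The result is on
    the unit-square scale (maximum = band width); multiply by 100 to report
    as a percentage.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"band must satisfy 0 <= low < high <= 1, got {band}")
    s = curve.sensitivity
    p = curve.specificity
    area = 0.0
    for i in range(len(s) - 1):
        s0, s1 = s[i], s[i + 1]
        if s1 <= lo or s0 >= hi or s1 == s0:
            continue
        a, b = max(s0, lo), min(s1, hi)
        # linear interpolation of specificity inside the segment
        pa = p[i] + (p[i + 1] - p[i]) * (a - s0) / (s1 - s0)
        pb = p[i] + (p[i + 1] - p[i]) * (b - s0) / (s1 - s0)
        area += (b - a) * (pa + pb) / 2.0
    return float(area)


def operating_point_at_sensitivity(
    curve: RocCurve, min_sens: float = 0.90
) -> tuple[float, float, float]:
    """Best attained operating point subject to sensitivity >= `min_sens`.

    Among attained points with sensitivity at or above the floor, returns
    the one with maximal specificity; ties broken toward higher sensitivity,
    then toward the more extreme (more conservative) threshold.  The
    (sens 1, spec 0) endpoint always qualifies, so a result is guaranteed.
    """
    if not (0.0 < min_sens <= 1.0):
        raise ValueError("min_sens must lie in (0, 1]")
    eligible = np.nonzero(curve.sensitivity >= min_sens - 1e-12)[0]
    sign = 1.0 if curve.direction == "positive_if_greater" else -1.0
    best = max(
        eligible,
        key=lambda i: (
            curve.specificity[i],
            curve.sensitivity[i],
            sign * curve.thresholds[i],
        ),
    )
    return (
        float(curve.thresholds[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )


def sens_spec_from_counts(
    tp: int, fn: int, tn: int, fp: int
) -> tuple[float, float]:
    """Sensitivity and specificity in percent from confusion counts.

    Returns percentages rounded half-up to one decimal, as used in report
    tables (e.g. 11 true negatives out of 49 -> specificity 22.4%).
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("empty margin: need at least one positive and one negative")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return round_half_up(sens, 1), round_half_up(spec, 1)


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI of a score/label statistic.

    Resampling is performed with replacement *within* each outcome class,
    preserving the class sizes, so no replicate can lose a class.  The
    interval is the (alpha/2, 1-alpha/2) percentile of the replicate
    distribution; reproducible under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateCohortError("both classes required for stratified bootstrap")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            (
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            )
        )
        reps[b] = statistic(s[idx], y[idx])
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
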
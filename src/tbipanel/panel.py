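"""Threshold-panel construction: combine per-marker cut-offs into a classifier.

A *panel* is a small set (1-3) of per-marker threshold rules, each with a
positivity direction (strictly greater / strictly less than its cut-off),
combined through a minimum-number-of-positive-rules decision: a patient is
classified positive (predicted unfavorable outcome) when at least
``min_positive`` of the rules fire.  The integer count of satisfied rules is
itself an ordinal score, so a panel has its own ROC (cuts at
min_positive = 1..size) and hence its own partial AUC.

Panel *optimization* is an exhaustive, deterministic search over marker
subsets, per-marker candidate thresholds, both directions and every
min_positive cut, constrained to sensitivity >= a floor (default 90%) and
ranked by specificity, then partial AUC, then parsimony, then a fixed
lexicographic order.  The rationale for the objective ordering is that at a
fixed high-sensitivity working point the clinically meaningful gain of a
panel over a single marker is specificity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import roc as _roc
from .roc import DegenerateCohortError, DIRECTIONS

__all__ = [
    "MarkerRule",
    "PanelDefinition",
    "PanelPerformance",
    "panel_score",
    "panel_classify",
    "evaluate_panel",
    "candidate_thresholds",
    "optimize_panel",
]

logger = logging.getLogger(__name__)

_BAND = (0.90, 1.00)


@dataclass(frozen=True)
class MarkerRule:
    """One per-marker threshold rule with a strict positivity direction."""

    marker: str
    threshold: float
    direction: str = "positive_if_greater"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def satisfied(self, value: float) -> bool:
        if self.direction == "positive_if_greater":
            return value > self.threshold
        return value < self.threshold

    def __str__(self) -> str:
        op = ">" if self.direction == "positive_if_greater" else "<"
        return f"{self.marker} ({op}{self.threshold:g})"


@dataclass(frozen=True)
class PanelDefinition:
    """A set of 1-3 marker rules plus the min-positive-count decision cut."""

    rules: tuple[MarkerRule, ...]
    min_positive: int = 1

    def __post_init__(self) -> None:
        rules = tuple(self.rules)
        object.__setattr__(self, "rules", rules)
        if not 1 <= len(rules) <= 3:
            raise ValueError("a panel holds between 1 and 3 rules")
        names = [r.marker for r in rules]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker in panel: {names}")
        if not 1 <= self.min_positive <= len(rules):
            raise ValueError(
                f"min_positive must lie in [1, {len(rules)}], got {self.min_positive}"
            )

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(r.marker for r in self.rules)

    def to_dict(self) -> dict:
        return {
            "rules": [
                {"marker": r.marker, "threshold": r.threshold, "direction": r.direction}
                for r in self.rules
            ],
            "min_positive": self.min_positive,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelDefinition":
        return cls(
            rules=tuple(MarkerRule(**r) for r in d["rules"]),
            min_positive=int(d["min_positive"]),
        )

    def __str__(self) -> str:
        return " + ".join(str(r) for r in self.rules)


@dataclass(frozen=True)
class PanelPerformance:
    """Performance of one panel on one cohort.

    Fractions are on the 0-1 scale; ``pauc`` is the partial AUC over the
    90-100% sensitivity band of the panel-count ROC (ceiling 0.10).
    ``constraint_met`` is False when the sensitivity floor could not be
    attained and the reported panel maximizes sensitivity instead.
    """

    pauc: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    pauc_ci: tuple[float, float] | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    n_excluded: int = 0
    constraint_met: bool = True

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def panel_score(panel: PanelDefinition, record: Mapping[str, float]) -> int:
    """Number of panel rules satisfied by one patient record (0..size)."""
    score = 0
    for rule in panel.rules:
        value = record[rule.marker]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"missing value for panel marker {rule.marker!r}; "
                "records with missing panel markers must be excluded upstream"
            )
        score += rule.satisfied(float(value))
    return score


def panel_classify(panel: PanelDefinition, record: Mapping[str, float]) -> bool:
    """Positive iff at least `min_positive` rules fire (boundary inclusive)."""
    return panel_score(panel, record) >= panel.min_positive


def _panel_counts(panel: PanelDefinition, cohort: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(cohort), dtype=np.int64)
    for rule in panel.rules:
        v = cohort[rule.marker].to_numpy(dtype=float)
        if rule.direction == "positive_if_greater":
            counts += v > rule.threshold
        else:
            counts += v < rule.threshold
    return counts


def _resolve_labels(cohort: pd.DataFrame, outcome) -> np.ndarray:
    if isinstance(outcome, str):
        return cohort[outcome].to_numpy(dtype=int)
    return np.asarray(outcome, dtype=int)


def evaluate_panel(
    panel: PanelDefinition,
    cohort: pd.DataFrame,
    outcome_labels,
    *,
    band: tuple[float, float] = _BAND,
    n_boot: int = 2000,
    seed: int = 0,
    with_ci: bool = True,
    constraint_met: bool = True,
) -> PanelPerformance:
    """Evaluate a fixed panel on a cohort.

    Records missing any panel marker are excluded listwise (count logged).
    The panel's ROC is built from the integer count of satisfied rules;
    the partial AUC is taken over `band`; sensitivity/specificity are
    evaluated at the panel's own ``min_positive`` cut.  CIs are percentile
    intervals from a stratified bootstrap of the panel counts.
    """
    y_all = _resolve_labels(cohort, outcome_labels)
    keep = ~cohort.loc[:, list(panel.markers)].isna().any(axis=1).to_numpy()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "evaluate_panel: excluded %d records with missing values in %s",
            n_excluded,
            panel.markers,
        )
    sub = cohort.loc[keep]
    y = y_all[keep]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise DegenerateCohortError("cohort must retain both outcome classes")
    counts = _panel_counts(panel, sub)

    curve = _roc.build_roc(counts, y, "positive_if_greater")
    pauc = _roc.pauc_sensitivity_band(curve, band)
    pred = counts >= panel.min_positive
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)

    pauc_ci = sens_ci = spec_ci = None
    if with_ci:
        k = panel.min_positive

        def stat_pauc(s, lab):
            return _roc.pauc_sensitivity_band(
                _roc.build_roc(s, lab, "positive_if_greater"), band
            )

        def stat_sens(s, lab):
            return float(np.mean(s[lab == 1] >= k))

        def stat_spec(s, lab):
            return float(np.mean(s[lab == 0] < k))

        pauc_ci = _roc.bootstrap_ci(counts, y, stat_pauc, n_boot=n_boot, seed=seed)
        sens_ci = _roc.bootstrap_ci(counts, y, stat_sens, n_boot=n_boot, seed=seed)
        spec_ci = _roc.bootstrap_ci(counts, y, stat_spec, n_boot=n_boot, seed=seed)

    return PanelPerformance(
        pauc=pauc,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        pauc_ci=pauc_ci,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        n_excluded=n_excluded,
        constraint_met=constraint_met,
    )


def candidate_thresholds(
    values: Sequence[float],
    strategy: str = "midpoints",
    grid_size: int = 19,
) -> list[float]:
    """Candidate cut-offs for one marker.

    ``"midpoints"`` returns the midpoints of consecutive distinct sorted
    values (the exhaustive grid: every achievable dichotomy).  ``"quantiles"``
    returns `grid_size` equally spaced quantile cuts (grid_size=19 gives
    ventile boundaries), the economical grid for larger cohorts.  Both are
    deduplicated and sorted; a constant marker yields an empty list.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    distinct = np.unique(v)
    if distinct.size < 2:
        logger.info("candidate_thresholds: marker constant, no usable cut-offs")
        return []
    if strategy == "midpoints":
        cuts = (distinct[:-1] + distinct[1:]) / 2.0
    elif strategy == "quantiles":
        if grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        q = np.arange(1, grid_size + 1) / (grid_size + 1)
        cuts = np.quantile(v, q)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return sorted(set(float(c) for c in cuts))


def _rule_grid(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    strategy: str,
    grid_size: int,
) -> dict[str, list[MarkerRule]]:
    """Per-marker rule lists (every candidate threshold x both directions)."""
    grids: dict[str, list[MarkerRule]] = {}
    for m in markers:
        cuts = candidate_thresholds(cohort[m].to_numpy(), strategy, grid_size)
        rules = [
            MarkerRule(m, t, d)
            for t in cuts
            for d in ("positive_if_greater", "positive_if_less")
        ]
        if rules:
            grids[m] = rules
        else:
            logger.warning("optimize_panel: marker %r has no usable cut-offs", m)
    return grids


def _sens_spec_grids(
    indicator_blocks: list[np.ndarray], y: np.ndarray, min_positive: int
):
    """Vectorised sensitivity/specificity over the cartesian rule grid.

    Each block is an (n, r_i) boolean indicator matrix; the result arrays
    have shape (r_1, ..., r_k)."""
    pos = y == 1
    neg = ~pos
    k = len(indicator_blocks)
    shape = [b.shape[1] for b in indicator_blocks]
    counts_pos = np.zeros((int(pos.sum()), *([1] * k)), dtype=np.int8)
    counts_neg = np.zeros((int(neg.sum()), *([1] * k)), dtype=np.int8)
    for axis, block in enumerate(indicator_blocks):
        sl = [None] * (k + 1)
        sl[0] = slice(None)
        sl[axis + 1] = slice(None)
        counts_pos = counts_pos + block[pos][tuple(sl)]
        counts_neg = counts_neg + block[neg][tuple(sl)]
    sens = (counts_pos >= min_positive).mean(axis=0)
    spec = (counts_neg < min_positive).mean(axis=0)
    return sens.reshape(shape), spec.reshape(shape)


def optimize_panel(
    cohort: pd.DataFrame,
    outcome_labels,
    markers: Sequence[str],
    max_size: int = 3,
    min_sens: float = 0.90,
    strategy: str = "quantiles",
    grid_size: int = 19,
    seed: int = 0,
    *,
    band: tuple[float, float] = _BAND,
    n_boot: int = 2000,
    with_ci: bool = True,
    engine: str = "exhaustive",
) -> tuple[PanelDefinition, PanelPerformance]:
    """Search panels maximizing specificity subject to sensitivity >= floor.

    Exhaustive and deterministic over every marker subset of size <=
    `max_size`, per-marker candidate thresholds, both directions, and every
    ``min_positive`` cut.  Feasible panels attain sensitivity >= `min_sens`;
    among them the winner maximizes specificity, ties broken by higher
    partial AUC, then smaller panel, then lexicographic order of (marker
    names, thresholds, directions, min_positive).  If nothing is feasible,
    the sensitivity-maximizing panel is returned with
    ``constraint_met=False``.  `seed` seeds only the bootstrap CIs of the
    returned performance; the search itself is deterministic.

    ``engine="greedy"`` is a heuristic forward search for larger marker
    pools: it grows the panel one marker at a time, keeping the best
    extension at each step, and does not guarantee the optimum.
    """
    if max_size not in (1, 2, 3):
        raise ValueError("max_size must be 1, 2 or 3")
    missing = [m for m in markers if m not in cohort.columns]
    if missing:
        raise KeyError(f"markers not in cohort: {missing}")
    y_all = _resolve_labels(cohort, outcome_labels)
    keep = ~cohort.loc[:, list(markers)].isna().any(axis=1).to_numpy()
    if (~keep).sum():
        logger.info(
            "optimize_panel: excluded %d records missing candidate markers",
            int((~keep).sum()),
        )
    sub = cohort.loc[keep].reset_index(drop=True)
    y = y_all[keep]
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise DegenerateCohortError("cohort must contain both outcome classes")

    grids = _rule_grid(sub, sorted(markers), strategy, grid_size)
    usable = sorted(grids)
    if not usable:
        raise ValueError("no marker has usable cut-offs")
    indicators = {
        m: np.column_stack([
            (sub[m].to_numpy(dtype=float) > r.threshold)
            if r.direction == "positive_if_greater"
            else (sub[m].to_numpy(dtype=float) < r.threshold)
            for r in grids[m]
        ])
        for m in usable
    }

    if engine == "greedy":
        subsets = _greedy_subsets(sub, y, usable, indicators, grids, max_size, min_sens)
    elif engine == "exhaustive":
        subsets = [
            c
            for k in range(1, max_size + 1)
            for c in itertools.combinations(usable, k)
        ]
    else:
        raise ValueError(f"unknown engine {engine!r}")

    best_spec = -1.0
    tied: list[tuple[tuple[str, ...], tuple[int, ...], int]] = []
    best_sens = -1.0
    fallback: tuple[tuple[str, ...], tuple[int, ...], int] | None = None
    fallback_spec = -1.0

    for subset in subsets:
        blocks = [indicators[m] for m in subset]
        for min_positive in range(1, len(subset) + 1):
            sens, spec = _sens_spec_grids(blocks, y, min_positive)
            feasible = sens >= min_sens - 1e-12
            if feasible.any():
                m_spec = spec[feasible].max()
                if m_spec > best_spec + 1e-15:
                    best_spec = m_spec
                    tied = []
                if abs(m_spec - best_spec) <= 1e-15:
                    hit = feasible & (np.abs(spec - best_spec) <= 1e-15)
                    for idx in np.argwhere(hit):
                        tied.append((subset, tuple(int(i) for i in idx), min_positive))
            # fallback tracking for the infeasible case
            m_sens = sens.max()
            if m_sens > best_sens + 1e-15 or (
                abs(m_sens - best_sens) <= 1e-15
                and spec[np.abs(sens - m_sens) <= 1e-15].max() > fallback_spec + 1e-15
            ):
                best_sens = max(best_sens, m_sens)
                at = (np.abs(sens - best_sens) <= 1e-15)
                fallback_spec = spec[at].max()
                pick = np.argwhere(at & (np.abs(spec - fallback_spec) <= 1e-15))[0]
                fallback = (subset, tuple(int(i) for i in pick), min_positive)

    constraint_met = bool(tied)
    if not constraint_met:
        logger.warning(
            "optimize_panel: sensitivity floor %.2f unattainable; "
            "returning sensitivity-maximizing panel",
            min_sens,
        )
        assert fallback is not None
        tied = [fallback]

    def build(entry) -> PanelDefinition:
        subset, idx, min_positive = entry
        rules = tuple(grids[m][i] for m, i in zip(subset, idx))
        return PanelDefinition(rules=rules, min_positive=min_positive)

    def rank_key(entry):
        panel = build(entry)
        counts = _panel_counts(panel, sub)
        pauc = _roc.pauc_sensitivity_band(
            _roc.build_roc(counts, y, "positive_if_greater"), band
        )
        lex = (
            panel.markers,
            tuple(r.threshold for r in panel.rules),
            tuple(r.direction for r in panel.rules),
            panel.min_positive,
        )
        return (-pauc, len(panel.rules), lex)

    winner = build(min(tied, key=rank_key))
    perf = evaluate_panel(
        winner,
        sub,
        y,
        band=band,
        n_boot=n_boot,
        seed=seed,
        with_ci=with_ci,
        constraint_met=constraint_met,
    )
    return winner, perf


def _greedy_subsets(sub, y, usable, indicators, grids, max_size, min_sens):
    """Forward-selection subset path (heuristic, for large marker pools)."""

    def subset_score(subset):
        best = (-1.0, -1.0)
        blocks = [indicators[m] for m in subset]
        for mp in range(1, len(subset) + 1):
            sens, spec = _sens_spec_grids(blocks, y, mp)
            feas = sens >= min_sens - 1e-12
            if feas.any():
                best = max(best, (1.0, float(spec[feas].max())))
            else:
                best = max(best, (0.0, float(sens.max())))
        return best

    chosen: list[str] = []
    path: list[tuple[str, ...]] = []
    for _ in range(max_size):
        candidates = [m for m in usable if m not in chosen]
        if not candidates:
            break
        nxt = max(candidates, key=lambda m: subset_score(tuple(sorted(chosen + [m]))))
        chosen.append(nxt)
        path.append(tuple(sorted(chosen)))
    return path
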
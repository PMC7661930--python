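"""Report generators: single-marker tables, baseline-vs-panel tables, and
the full analysis report.

Outcome dichotomies are fixed in one place: *favorable* recovery is GOSE
5-8 (positive class = unfavorable, GOSE 1-4) and *complete* recovery is
GOSE 8 (positive class = incomplete, GOSE 1-7).  All percentages carry the
confusion counts they were computed from, so every table row is
re-derivable from its own stored counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._formatting import fmt_ci, fmt_pct
from .panel import evaluate_panel, optimize_panel, PanelDefinition
from .roc import (
    build_roc,
    bootstrap_ci,
    operating_point_at_sensitivity,
    pauc_sensitivity_band,
)
from .simulate import MARKER_COLUMNS
from .stats import comparisons_to_frame, summarize_cohort

__all__ = [
    "DICHOTOMIES",
    "outcome_labels",
    "run_single_marker_analysis",
    "run_panel_analysis",
    "run_full_report",
    "AnalysisReport",
]

logger = logging.getLogger(__name__)

_BAND = (0.90, 1.00)

#: dichotomy -> column whose *False* level is the positive (adverse) class
DICHOTOMIES = {
    "favorable_vs_unfavorable": "outcome_favorable",
    "complete_vs_incomplete": "outcome_complete",
}


def outcome_labels(cohort: pd.DataFrame, dichotomy: str) -> np.ndarray:
    """1 = adverse class (unfavorable, or incomplete recovery)."""
    if dichotomy not in DICHOTOMIES:
        raise ValueError(f"dichotomy must be one of {sorted(DICHOTOMIES)}")
    return (~cohort[DICHOTOMIES[dichotomy]].astype(bool)).to_numpy(dtype=int)


def run_single_marker_analysis(
    cohort: pd.DataFrame,
    dichotomy: str = "favorable_vs_unfavorable",
    min_sens: float = 0.90,
    markers: Sequence[str] | None = None,
    *,
    band: tuple[float, float] = _BAND,
    n_boot: int = 2000,
    seed: int = 0,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Individual marker performance table, sorted by partial AUC.

    Per marker: the operating point with maximal specificity subject to
    sensitivity >= `min_sens`, the partial AUC over the 90-100% sensitivity
    band, and stratified-bootstrap CIs.  A marker that cannot attain the
    floor except at zero specificity is reported with threshold "–"
    (specificity 0%, sensitivity 100%).
    """
    if markers is None:
        markers = [m for m in (*MARKER_COLUMNS, "hcts_sum") if m in cohort.columns]
    missing = [m for m in markers if m not in cohort.columns]
    if missing:
        raise KeyError(f"marker column(s) not in cohort: {missing}")
    y = outcome_labels(cohort, dichotomy)
    rows = []
    for marker in markers:
        vals = cohort[marker].to_numpy(dtype=float)
        keep = ~np.isnan(vals)
        v, yy = vals[keep], y[keep]
        curve = build_roc(v, yy, "positive_if_greater")
        thr, sens, spec = operating_point_at_sensitivity(curve, min_sens)
        pauc = pauc_sensitivity_band(curve, band)
        pred = v > thr
        tp = int(np.sum(pred & (yy == 1)))
        fp = int(np.sum(pred & (yy == 0)))
        tn = int(np.sum(~pred & (yy == 0)))
        fn = int(np.sum(~pred & (yy == 1)))
        ci = {}
        if with_ci:
            ci["pauc"] = bootstrap_ci(
                v, yy,
                lambda s, l: pauc_sensitivity_band(build_roc(s, l, "positive_if_greater"), band),
                n_boot=n_boot, seed=seed,
            )
            ci["spec"] = bootstrap_ci(
                v, yy,
                lambda s, l: operating_point_at_sensitivity(
                    build_roc(s, l, "positive_if_greater"), min_sens)[2],
                n_boot=n_boot, seed=seed,
            )
            ci["sens"] = bootstrap_ci(
                v, yy,
                lambda s, l: operating_point_at_sensitivity(
                    build_roc(s, l, "positive_if_greater"), min_sens)[1],
                n_boot=n_boot, seed=seed,
            )
        attainable = spec > 0.0
        rows.append(
            {
                "marker": marker,
                "threshold": f"{thr:g}" if attainable else "–",
                "pauc_pct": 100 * pauc,
                "specificity_pct": 100 * spec,
                "sensitivity_pct": 100 * sens,
                "pauc_ci": fmt_ci(*(100 * np.array(ci["pauc"]))) if ci else "",
                "specificity_ci": fmt_ci(*(100 * np.array(ci["spec"]))) if ci else "",
                "sensitivity_ci": fmt_ci(*(100 * np.array(ci["sens"]))) if ci else "",
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "n_missing": int((~keep).sum()),
                "constraint_met": bool(sens >= min_sens - 1e-12),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["pauc_pct", "specificity_pct", "marker"], ascending=[False, False, True]
    )
    return table.reset_index(drop=True)


def run_panel_analysis(
    cohort: pd.DataFrame,
    dichotomy: str = "favorable_vs_unfavorable",
    baseline_marker: str = "hcts_sum",
    candidate_markers: Sequence[str] | None = None,
    max_sizes: Sequence[int] = (2, 3),
    min_sens: float = 0.90,
    *,
    strategy: str = "quantiles",
    grid_size: int = 19,
    band: tuple[float, float] = _BAND,
    n_boot: int = 2000,
    seed: int = 0,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Baseline-vs-panel table: the baseline marker alone at its constrained
    operating point, then one optimized panel per entry of `max_sizes`.

    When the baseline cannot reach the sensitivity floor at positive
    specificity, the panel analysis is skipped (the baseline row is emitted
    with a logged reason), mirroring the practice of not panel-optimizing a
    dichotomy where the anchor score has no clinically relevant performance.
    """
    if baseline_marker not in cohort.columns:
        raise KeyError(f"baseline marker {baseline_marker!r} not in cohort")
    if candidate_markers is None:
        candidate_markers = [m for m in MARKER_COLUMNS if m in cohort.columns]
    y = outcome_labels(cohort, dichotomy)

    base = run_single_marker_analysis(
        cohort, dichotomy, min_sens, [baseline_marker],
        band=band, n_boot=n_boot, seed=seed, with_ci=with_ci,
    )
    base.insert(0, "row", "baseline")
    base.insert(1, "panel", f"{baseline_marker} (>{base.loc[0, 'threshold']})"
                if base.loc[0, "threshold"] != "–" else baseline_marker)

    baseline_relevant = (
        base.loc[0, "threshold"] != "–" and base.loc[0, "specificity_pct"] > 0
    )
    if not baseline_relevant:
        logger.warning(
            "panel analysis skipped for %s: baseline %s has no clinically "
            "relevant operating point (specificity 0 at the sensitivity floor)",
            dichotomy, baseline_marker,
        )
        base["skip_reason"] = "baseline without clinically relevant performance"
        return base

    pool = sorted(set([baseline_marker, *candidate_markers]))
    rows = [base]
    for k in max_sizes:
        panel, perf = optimize_panel(
            cohort, y, pool,
            max_size=k, min_sens=min_sens, strategy=strategy,
            grid_size=grid_size, seed=seed, band=band, n_boot=n_boot,
            with_ci=with_ci,
        )
        rows.append(pd.DataFrame([{
            "row": f"panel_max{k}",
            "panel": str(panel) + f" [>= {panel.min_positive} positive]",
            "marker": "+".join(panel.markers),
            "threshold": ";".join(f"{r.threshold:g}" for r in panel.rules),
            "pauc_pct": 100 * perf.pauc,
            "specificity_pct": 100 * perf.specificity,
            "sensitivity_pct": 100 * perf.sensitivity,
            "pauc_ci": fmt_ci(*(100 * np.array(perf.pauc_ci))) if perf.pauc_ci else "",
            "specificity_ci": fmt_ci(*(100 * np.array(perf.specificity_ci))) if perf.specificity_ci else "",
            "sensitivity_ci": fmt_ci(*(100 * np.array(perf.sensitivity_ci))) if perf.sensitivity_ci else "",
            "tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn,
            "n_missing": perf.n_excluded,
            "constraint_met": perf.constraint_met,
        }]))
    return pd.concat(rows, ignore_index=True)


@dataclass
class AnalysisReport:
    """Bundle of the full-analysis tables plus run metadata."""

    single_marker_tables: dict[str, pd.DataFrame]
    panel_tables: dict[str, pd.DataFrame]
    cohort_summary: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        names = {"favorable_vs_unfavorable": "table3_like", "complete_vs_incomplete": "table4_like"}
        for dich, table in self.single_marker_tables.items():
            table.to_csv(out / f"{names.get(dich, dich)}.csv", index=False)
        panel_names = {2: "table5a_like", 3: "table5b_like"}
        for key, table in self.panel_tables.items():
            table.to_csv(out / f"{key}.csv", index=False)
        self.cohort_summary.to_csv(out / "cohort_summary.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full_report(
    cohort: pd.DataFrame,
    min_sens: float = 0.90,
    *,
    strategy: str = "quantiles",
    grid_size: int = 19,
    n_boot: int = 2000,
    seed: int = 0,
    ct_positive_only: bool = True,
    with_ci: bool = True,
) -> AnalysisReport:
    """Run the complete analysis on one cohort table.

    Single-marker tables for both outcome dichotomies, baseline-vs-panel
    tables (panel sizes 2 and 3) anchored on the HCTS for each dichotomy
    where the baseline is clinically relevant, and the two-group cohort
    summary.  The main analysis is restricted to CT-positive patients by
    default, matching the design in which CT-negative patients form a
    separate comparison cohort.
    """
    main = cohort[cohort["ct_positive"].astype(bool)] if ct_positive_only else cohort
    main = main.reset_index(drop=True)
    single = {}
    panels = {}
    for dich in DICHOTOMIES:
        single[dich] = run_single_marker_analysis(
            main, dich, min_sens, n_boot=n_boot, seed=seed, with_ci=with_ci
        )
    for k in (2, 3):
        panels[f"table5{'a' if k == 2 else 'b'}_like"] = run_panel_analysis(
            main, "favorable_vs_unfavorable", "hcts_sum",
            max_sizes=(k,), min_sens=min_sens, strategy=strategy,
            grid_size=grid_size, n_boot=n_boot, seed=seed, with_ci=with_ci,
        )
    # the incomplete-recovery dichotomy is panel-optimized only if its
    # baseline is relevant; run_panel_analysis handles (and logs) the skip
    panels["panel_incomplete"] = run_panel_analysis(
        main, "complete_vs_incomplete", "hcts_sum",
        max_sizes=(2,), min_sens=min_sens, strategy=strategy,
        grid_size=grid_size, n_boot=n_boot, seed=seed, with_ci=with_ci,
    )
    summary = comparisons_to_frame(
        summarize_cohort(main, "outcome_favorable")
    )
    metadata = {
        "seed": seed,
        "min_sens": min_sens,
        "band": list(_BAND),
        "strategy": strategy,
        "grid_size": grid_size,
        "n_boot": n_boot,
        "rounding": "half-up, 1 decimal, reporting layer only",
        "version": __version__,
        "config_hash": _config_hash(
            {"min_sens": min_sens, "strategy": strategy, "grid_size": grid_size,
             "n_boot": n_boot, "seed": seed, "n": len(cohort)}
        ),
    }
    return AnalysisReport(single, panels, summary, metadata)
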
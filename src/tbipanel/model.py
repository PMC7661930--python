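"""Model/Results interface over threshold-panel optimization.

`ThresholdPanelModel` is constructed from a cohort DataFrame and an outcome
column; `fit()` runs the constrained exhaustive panel search and returns a
`PanelResults` carrying the selected panel (the point estimate), its
bootstrap confidence intervals, the confusion counts, and a text
``summary()``.  Prediction on new records goes through the fitted panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._formatting import fmt_ci, fmt_pct
from .panel import PanelDefinition, PanelPerformance, optimize_panel, _panel_counts

__all__ = ["ThresholdPanelModel", "PanelResults"]


class ThresholdPanelModel:
    """Threshold-panel classifier for a binary clinical outcome.

    Parameters
    ----------
    data : pandas.DataFrame
        Cohort table, one row per patient.
    outcome : str or array-like
        Binary outcome (1 = positive class, e.g. unfavorable recovery);
        either a column name or a label vector.
    markers : sequence of str
        Candidate marker columns (biomarkers and/or an imaging score).
    max_size : int
        Largest panel considered (1-3 rules).
    min_sens : float
        Sensitivity floor of the constrained search (default 0.90).
    strategy, grid_size
        Candidate-threshold grid: ``"quantiles"`` (default, `grid_size`
        cuts) or ``"midpoints"`` (exhaustive).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome,
        markers,
        *,
        max_size: int = 3,
        min_sens: float = 0.90,
        strategy: str = "quantiles",
        grid_size: int = 19,
        band: tuple[float, float] = (0.90, 1.00),
    ) -> None:
        self.data = data
        self.outcome = outcome
        self.markers = list(markers)
        self.max_size = max_size
        self.min_sens = min_sens
        self.strategy = strategy
        self.grid_size = grid_size
        self.band = band

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, markers, **kwargs):
        """Construct from a cohort DataFrame and an outcome column name."""
        return cls(data, outcome, markers, **kwargs)

    def fit(
        self, seed: int = 0, n_boot: int = 2000, engine: str = "exhaustive"
    ) -> "PanelResults":
        """Run the constrained panel search; returns the fitted results."""
        panel, perf = optimize_panel(
            self.data,
            self.outcome,
            self.markers,
            max_size=self.max_size,
            min_sens=self.min_sens,
            strategy=self.strategy,
            grid_size=self.grid_size,
            seed=seed,
            band=self.band,
            n_boot=n_boot,
            engine=engine,
        )
        return PanelResults(model=self, panel=panel, performance=perf, seed=seed)


@dataclass
class PanelResults:
    """Fitted panel, its performance and uncertainties."""

    model: ThresholdPanelModel
    panel: PanelDefinition
    performance: PanelPerformance
    seed: int

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Panel-positive indicator for each row of `data`."""
        return _panel_counts(self.panel, data) >= self.panel.min_positive

    def summary(self) -> str:
        p = self.performance
        lines = [
            "Threshold panel (sensitivity-constrained search)",
            "=" * 48,
            f"Panel:         {self.panel}",
            f"Decision rule: >= {self.panel.min_positive} rule(s) positive",
            f"Constraint:    sensitivity >= {self.model.min_sens:.0%}"
            + ("" if p.constraint_met else "  [NOT MET]"),
            "-" * 48,
            f"pAUC (90-100% sens band): {fmt_pct(100 * p.pauc)}% "
            + (f"{fmt_ci(100 * p.pauc_ci[0], 100 * p.pauc_ci[1])}" if p.pauc_ci else ""),
            f"Sensitivity:              {fmt_pct(100 * p.sensitivity)}% "
            + (f"{fmt_ci(100 * p.sensitivity_ci[0], 100 * p.sensitivity_ci[1])}" if p.sensitivity_ci else ""),
            f"Specificity:              {fmt_pct(100 * p.specificity)}% "
            + (f"{fmt_ci(100 * p.specificity_ci[0], 100 * p.specificity_ci[1])}" if p.specificity_ci else ""),
            f"Confusion (tp/fp/tn/fn):  {p.tp}/{p.fp}/{p.tn}/{p.fn}"
            + (f"  ({p.n_excluded} excluded)" if p.n_excluded else ""),
            f"Bootstrap seed:           {self.seed}",
        ]
        return "\n".join(lines)
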
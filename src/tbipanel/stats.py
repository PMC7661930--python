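"""Group-comparison statistics and cohort summary tables.

Continuous skewed variables (the plasma biomarkers; ordinal severity scores)
are compared between outcome groups with the Mann-Whitney U-test; normally
distributed demographics with Welch two-sample t-tests; and categorical
variables with two-sample proportion tests.  The variable-to-test mapping is
*declared*, never inferred from the data, so results are deterministic;
normality screening, if wanted, is descriptive only and never switches a
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from ._formatting import round_half_up

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "summarize_cohort",
    "DEFAULT_VARIABLES",
]

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    """One row of a two-group summary table."""

    variable: str
    summary_a: str
    summary_b: str
    p_value: float | None
    test: str
    n_missing_a: int = 0
    n_missing_b: int = 0
    flag: str = ""


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U statistic (for group_a) and two-sided p-value.

    Ties are handled by midranks.  The p-value uses the exact null
    distribution when the combined sample size is at most 12 and the data
    are untied, and otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate((a, b))
    untied = np.unique(pooled).size == pooled.size
    if a.size + b.size <= _EXACT_MAX_N and untied:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# variable -> (summary format, declared test)
DEFAULT_VARIABLES: Mapping[str, tuple[str, str]] = {
    "age": ("mean_sd", "t_test"),
    "sex": ("n_pct_male", "proportion_test"),
    "gcs": ("median_range", "mann_whitney"),
    "iss": ("median_range", "mann_whitney"),
    "hcts_sum": ("median_range", "mann_whitney"),
    "ab40": ("median_iqr", "mann_whitney"),
    "ab42": ("median_iqr", "mann_whitney"),
    "gfap": ("median_iqr", "mann_whitney"),
    "hfabp": ("median_iqr", "mann_whitney"),
    "il10": ("median_iqr", "mann_whitney"),
    "nfl": ("median_iqr", "mann_whitney"),
    "s100b": ("median_iqr", "mann_whitney"),
    "ttau": ("median_iqr", "mann_whitney"),
}


def _summarize(values: np.ndarray, how: str) -> str:
    if values.size == 0:
        return "–"
    if how == "mean_sd":
        return f"{round_half_up(float(np.mean(values)), 1)} ± {round_half_up(float(np.std(values, ddof=1)), 1)}"
    if how == "median_range":
        return f"{round_half_up(float(np.median(values)), 1)} [{round_half_up(float(values.min()), 1)}–{round_half_up(float(values.max()), 1)}]"
    if how == "median_iqr":
        q1, q3 = np.percentile(values, [25, 75])
        return f"{round_half_up(float(np.median(values)), 1)} ({round_half_up(float(q3 - q1), 1)})"
    if how == "n_pct_male":
        n = int(np.sum(values))
        pct = 100.0 * n / values.size
        return f"{n} ({round_half_up(pct, 0):.0f}%)"
    raise ValueError(f"unknown summary format {how!r}")


def _coerce(series: pd.Series, how: str) -> np.ndarray:
    if how == "n_pct_male":
        return (series.astype(str).str.lower() == "male").to_numpy(dtype=float)
    return pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)


def _compare(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float | None, str]:
    if np.unique(np.concatenate((a, b))).size == 1:
        return 1.0, "degenerate"
    if test == "mann_whitney":
        return mann_whitney_u(a, b)[1], ""
    if test == "t_test":
        # Welch by default: no pooled-variance assumption
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue), ""
    if test == "proportion_test":
        counts = np.array([a.sum(), b.sum()])
        nobs = np.array([a.size, b.size])
        return float(proportions_ztest(counts, nobs)[1]), ""
    raise ValueError(f"unknown test {test!r}")


def summarize_cohort(
    cohort: pd.DataFrame,
    grouping: str,
    variables: Mapping[str, tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Two-group summary table (one GroupComparison per declared variable).

    `grouping` must name a binary column; group A is the truthy (or larger)
    level.  Records with missing values are excluded per variable, with the
    exclusion counts reported on the row.  A variable observed in only one
    group is flagged ``"not comparable"`` and carries no p-value.
    """
    groups = pd.unique(cohort[grouping].dropna())
    if len(groups) != 2:
        raise ValueError(
            f"grouping column {grouping!r} must be binary, found levels {list(groups)}"
        )
    level_a, level_b = sorted(groups, reverse=True)  # truthy / larger first
    variables = DEFAULT_VARIABLES if variables is None else variables
    rows: list[GroupComparison] = []
    for var, (how, test) in variables.items():
        if var not in cohort.columns:
            continue
        in_a = cohort[grouping] == level_a
        in_b = cohort[grouping] == level_b
        a_raw = _coerce(cohort.loc[in_a, var], how)
        b_raw = _coerce(cohort.loc[in_b, var], how)
        a = a_raw[~np.isnan(a_raw)]
        b = b_raw[~np.isnan(b_raw)]
        miss_a = int(np.isnan(a_raw).sum())
        miss_b = int(np.isnan(b_raw).sum())
        if a.size == 0 or b.size == 0:
            rows.append(
                GroupComparison(var, _summarize(a, how), _summarize(b, how),
                                None, test, miss_a, miss_b, "not comparable")
            )
            continue
        p, flag = _compare(a, b, test)
        rows.append(
            GroupComparison(var, _summarize(a, how), _summarize(b, how),
                            p, test, miss_a, miss_b, flag)
        )
    return rows


def comparisons_to_frame(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    """Serialize summary rows to the report-table layout."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "group_a_summary": [r.summary_a for r in rows],
            "group_b_summary": [r.summary_b for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test for r in rows],
            "n_missing_a": [r.n_missing_a for r in rows],
            "n_missing_b": [r.n_missing_b for r in rows],
            "flag": [r.flag for r in rows],
        }
    )
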
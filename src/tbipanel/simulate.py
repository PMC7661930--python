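"""Synthetic TBI cohort generator.

Patient-level data behind published TBI biomarker studies are rarely
shareable, so this module generates cohorts that emulate the *printed*
statistical structure of such a study: fixed group sizes (82 CT-positive
patients split 49 favorable / 33 unfavorable by dichotomised GOSE, and 55
CT-negative patients split 51 / 4), right-skewed biomarker concentrations
matched to published median/IQR pairs via a two-parameter lognormal, and
per-outcome-group prevalences of each Helsinki CT Score finding.  CT-negative
patients carry all-negative CT findings and an HCTS sum of 0 by construction.

The lognormal family is an emulation assumption, not a claim about the true
data: it is strictly positive, right-skewed, and exactly identifiable from a
median/IQR pair (location = ln median; scale from the IQR equation).  Marker
distributions whose per-group summaries were published are tagged
``provenance="published"``; the remainder are plausible placeholders tagged
``provenance="assumed"`` and should never be treated as reference values.

Generation is fully deterministic under the config seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .hcts import HctsFindings, score_hcts

__all__ = [
    "MarkerDistribution",
    "GroupCtPrevalence",
    "CohortConfig",
    "fit_lognormal_from_median_iqr",
    "generate_cohort",
    "default_config",
    "MARKER_COLUMNS",
]

#: z-score of the 75th percentile of the standard normal
_Z75 = float(norm.ppf(0.75))

MARKER_COLUMNS = ("ab40", "ab42", "gfap", "hfabp", "il10", "nfl", "s100b", "ttau")

COHORT_COLUMNS = (
    "id", "ct_positive", "gose", "outcome_favorable", "outcome_complete",
    *MARKER_COLUMNS,
    "sdh", "edh", "ich", "mass_gt25", "ivh", "cisterns", "hcts_sum",
    "age", "sex", "gcs", "iss", "delay_h",
)


@dataclass(frozen=True)
class MarkerDistribution:
    """Lognormal marker distribution for one patient group, parameterised by
    the published summary pair (median, IQR) in pg/ml."""

    marker: str
    group: str
    median: float
    iqr: float
    family: str = "lognormal"
    provenance: str = "assumed"

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.iqr < 0:
            raise ValueError("iqr must be nonnegative")
        if self.family != "lognormal":
            raise ValueError("only the lognormal family is supported")


@dataclass(frozen=True)
class GroupCtPrevalence:
    """Per-group probabilities of each HCTS finding."""

    sdh: float
    edh: float
    ich: float
    mass_gt25: float
    ivh: float
    cisterns: tuple[float, float, float]  # normal, compressed, obliterated

    def __post_init__(self) -> None:
        probs = [self.sdh, self.edh, self.ich, self.mass_gt25, self.ivh, *self.cisterns]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.cisterns) - 1.0) > 1e-9:
            raise ValueError("cistern probabilities must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_ct_positive: int
    n_ct_negative: int
    n_favorable: int            # within CT-positive
    n_unfavorable: int          # within CT-positive
    n_ct_neg_favorable: int     # within CT-negative
    n_ct_neg_unfavorable: int
    marker_distributions: tuple[MarkerDistribution, ...]
    ct_feature_prevalence: Mapping[str, GroupCtPrevalence]
    p_complete_given_favorable: Mapping[str, float]
    below_lod_rule: tuple[str, float] = ("s100b", 1.0)
    age_mean_sd: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    p_male: Mapping[str, float] = field(default_factory=dict)
    delay_mean_sd_h: tuple[float, float] = (13.1, 10.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_favorable + self.n_unfavorable != self.n_ct_positive:
            raise ValueError("CT-positive outcome groups must sum to n_ct_positive")
        if self.n_ct_neg_favorable + self.n_ct_neg_unfavorable != self.n_ct_negative:
            raise ValueError("CT-negative outcome groups must sum to n_ct_negative")
        for p in self.p_complete_given_favorable.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_complete_given_favorable must lie in [0, 1]")

    def distribution(self, marker: str, group: str) -> MarkerDistribution:
        for d in self.marker_distributions:
            if d.marker == marker and d.group == group:
                return d
        raise KeyError(f"no distribution for marker={marker!r} group={group!r}")


def fit_lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Lognormal (log-location mu, log-scale sigma) from a median/IQR pair.

    The quartiles of LogNormal(mu, sigma) are exp(mu ± z75·sigma), so the
    IQR equation exp(mu + z·sigma) − exp(mu − z·sigma) = iqr reduces to
    2·median·sinh(z·sigma) = iqr, whose unique nonnegative solution is
    sigma = asinh(iqr / (2·median)) / z75 — exact and monotone in iqr.
    iqr = 0 degenerates to a point mass at the median (sigma = 0).
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("iqr must be nonnegative")
    mu = float(np.log(median))
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return mu, sigma


def _draw_marker(rng: np.random.Generator, dist: MarkerDistribution, n: int) -> np.ndarray:
    mu, sigma = fit_lognormal_from_median_iqr(dist.median, dist.iqr)
    return np.exp(rng.normal(mu, sigma, size=n))


def _draw_findings(rng: np.random.Generator, prev: GroupCtPrevalence, n: int) -> pd.DataFrame:
    cist = rng.choice(
        ["normal", "compressed", "obliterated"], size=n, p=list(prev.cisterns)
    )
    return pd.DataFrame(
        {
            "sdh": rng.random(n) < prev.sdh,
            "edh": rng.random(n) < prev.edh,
            "ich": rng.random(n) < prev.ich,
            "mass_gt25": rng.random(n) < prev.mass_gt25,
            "ivh": rng.random(n) < prev.ivh,
            "cisterns": cist,
        }
    )


def _hcts_sums(findings: pd.DataFrame) -> np.ndarray:
    sums = np.empty(len(findings), dtype=int)
    for i, row in enumerate(findings.itertuples(index=False)):
        f = HctsFindings(
            subdural_hematoma=bool(row.sdh),
            epidural_hematoma=bool(row.edh),
            intracerebral_hematoma=bool(row.ich),
            mass_lesion_gt_25cm3=bool(row.mass_gt25 and (row.sdh or row.edh or row.ich)),
            intraventricular_hemorrhage=bool(row.ivh),
            suprasellar_cisterns=str(row.cisterns),
        )
        sums[i] = score_hcts(f).sum
    return sums


def _draw_gose(
    rng: np.random.Generator, favorable: bool, p_complete: float, n: int
) -> np.ndarray:
    if favorable:
        # GOSE 8 frequency matched to the published share of complete
        # recovery among favorable outcomes; 5-7 uniform otherwise.
        complete = rng.random(n) < p_complete
        gose = rng.integers(5, 8, size=n)  # 5, 6, 7
        gose[complete] = 8
        return gose
    return rng.integers(1, 5, size=n)  # 1..4


def _group_frame(
    rng: np.random.Generator,
    config: CohortConfig,
    group: str,
    ct_positive: bool,
    favorable: bool,
    n: int,
) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n))
    df["ct_positive"] = ct_positive
    p_complete = config.p_complete_given_favorable.get(group, 0.0) if favorable else 0.0
    df["gose"] = _draw_gose(rng, favorable, p_complete, n)
    df["outcome_favorable"] = favorable
    df["outcome_complete"] = df["gose"] == 8
    for marker in MARKER_COLUMNS:
        df[marker] = _draw_marker(rng, config.distribution(marker, group), n)
    lod_marker, lod_floor = config.below_lod_rule
    df[lod_marker] = np.maximum(df[lod_marker], lod_floor)
    if ct_positive:
        findings = _draw_findings(rng, config.ct_feature_prevalence[group], n)
        df = pd.concat([df, findings], axis=1)
        df["hcts_sum"] = _hcts_sums(findings)
    else:
        for c in ("sdh", "edh", "ich", "mass_gt25", "ivh"):
            df[c] = False
        df["cisterns"] = "normal"
        df["hcts_sum"] = 0
    mean, sd = config.age_mean_sd.get(group, (50.0, 20.0))
    df["age"] = np.clip(rng.normal(mean, sd, size=n), 18.0, 100.0).round(1)
    df["sex"] = np.where(rng.random(n) < config.p_male.get(group, 0.7), "male", "female")
    df["gcs"] = rng.integers(3, 16, size=n) if not favorable else rng.integers(9, 16, size=n)
    df["iss"] = rng.integers(1, 51, size=n)
    dmean, dsd = config.delay_mean_sd_h
    df["delay_h"] = np.maximum(rng.normal(dmean, dsd, size=n), 0.0).round(2)
    return df


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table (one row per patient).

    Deterministic under ``config.seed``; markers in pg/ml; HCTS sum computed
    from the drawn findings (always 0 for CT-negative rows); the below-LOD
    floor applied to the configured marker.
    """
    rng = np.random.default_rng(config.seed)
    parts = [
        _group_frame(rng, config, "favorable", True, True, config.n_favorable),
        _group_frame(rng, config, "unfavorable", True, False, config.n_unfavorable),
        _group_frame(rng, config, "ct_neg_favorable", False, True, config.n_ct_neg_favorable),
        _group_frame(rng, config, "ct_neg_unfavorable", False, False, config.n_ct_neg_unfavorable),
    ]
    df = pd.concat(parts, ignore_index=True)
    df.insert(0, "id", [f"P{i + 1:03d}" for i in range(len(df))])
    df[list(MARKER_COLUMNS)] = df[list(MARKER_COLUMNS)].round(6)
    return df[list(COHORT_COLUMNS)]


def cohort_to_csv(cohort: pd.DataFrame) -> str:
    """Serialize a cohort with stable formatting (byte-identical per seed)."""
    buf = io.StringIO()
    cohort.to_csv(buf, index=False)
    return buf.getvalue()


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON serializable)."""
    d = asdict(config)
    d["marker_distributions"] = [asdict(m) for m in config.marker_distributions]
    d["ct_feature_prevalence"] = {
        g: {**asdict(p), "cisterns": list(p.cisterns)}
        for g, p in config.ct_feature_prevalence.items()
    }
    d["below_lod_rule"] = list(config.below_lod_rule)
    d["delay_mean_sd_h"] = list(config.delay_mean_sd_h)
    d["age_mean_sd"] = {g: list(v) for g, v in config.age_mean_sd.items()}
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    d["marker_distributions"] = tuple(
        MarkerDistribution(**m) for m in d["marker_distributions"]
    )
    d["ct_feature_prevalence"] = {
        g: GroupCtPrevalence(**{**p, "cisterns": tuple(p["cisterns"])})
        for g, p in d["ct_feature_prevalence"].items()
    }
    d["below_lod_rule"] = tuple(d.get("below_lod_rule", ("s100b", 1.0)))
    d["delay_mean_sd_h"] = tuple(d.get("delay_mean_sd_h", (13.1, 10.4)))
    d["age_mean_sd"] = {g: tuple(v) for g, v in d.get("age_mean_sd", {}).items()}
    return CohortConfig(**d)


def load_config(path: str | Path) -> CohortConfig:
    """Read a generator config from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(data)


def save_config(config: CohortConfig, path: str | Path) -> None:
    """Write a generator config as YAML (or JSON if the suffix is .json)."""
    d = config_to_dict(config)
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


def default_config(seed: int = 0) -> CohortConfig:
    """The default study-structure configuration.

    Group sizes, CT-feature prevalences per outcome group, and the NF-L and
    Aβ42 distributions encode published summaries (``provenance=
    "published"``); the remaining marker distributions are plausible
    placeholders (``provenance="assumed"``) chosen once to echo the
    published single-marker threshold scale, and must not be used as
    reference values.
    """
    published = [
        # marker, group, median, iqr  — printed per-outcome summaries
        ("nfl", "favorable", 36.9, 57.6),
        ("nfl", "unfavorable", 99.9, 120.0),
        ("ab42", "favorable", 16.9, 16.4),
        ("ab42", "unfavorable", 21.9, 40.6),
    ]
    assumed = [
        # Aβ40 medians overlap between groups (no significant difference),
        # scale echoing the ~15 pg/ml single-marker threshold.
        ("ab40", "favorable", 18.0, 20.0),
        ("ab40", "unfavorable", 22.0, 35.0),
        ("gfap", "favorable", 60.0, 160.0),
        ("gfap", "unfavorable", 160.0, 420.0),
        ("hfabp", "favorable", 18.0, 22.0),
        ("hfabp", "unfavorable", 32.0, 45.0),
        ("il10", "favorable", 0.8, 2.2),
        ("il10", "unfavorable", 1.6, 6.0),
        ("s100b", "favorable", 90.0, 180.0),
        ("s100b", "unfavorable", 260.0, 600.0),
        ("ttau", "favorable", 4.0, 8.0),
        ("ttau", "unfavorable", 11.0, 28.0),
        # CT-negative patients: milder injuries, lower marker levels,
        # echoing the CT-negative single-marker threshold scale.
        ("nfl", "ct_neg_favorable", 7.0, 10.0),
        ("nfl", "ct_neg_unfavorable", 25.0, 40.0),
        ("ab42", "ct_neg_favorable", 12.0, 12.0),
        ("ab42", "ct_neg_unfavorable", 15.0, 18.0),
        ("ab40", "ct_neg_favorable", 14.0, 14.0),
        ("ab40", "ct_neg_unfavorable", 22.0, 20.0),
        ("gfap", "ct_neg_favorable", 0.35, 0.8),
        ("gfap", "ct_neg_unfavorable", 1.2, 2.5),
        ("hfabp", "ct_neg_favorable", 3.5, 5.0),
        ("hfabp", "ct_neg_unfavorable", 7.0, 9.0),
        ("il10", "ct_neg_favorable", 0.25, 0.6),
        ("il10", "ct_neg_unfavorable", 0.6, 1.5),
        ("s100b", "ct_neg_favorable", 40.0, 70.0),
        ("s100b", "ct_neg_unfavorable", 90.0, 160.0),
        ("ttau", "ct_neg_favorable", 1.4, 2.2),
        ("ttau", "ct_neg_unfavorable", 3.0, 5.0),
    ]
    dists = tuple(
        [MarkerDistribution(m, g, md, iq, provenance="published") for m, g, md, iq in published]
        + [MarkerDistribution(m, g, md, iq, provenance="assumed") for m, g, md, iq in assumed]
    )
    prevalence = {
        # published per-outcome-group finding counts among CT-positive
        # patients, encoded as exact fractions
        "favorable": GroupCtPrevalence(
            sdh=27 / 49, edh=7 / 49, ich=27 / 49, mass_gt25=10 / 49, ivh=9 / 49,
            cisterns=(33 / 49, 13 / 49, 3 / 49),
        ),
        "unfavorable": GroupCtPrevalence(
            sdh=26 / 33, edh=4 / 33, ich=26 / 33, mass_gt25=16 / 33, ivh=12 / 33,
            cisterns=(14 / 33, 18 / 33, 1 / 33),
        ),
    }
    return CohortConfig(
        n_ct_positive=82,
        n_ct_negative=55,
        n_favorable=49,
        n_unfavorable=33,
        n_ct_neg_favorable=51,
        n_ct_neg_unfavorable=4,
        marker_distributions=dists,
        ct_feature_prevalence=prevalence,
        # complete recovery (GOSE 8): 10/49 of CT-positive favorable,
        # 23/51 of CT-negative favorable
        p_complete_given_favorable={
            "favorable": 10 / 49,
            "ct_neg_favorable": 23 / 51,
        },
        below_lod_rule=("s100b", 1.0),
        age_mean_sd={
            "favorable": (44.69, 19.55),
            "unfavorable": (59.03, 18.67),
            "ct_neg_favorable": (43.67, 18.21),
            "ct_neg_unfavorable": (43.67, 18.21),
        },
        p_male={
            "favorable": 37 / 49,
            "unfavorable": 27 / 33,
            "ct_neg_favorable": 34 / 55,
            "ct_neg_unfavorable": 34 / 55,
        },
        delay_mean_sd_h=(13.1, 10.4),
        seed=seed,
    )
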
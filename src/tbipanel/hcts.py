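"""Helsinki CT Score (HCTS) computation from structured head-CT findings.

The HCTS is an integer score summarising acute traumatic intracranial
pathology on the admission head CT: the presence of subdural, epidural and
intracerebral hematoma/contusion, a mass lesion larger than 25 cm^3,
intraventricular hemorrhage, and the state of the suprasellar cisterns
(normal, compressed or obliterated).  Each finding carries a fixed integer
weight and the score is the plain sum of the applicable weights; over all
possible findings the sum ranges from -3 (isolated epidural hematoma, which
carries a protective weight) to 14 (every adverse finding present with
obliterated cisterns and no epidural hematoma).

The weight table is shipped as versioned data (``data/hcts_weights.json``)
rather than hard-coded, so that alternative CT scores or a corrected weight
table can be swapped in without touching code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

__all__ = [
    "CISTERN_CATEGORIES",
    "HctsFindings",
    "HctsScore",
    "load_weight_table",
    "score_hcts",
    "classify_hcts",
    "hcts_score_range",
]

CISTERN_CATEGORIES = ("normal", "compressed", "obliterated")

_FLAG_FIELDS = (
    "subdural_hematoma",
    "epidural_hematoma",
    "intracerebral_hematoma",
    "mass_lesion_gt_25cm3",
    "intraventricular_hemorrhage",
)

_MASS_LESION_FLAGS = ("subdural_hematoma", "epidural_hematoma", "intracerebral_hematoma")


def load_weight_table() -> dict:
    """Load the versioned HCTS component weight table shipped with the package."""
    with resources.files("tbipanel.data").joinpath("hcts_weights.json").open() as fh:
        return json.load(fh)


_WEIGHTS = load_weight_table()


@dataclass(frozen=True)
class HctsFindings:
    """Structured head-CT findings feeding the HCTS sum.

    Parameters
    ----------
    subdural_hematoma, epidural_hematoma, intracerebral_hematoma : bool
        Mass-lesion type flags (intracerebral covers hematoma/contusion).
    mass_lesion_gt_25cm3 : bool
        Any mass lesion with volume above 25 cm^3.
    intraventricular_hemorrhage : bool
    suprasellar_cisterns : str
        One of ``"normal"``, ``"compressed"``, ``"obliterated"``.
    strict : bool
        If True, a ``mass_lesion_gt_25cm3`` flag without any mass-lesion
        type flag is rejected; by default it only warns, because lesion
        types and lesion size are tallied independently in practice.
    """

    subdural_hematoma: bool = False
    epidural_hematoma: bool = False
    intracerebral_hematoma: bool = False
    mass_lesion_gt_25cm3: bool = False
    intraventricular_hemorrhage: bool = False
    suprasellar_cisterns: str = "normal"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.suprasellar_cisterns not in CISTERN_CATEGORIES:
            raise ValueError(
                f"suprasellar_cisterns must be one of {CISTERN_CATEGORIES}, "
                f"got {self.suprasellar_cisterns!r}"
            )
        if self.mass_lesion_gt_25cm3 and not any(
            getattr(self, f) for f in _MASS_LESION_FLAGS
        ):
            msg = "mass_lesion_gt_25cm3 is set but no mass-lesion type flag is set"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)


@dataclass(frozen=True)
class HctsScore:
    """An HCTS sum; valid values span the closed interval [-3, 14]."""

    sum: int

    def __post_init__(self) -> None:
        lo, hi = hcts_score_range()
        if not lo <= self.sum <= hi:
            raise ValueError(f"HCTS sum {self.sum} outside attainable range [{lo}, {hi}]")


def score_hcts(findings: HctsFindings, weights: Mapping | None = None) -> HctsScore:
    """Sum the component weights for one patient's CT findings.

    Parameters
    ----------
    findings : HctsFindings
    weights : mapping, optional
        Alternative weight table with the same layout as
        ``load_weight_table()``; defaults to the shipped table.
    """
    table = weights if weights is not None else _WEIGHTS
    total = sum(table["weights"][f] for f in _FLAG_FIELDS if getattr(findings, f))
    total += table["suprasellar_cisterns"][findings.suprasellar_cisterns]
    return HctsScore(sum=int(total))


def classify_hcts(score: HctsScore | int, threshold: int) -> bool:
    """Predict unfavorable outcome iff the score strictly exceeds the threshold.

    The dichotomisation is strictly greater-than ("HCTS > 1"): a sum equal
    to the threshold is classified negative.
    """
    value = score.sum if isinstance(score, HctsScore) else int(score)
    return value > threshold


def hcts_score_range(weights: Mapping | None = None) -> tuple[int, int]:
    """Attainable (min, max) of the score over all findings combinations."""
    table = weights if weights is not None else _WEIGHTS
    lo = sum(min(0, w) for w in table["weights"].values())
    lo += min(table["suprasellar_cisterns"].values())
    hi = sum(max(0, w) for w in table["weights"].values())
    hi += max(table["suprasellar_cisterns"].values())
    return lo, hi
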
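"""Response classification and concordance of the two assessment methods.

Molecular imaging response follows PERCIST-style thresholding applied to the
percent change of total lesion PSMA: partial remission (PR) is a TLP decline
of more than 30%, progressive disease (PD) an increase of more than 30%, and
stable disease (SD) anything in between (boundaries inclusive to SD).  No
new-lesion override is applied — the rule is pure delta thresholding.

Biochemical response follows the PCWG3 PSA rules in their simplified form:
PR is a PSA decline of more than 50%, PD an increase of more than 25%, SD in
between.  Confirmation requirements (repeat PSA measurement, minimum 2 ng/mL
rise) are intentionally not modeled.

Concordance is per-patient agreement of the two categories, summarised as a
3x3 cross-tabulation (biochemical rows x molecular columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ResponseCategory",
    "ResponsePair",
    "ConcordanceSummary",
    "classify_molecular",
    "classify_biochemical",
    "cross_tabulate",
]

#: canonical category order (best to worst); also the cross-tab axis order
_CATEGORY_ORDER = ("PR", "SD", "PD")


class ResponseCategory(str, Enum):
    PR = "PR"  # partial remission
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease


@dataclass(frozen=True)
class ResponsePair:
    """One patient's molecular (ΔTLP) and biochemical (ΔPSA) assessment."""

    patient_id: str
    dtlp_percent: float
    dpsa_percent: float
    molecular: ResponseCategory
    biochemical: ResponseCategory

    @classmethod
    def from_deltas(cls, patient_id: str, dtlp_percent: float, dpsa_percent: float) -> "ResponsePair":
        return cls(
            patient_id=patient_id,
            dtlp_percent=float(dtlp_percent),
            dpsa_percent=float(dpsa_percent),
            molecular=classify_molecular(dtlp_percent),
            biochemical=classify_biochemical(dpsa_percent),
        )

    @property
    def concordant(self) -> bool:
        return self.molecular == self.biochemical


@dataclass(frozen=True)
class ConcordanceSummary:
    """3x3 agreement table with concordance percentages.

    ``cross_tab`` has biochemical categories as rows and molecular categories
    as columns, both in PR/SD/PD order.
    """

    cross_tab: pd.DataFrame
    n_total: int
    n_concordant: int
    percent_concordant: float
    n_discordant: int
    percent_discordant: float


def _check_finite(delta_percent: float) -> float:
    d = float(delta_percent)
    if math.isnan(d) or math.isinf(d):
        raise ValueError(f"percent change must be finite, got {delta_percent!r}")
    return d


def classify_molecular(dtlp_percent: float) -> ResponseCategory:
    """PR iff ΔTLP < -30%, PD iff ΔTLP > +30%, SD otherwise (±30 exactly is SD)."""
    d = _check_finite(dtlp_percent)
    if d < -30.0:
        return ResponseCategory.PR
    if d > 30.0:
        return ResponseCategory.PD
    return ResponseCategory.SD


def classify_biochemical(dpsa_percent: float) -> ResponseCategory:
    """PR iff ΔPSA < -50%, PD iff ΔPSA > +25%, SD otherwise (-50 and +25 are SD)."""
    d = _check_finite(dpsa_percent)
    if d < -50.0:
        return ResponseCategory.PR
    if d > 25.0:
        return ResponseCategory.PD
    return ResponseCategory.SD


def cross_tabulate(pairs: Iterable[ResponsePair]) -> ConcordanceSummary:
    """Cross-tabulate biochemical (rows) versus molecular (columns) response."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no response pairs supplied")
    table = pd.DataFrame(
        np.zeros((3, 3), dtype=int),
        index=pd.Index(_CATEGORY_ORDER, name="biochemical"),
        columns=pd.Index(_CATEGORY_ORDER, name="molecular"),
    )
    for p in pairs:
        table.loc[p.biochemical.value, p.molecular.value] += 1
    n_total = len(pairs)
    n_concordant = int(np.trace(table.to_numpy()))
    n_discordant = n_total - n_concordant
    return ConcordanceSummary(
        cross_tab=table,
        n_total=n_total,
        n_concordant=n_concordant,
        percent_concordant=100.0 * n_concordant / n_total,
        n_discordant=n_discordant,
        percent_discordant=100.0 * n_discordant / n_total,
    )
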
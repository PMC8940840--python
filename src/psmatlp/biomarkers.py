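"""Total lesion PSMA (TLP), percent-change biomarkers, and rank correlation.

TLP is the whole-body viable-tumor-burden surrogate: the sum over all
segmented lesions of lesion volume (mL) times lesion SUVmean, in units of
mL x SUV.  Response biomarkers are the percent change of TLP and of serum
PSA from baseline to after the second therapy cycle; deltas are computed
from exact stored values and never rounded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .image_model import Timepoint
from .segmentation import LesionSet

__all__ = [
    "BiomarkerVariable",
    "TlpMeasurement",
    "PercentChange",
    "compute_tlp",
    "percent_change",
    "spearman_rho",
]


class BiomarkerVariable(str, Enum):
    TLP = "TLP"
    PSA = "PSA"


@dataclass(frozen=True)
class TlpMeasurement:
    """Per patient/timepoint whole-body tumor burden."""

    patient_id: str
    timepoint: Timepoint
    tlp: float  # mL x SUV
    lesion_count: int
    total_volume_ml: float


@dataclass(frozen=True)
class PercentChange:
    """Relative change 100 x (post - baseline) / baseline, in percent."""

    variable: BiomarkerVariable
    baseline: float
    post: float
    delta_percent: float


def compute_tlp(lesions: LesionSet, timepoint: Timepoint | str = Timepoint.BASELINE) -> TlpMeasurement:
    """TLP = sum over lesions of volume_ml x SUVmean (mL x SUV)."""
    tlp = sum(l.volume_ml * l.suv_mean for l in lesions)
    total_volume = sum(l.volume_ml for l in lesions)
    return TlpMeasurement(
        patient_id=lesions.source_image_id,
        timepoint=Timepoint(timepoint),
        tlp=float(tlp),
        lesion_count=len(lesions),
        total_volume_ml=float(total_volume),
    )


def percent_change(
    baseline: float,
    post: float,
    variable: BiomarkerVariable | str = BiomarkerVariable.TLP,
) -> PercentChange:
    """Percent change from baseline; a non-positive baseline is undefined
    (raises rather than returning a silent zero)."""
    if not np.isfinite(baseline) or not np.isfinite(post):
        raise ValueError("baseline and post must be finite")
    if baseline <= 0:
        raise ValueError(f"percent change undefined for baseline {baseline!r} <= 0")
    if post < 0:
        raise ValueError("post value must be non-negative")
    delta = 100.0 * (post - baseline) / baseline
    return PercentChange(
        variable=BiomarkerVariable(variable),
        baseline=float(baseline),
        post=float(post),
        delta_percent=float(delta),
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p_value)`` with a two-sided p from the t-approximation.
    Constant input has no defined rank correlation and raises.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-D sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
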
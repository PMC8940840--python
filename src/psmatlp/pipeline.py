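"""End-to-end orchestration: per-patient response assessment and cohort-level
statistics, producing a single JSON-serializable report.

``run_patient_assessment`` takes a baseline and a post-cycle-2 scan (with
aligned masks), segments both, computes TLP and its percent change together
with the PSA percent change, and classifies molecular and biochemical
response.  ``run_cohort_analysis`` takes the per-patient table and produces
the study-level report: response concordance, Spearman correlations, a
Kaplan-Meier / log-rank comparison per response dichotomy, the univariate
Cox screen, and the multivariable model with backward elimination.  Stages
that cannot run (e.g. no deaths observed) are skipped with an explicit flag
rather than failing the whole report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import BiomarkerVariable, compute_tlp, percent_change, spearman_rho
from .image_model import LabelMask, SuvImage, Timepoint
from .response import ResponsePair, cross_tabulate
from .segmentation import SegmentationConfig, segment_whole_body
from .survival import (
    DEFAULT_RULES,
    backward_eliminate,
    dichotomize,
    km_estimate,
    logrank_test,
    median_follow_up,
    univariate_screen,
)

__all__ = [
    "RunConfig",
    "ScanInputs",
    "PatientAssessment",
    "run_patient_assessment",
    "run_cohort_analysis",
    "write_report",
]

logger = logging.getLogger("psmatlp")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings: segmentation parameters, modeling thresholds,
    output location and seed."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    p_entry: float = 0.1  # univariate screen entry threshold
    p_removal: float = 0.05  # backward-elimination removal threshold
    output_dir: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def provenance(self) -> dict:
        d = {
            "segmentation": asdict(self.segmentation),
            "p_entry": self.p_entry,
            "p_removal": self.p_removal,
            "seed": self.seed,
            "version": __version__,
        }
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
        return d


@dataclass
class ScanInputs:
    """One scan and its aligned masks (any mask may be absent)."""

    image: SuvImage
    exclusion_mask: LabelMask | None = None
    liver_mask: LabelMask | None = None
    liver_ref_voi: LabelMask | None = None


@dataclass
class PatientAssessment:
    """Per-patient two-timepoint result record."""

    patient_id: str
    tlp_baseline: float
    tlp_post: float
    dtlp_percent: float
    psa_baseline: float
    psa_post: float
    dpsa_percent: float
    molecular: str
    biochemical: str
    concordant: bool
    lesion_count_baseline: int
    lesion_count_post: int
    liver_threshold_baseline: float | None
    liver_threshold_post: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def run_patient_assessment(
    baseline: ScanInputs,
    post: ScanInputs,
    psa_baseline: float,
    psa_post: float,
    config: RunConfig | None = None,
    patient_id: str | None = None,
) -> PatientAssessment:
    """Segment both timepoints, quantify TLP, and classify response.

    A baseline scan with no segmentable tumor (TLP 0) or a non-positive
    baseline PSA makes the percent changes undefined and raises.
    """
    config = config or RunConfig()
    pid = patient_id or baseline.image.patient_id

    results = {}
    for label, scan, tp in (
        ("baseline", baseline, Timepoint.BASELINE),
        ("post", post, Timepoint.POST_CYCLE2),
    ):
        lesions = segment_whole_body(
            scan.image,
            exclusion_mask=scan.exclusion_mask,
            liver_mask=scan.liver_mask,
            liver_ref_voi=scan.liver_ref_voi,
            config=config.segmentation,
        )
        logger.info(
            "%s %s: %d lesions, global threshold %.2f, liver threshold %s",
            pid, label, len(lesions), config.segmentation.global_threshold_suv,
            f"{lesions.liver_threshold_used:.2f}" if lesions.liver_threshold_used else "n/a",
        )
        results[label] = (lesions, compute_tlp(lesions, timepoint=tp))

    tlp_b = results["baseline"][1].tlp
    tlp_p = results["post"][1].tlp
    if tlp_b <= 0:
        raise ValueError(f"patient {pid}: baseline TLP is 0, percent change undefined")
    d_tlp = percent_change(tlp_b, tlp_p, BiomarkerVariable.TLP)
    d_psa = percent_change(psa_baseline, psa_post, BiomarkerVariable.PSA)
    pair = ResponsePair.from_deltas(pid, d_tlp.delta_percent, d_psa.delta_percent)

    record = PatientAssessment(
        patient_id=pid,
        tlp_baseline=tlp_b,
        tlp_post=tlp_p,
        dtlp_percent=d_tlp.delta_percent,
        psa_baseline=float(psa_baseline),
        psa_post=float(psa_post),
        dpsa_percent=d_psa.delta_percent,
        molecular=pair.molecular.value,
        biochemical=pair.biochemical.value,
        concordant=pair.concordant,
        lesion_count_baseline=results["baseline"][1].lesion_count,
        lesion_count_post=results["post"][1].lesion_count,
        liver_threshold_baseline=results["baseline"][0].liver_threshold_used,
        liver_threshold_post=results["post"][0].liver_threshold_used,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{pid}_assessment.json").write_text(json.dumps(record.to_dict(), indent=2))
    return record


# ---------------------------------------------------------------------------
# cohort analysis


def _clean(value):
    """Make a number JSON-safe: inf -> 'not_reached', nan -> None."""
    if isinstance(value, (float, np.floating)):
        if math.isinf(value):
            return "not_reached"
        if math.isnan(value):
            return None
        return float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def _km_section(times, events) -> dict:
    km = km_estimate(times, events)
    return {
        "n": km.n,
        "events": km.n_events,
        "median_months": _clean(km.median),
        "median_ci": [_clean(km.median_ci[0]), _clean(km.median_ci[1])],
    }


def run_cohort_analysis(cohort: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Cohort-level statistics on a per-patient table.

    Expects at least ``patient_id``, ``dtlp_percent`` and ``dpsa_percent``
    (or precomputed ``molecular``/``biochemical`` categories); survival and
    covariate columns unlock the corresponding report sections.
    """
    config = config or RunConfig()
    if cohort.empty:
        raise ValueError("empty cohort")
    report: dict = {"provenance": config.provenance(), "n_patients": int(len(cohort))}

    # response pairs and concordance (categories re-derived from the stored deltas)
    if {"dtlp_percent", "dpsa_percent"}.issubset(cohort.columns):
        pairs = [
            ResponsePair.from_deltas(str(r.patient_id), float(r.dtlp_percent), float(r.dpsa_percent))
            for r in cohort.itertuples()
        ]
        summary = cross_tabulate(pairs)
        report["concordance"] = {
            "cross_tab": {
                bio: {mol: int(summary.cross_tab.loc[bio, mol]) for mol in summary.cross_tab.columns}
                for bio in summary.cross_tab.index
            },
            "n_total": summary.n_total,
            "n_concordant": summary.n_concordant,
            "percent_concordant": summary.percent_concordant,
            "n_discordant": summary.n_discordant,
            "percent_discordant": summary.percent_discordant,
        }
        report["response_counts"] = {
            "molecular": pd.Series([p.molecular.value for p in pairs]).value_counts().to_dict(),
            "biochemical": pd.Series([p.biochemical.value for p in pairs]).value_counts().to_dict(),
        }
        cohort = cohort.copy()
        cohort["molecular"] = [p.molecular.value for p in pairs]
        cohort["biochemical"] = [p.biochemical.value for p in pairs]

    # correlations
    corr = {}
    for key, (xcol, ycol) in {
        "baseline": ("tlp_baseline", "psa_baseline"),
        "post": ("tlp_post", "psa_post"),
        "delta": ("dtlp_percent", "dpsa_percent"),
    }.items():
        if {xcol, ycol}.issubset(cohort.columns):
            rho, p = spearman_rho(cohort[xcol], cohort[ycol])
            corr[key] = {"rho": rho, "p_value": p}
    if corr:
        report["spearman"] = corr

    # survival
    if {"os_months", "event"}.issubset(cohort.columns):
        times = cohort["os_months"].to_numpy(float)
        events = cohort["event"].to_numpy(bool)
        n_events = int(events.sum())
        surv: dict = {
            "n_events": n_events,
            "median_follow_up_months": _clean(median_follow_up(times, events)),
            "overall": _km_section(times, events),
        }
        for method in ("molecular", "biochemical"):
            if method not in cohort.columns:
                continue
            pr = cohort[method].astype(str) == "PR"
            sec: dict = {}
            for label, sel in (("PR", pr), ("SD_PD", ~pr)):
                if sel.any():
                    sec[label] = _km_section(times[sel.to_numpy()], events[sel.to_numpy()])
            if pr.any() and (~pr).any():
                lr = logrank_test(times, events, pr.to_numpy())
                sec["logrank"] = {"statistic": lr.statistic, "p_value": lr.p_value}
            surv[f"km_{method}"] = sec

        # Cox modeling on dichotomized covariates
        rules = [r for r in DEFAULT_RULES if r.column in cohort.columns]
        if rules:
            binary = dichotomize(cohort, rules)
            usable = [c for c in binary.columns if 0 < binary[c].sum() < len(binary)]
            data = pd.concat(
                [cohort[["os_months", "event"]].reset_index(drop=True),
                 binary[usable].reset_index(drop=True)],
                axis=1,
            )
            if n_events >= 2 and usable:
                try:
                    screen = univariate_screen(data, usable, p_entry=config.p_entry)
                    surv["univariate"] = {
                        var: {
                            "hazard_ratio": _clean(row["hazard_ratio"]),
                            "ci": [_clean(row["ci_lower"]), _clean(row["ci_upper"])],
                            "p": _clean(row["p"]),
                            "selected": bool(row["selected"]),
                        }
                        for var, row in screen.iterrows()
                    }
                    candidates = list(screen.index[screen["selected"]])
                    if candidates:
                        elim = backward_eliminate(
                            data, candidates, p_removal=config.p_removal
                        )
                        surv["multivariable"] = {
                            "full_model": {
                                var: {
                                    "hazard_ratio": _clean(row["hazard_ratio"]),
                                    "ci": [_clean(row["ci_lower"]), _clean(row["ci_upper"])],
                                    "p": _clean(row["p"]),
                                }
                                for var, row in elim.full_model.summary.iterrows()
                            },
                            "final_model": (
                                {
                                    var: {
                                        "hazard_ratio": _clean(row["hazard_ratio"]),
                                        "ci": [_clean(row["ci_lower"]), _clean(row["ci_upper"])],
                                        "p": _clean(row["p"]),
                                    }
                                    for var, row in elim.final_model.summary.iterrows()
                                }
                                if elim.final_model is not None
                                else None
                            ),
                            "elimination_trace": [
                                {"removed": s.removed, "p_value": s.p_value,
                                 "remaining": list(s.remaining)}
                                for s in elim.trace
                            ],
                        }
                    else:
                        surv["multivariable"] = {"skipped": "no univariate candidates at p < %.2f" % config.p_entry}
                except (ValueError, RuntimeError) as err:
                    surv["cox_skipped"] = str(err)
            else:
                surv["cox_skipped"] = f"insufficient events ({n_events}) for Cox modeling"
        report["survival"] = surv

    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_clean))
    return path
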
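"""Synthetic phantoms and cohorts with recorded ground truth.

The study data this pipeline targets (whole-body PSMA PET scans plus a
per-patient outcome registry) are not publicly available, so every
downstream stage is exercised against generated inputs whose truth is known
exactly:

* **Phantoms** — 3-D SUV grids built from rasterized ellipsoids with uniform
  uptake: a low-uptake background, a physiologically avid liver (handled by
  the elevated liver threshold), high-uptake excluded organs (bladder,
  salivary glands), and tumor lesions.  Because lesions are uniform and the
  background sits below threshold, the analytic lesion table (voxel count,
  volume, SUVmean) is exact and noiseless segmentation must recover it
  voxel-for-voxel.  Optional Gaussian noise is added after rasterization.
* **Paired phantoms** — a baseline/post-treatment pair in which every lesion's
  uptake is scaled by a common factor, so the true TLP percent change equals
  the requested target exactly.
* **Cohorts** — per-patient tables with log-normal baseline TLP and PSA,
  (ΔTLP, ΔPSA) drawn from a Gaussian copula with a target Spearman
  correlation and log-normal ratio marginals, response categories derived
  from the deltas, and exponential overall survival whose rate depends on the
  molecular response group through a configurable true hazard ratio.

Seeds are mandatory; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import LabelMask, MaskRole, SuvImage, Timepoint
from .response import ResponseCategory, classify_biochemical, classify_molecular
from .segmentation import SegmentationConfig

__all__ = [
    "EllipsoidSpec",
    "PhantomSpec",
    "PhantomResult",
    "CohortSpec",
    "default_phantom_spec",
    "generate_phantom",
    "generate_paired_phantoms",
    "generate_cohort",
    "simulate_survival_data",
    "ground_truth_tlp",
]


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid: center in voxel indices, radii in mm, uniform SUV."""

    center: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float

    def __post_init__(self) -> None:
        if self.suv <= 0:
            raise ValueError("ellipsoid SUV must be positive")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("ellipsoid radii must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Layout of one whole-body SUV phantom.

    The liver is rasterized at its physiologic SUV and reported in the liver
    mask (so segmentation applies the elevated liver threshold there); the
    organs in ``exclusion_organs`` go into the exclusion mask.  Lesions may
    overlap the liver (liver metastases) but must not overlap or touch each
    other.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    noise_sd: float = 0.0
    liver: EllipsoidSpec | None = None
    liver_ref_voi: EllipsoidSpec | None = None
    exclusion_organs: tuple[EllipsoidSpec, ...] = ()
    lesions: tuple[EllipsoidSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background SUV and noise sd must be >= 0")


def default_phantom_spec(seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """A realistic-geometry default: liver with physiologic uptake plus a
    liver metastasis, a bone and a nodal lesion, bladder and salivary glands
    as excluded high-uptake sites."""
    return PhantomSpec(
        shape=(48, 48, 48),
        spacing=(4.0, 4.0, 4.0),
        background_suv=1.0,
        noise_sd=noise_sd,
        liver=EllipsoidSpec(center=(14, 14, 28), radii_mm=(30, 26, 22), suv=4.0),
        liver_ref_voi=EllipsoidSpec(center=(12, 12, 26), radii_mm=(6, 6, 6), suv=4.0),
        exclusion_organs=(
            EllipsoidSpec(center=(34, 34, 8), radii_mm=(14, 14, 14), suv=30.0),  # bladder
            EllipsoidSpec(center=(24, 8, 42), radii_mm=(8, 8, 8), suv=12.0),  # salivary
        ),
        lesions=(
            EllipsoidSpec(center=(10, 34, 18), radii_mm=(11, 9, 9), suv=12.0),  # bone
            EllipsoidSpec(center=(36, 12, 30), radii_mm=(7, 7, 7), suv=15.0),  # node
            EllipsoidSpec(center=(17, 17, 31), radii_mm=(6, 6, 6), suv=20.0),  # liver met
        ),
        seed=seed,
    )


@dataclass
class PhantomResult:
    """Generated phantom plus every piece of ground truth a test can need."""

    image: SuvImage
    exclusion_mask: LabelMask
    liver_mask: LabelMask
    liver_ref_voi: LabelMask
    ground_truth: pd.DataFrame  # per-lesion voxel_count, volume_ml, suv_mean, suv_max
    lesion_masks: list[np.ndarray]  # boolean grid per lesion, ground-truth voxel sets
    spec: PhantomSpec


def _rasterize(spec: EllipsoidSpec, shape, spacing) -> np.ndarray:
    """Boolean mask of voxels whose index lies inside the ellipsoid."""
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r, sp in zip(grids, spec.center, spec.radii_mm, spacing):
        acc += ((g - c) * sp / r) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rasterize a phantom; deterministic given ``spec.seed``.

    Lesions that overlap or touch (26-neighbourhood) are rejected: adjacent
    uniform lesions would merge into one connected component and the
    per-lesion ground truth would no longer be recoverable.
    """
    shape, spacing = spec.shape, spec.spacing
    volume = np.full(shape, spec.background_suv, dtype=np.float64)

    liver_mask = np.zeros(shape, dtype=np.int16)
    if spec.liver is not None:
        lm = _rasterize(spec.liver, shape, spacing)
        volume[lm] = spec.liver.suv
        liver_mask[lm] = 1

    exclusion = np.zeros(shape, dtype=np.int16)
    for organ in spec.exclusion_organs:
        om = _rasterize(organ, shape, spacing)
        volume[om] = organ.suv
        exclusion[om] = 1

    ref_voi = np.zeros(shape, dtype=np.int16)
    if spec.liver_ref_voi is not None:
        rv = _rasterize(spec.liver_ref_voi, shape, spacing)
        if not rv.any():
            raise ValueError("liver reference VOI rasterizes to no voxels")
        ref_voi[rv] = 1

    struct26 = ndimage.generate_binary_structure(3, 3)
    lesion_masks: list[np.ndarray] = []
    occupied = np.zeros(shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        m = _rasterize(lesion, shape, spacing)
        if not m.any():
            raise ValueError(f"lesion {i} rasterizes to no voxels")
        if (ndimage.binary_dilation(m, structure=struct26) & occupied).any():
            raise ValueError(f"lesion {i} overlaps or touches another lesion")
        if (m & exclusion.astype(bool)).any():
            raise ValueError(f"lesion {i} overlaps an excluded organ")
        occupied |= m
        lesion_masks.append(m)
        volume[m] = lesion.suv

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volume = np.clip(volume + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None)

    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    rows = []
    for i, (lesion, m) in enumerate(zip(spec.lesions, lesion_masks), start=1):
        centroid = np.argwhere(m).mean(axis=0)
        idx = tuple(int(round(c)) for c in centroid)
        rows.append(
            {
                "lesion_id": i,
                "voxel_count": int(m.sum()),
                "volume_ml": float(m.sum() * voxel_ml),
                "suv_mean": lesion.suv,  # uniform uptake, pre-noise
                "suv_max": lesion.suv,
                "in_liver": bool(liver_mask[idx]),
            }
        )
    ground_truth = pd.DataFrame(
        rows,
        columns=["lesion_id", "voxel_count", "volume_ml", "suv_mean", "suv_max", "in_liver"],
    )

    image = SuvImage(voxels=volume, spacing=spacing, patient_id=f"phantom-{spec.seed}")
    mk = lambda arr, role: LabelMask(voxels=arr, role=role, spacing=spacing)
    return PhantomResult(
        image=image,
        exclusion_mask=mk(exclusion, MaskRole.EXCLUSION),
        liver_mask=mk(liver_mask, MaskRole.LIVER),
        liver_ref_voi=mk(ref_voi, MaskRole.LIVER_REFERENCE_VOI),
        ground_truth=ground_truth,
        lesion_masks=lesion_masks,
        spec=spec,
    )


def ground_truth_tlp(phantom: PhantomResult) -> float:
    """Analytic TLP of the ground-truth lesion table (mL x SUV)."""
    gt = phantom.ground_truth
    return float((gt["volume_ml"] * gt["suv_mean"]).sum())


def generate_paired_phantoms(
    spec: PhantomSpec,
    true_dtlp_percent: float,
    config: SegmentationConfig | None = None,
) -> tuple[PhantomResult, PhantomResult]:
    """Baseline/post pair with an exact target TLP change.

    Lesion geometry is frozen and every lesion's uptake is scaled by
    ``1 + true_dtlp_percent / 100``; since TLP is linear in SUVmean at fixed
    volume, the analytic change equals the target exactly, and threshold
    segmentation sees identical voxel sets on both scans.  Targets that push
    any lesion below its applicable threshold (global, or the liver threshold
    for lesions inside the liver) are infeasible and raise.
    """
    config = config or SegmentationConfig()
    factor = 1.0 + true_dtlp_percent / 100.0
    if factor <= 0:
        raise ValueError("target TLP change must be > -100%")
    if not spec.lesions:
        raise ValueError("paired phantoms need at least one lesion")

    liver_thr = config.liver_factor * spec.liver.suv if spec.liver is not None else None
    baseline = generate_phantom(spec)
    for lesion, row in zip(spec.lesions, baseline.ground_truth.itertuples()):
        applicable = liver_thr if (row.in_liver and liver_thr is not None) else config.global_threshold_suv
        scaled = lesion.suv * factor
        if scaled < applicable:
            raise ValueError(
                f"target {true_dtlp_percent}% scales lesion SUV {lesion.suv} to "
                f"{scaled:.3g}, below its threshold {applicable:.3g}"
            )
        if scaled <= spec.background_suv:
            raise ValueError("scaled lesion uptake would sink into the background")

    post_spec = replace(
        spec,
        lesions=tuple(replace(l, suv=l.suv * factor) for l in spec.lesions),
    )
    post = generate_phantom(post_spec)
    post.image.timepoint = Timepoint.POST_CYCLE2
    baseline.image.timepoint = Timepoint.BASELINE
    return baseline, post


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated patient cohort.

    Baseline TLP/PSA are log-normal around clinically typical medians for
    heavily pretreated metastatic castration-resistant prostate cancer.
    (ΔTLP, ΔPSA) come from a Gaussian copula whose normal scores carry
    Pearson correlation 2·sin(π·rank_correlation/6), so the population
    Spearman correlation equals ``rank_correlation``; each marginal is
    ``100·(R − 1)`` with R log-normal, keeping deltas above −100%.  Overall
    survival is exponential per molecular response group: median
    ``median_os_pr_months`` for partial remission and a hazard
    ``hr_sdpd``-fold higher otherwise, censored by an independent uniform
    follow-up window.
    """

    n: int = 66
    seed: int = 0
    # baseline tumor burden / PSA
    tlp_baseline_median: float = 5710.0
    tlp_baseline_log_sd: float = 1.1
    psa_baseline_median: float = 145.0
    psa_baseline_log_sd: float = 1.5
    baseline_rank_correlation: float = 0.48
    # percent-change model
    dtlp_median_percent: float = -44.0
    dtlp_log_sd: float = 0.8
    dpsa_median_percent: float = -53.0
    dpsa_log_sd: float = 1.0
    rank_correlation: float = 0.7
    # survival model
    median_os_pr_months: float = 24.6
    hr_sdpd: float = 2.76
    censoring_low_months: float = 6.0
    censoring_high_months: float = 42.0
    # baseline covariates
    age_mean: float = 71.0
    age_sd: float = 8.0
    ecog_probs: tuple[float, float, float] = (0.26, 0.47, 0.27)
    hemoglobin_mean: float = 12.0
    hemoglobin_sd: float = 1.6
    alp_median: float = 112.0
    alp_log_sd: float = 0.8
    p_visceral: float = 0.35
    p_prior_chemo: float = 0.71
    activity_mean: float = 14.1
    activity_sd: float = 1.8

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("tlp_baseline_median", "psa_baseline_median", "tlp_baseline_log_sd",
                     "psa_baseline_log_sd", "dtlp_log_sd", "dpsa_log_sd",
                     "median_os_pr_months", "hr_sdpd", "alp_median", "alp_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rank_correlation", "baseline_rank_correlation"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if self.dtlp_median_percent <= -100 or self.dpsa_median_percent <= -100:
            raise ValueError("median percent changes must be > -100")
        if not 0 < self.censoring_low_months < self.censoring_high_months:
            raise ValueError("censoring window must satisfy 0 < low < high")
        if not math.isclose(sum(self.ecog_probs), 1.0, abs_tol=1e-9):
            raise ValueError("ECOG probabilities must sum to 1")


def _copula_pearson(rank_corr: float) -> float:
    # Pearson correlation of normal scores giving the target Spearman rho
    return 2.0 * math.sin(math.pi * rank_corr / 6.0)


def _correlated_normals(rng: np.random.Generator, n: int, rank_corr: float) -> tuple[np.ndarray, np.ndarray]:
    rho = _copula_pearson(rank_corr)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return z1, z2


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table; returns ``(table, true_parameters)``.

    The table has one row per patient with baseline/post TLP and PSA, percent
    changes, response categories, baseline covariates, and (os_months, event).
    ``true_parameters`` records every generating value a downstream stage
    could try to recover.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    zb1, zb2 = _correlated_normals(rng, n, spec.baseline_rank_correlation)
    tlp_baseline = spec.tlp_baseline_median * np.exp(spec.tlp_baseline_log_sd * zb1)
    psa_baseline = spec.psa_baseline_median * np.exp(spec.psa_baseline_log_sd * zb2)

    zd1, zd2 = _correlated_normals(rng, n, spec.rank_correlation)
    ratio_tlp = (1.0 + spec.dtlp_median_percent / 100.0) * np.exp(spec.dtlp_log_sd * zd1)
    ratio_psa = (1.0 + spec.dpsa_median_percent / 100.0) * np.exp(spec.dpsa_log_sd * zd2)
    dtlp = 100.0 * (ratio_tlp - 1.0)
    dpsa = 100.0 * (ratio_psa - 1.0)

    molecular = np.array([classify_molecular(d).value for d in dtlp])
    biochemical = np.array([classify_biochemical(d).value for d in dpsa])

    lam_pr = math.log(2.0) / spec.median_os_pr_months
    lam = np.where(molecular == ResponseCategory.PR.value, lam_pr, lam_pr * spec.hr_sdpd)
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(spec.censoring_low_months, spec.censoring_high_months, size=n)
    os_months = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "tlp_baseline": tlp_baseline,
            "tlp_post": tlp_baseline * ratio_tlp,
            "dtlp_percent": dtlp,
            "psa_baseline": psa_baseline,
            "psa_post": psa_baseline * ratio_psa,
            "dpsa_percent": dpsa,
            "molecular": molecular,
            "biochemical": biochemical,
            "os_months": os_months,
            "event": event,
            "age": np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 40.0, 95.0),
            "ecog": rng.choice(3, size=n, p=spec.ecog_probs),
            "hemoglobin": np.clip(rng.normal(spec.hemoglobin_mean, spec.hemoglobin_sd, n), 5.0, 18.0),
            "alp": spec.alp_median * np.exp(spec.alp_log_sd * rng.standard_normal(n)),
            "visceral_metastases": rng.random(n) < spec.p_visceral,
            "prior_chemotherapy": rng.random(n) < spec.p_prior_chemo,
            "cumulative_activity": np.clip(rng.normal(spec.activity_mean, spec.activity_sd, n), 9.0, 19.4),
        }
    )
    true_params = asdict(spec)
    true_params["copula_pearson"] = _copula_pearson(spec.rank_correlation)
    true_params["hazard_pr_per_month"] = lam_pr
    return df, true_params


def simulate_survival_data(
    n: int,
    seed: int,
    hazard_ratios: dict[str, float] | None = None,
    baseline_median_months: float = 18.0,
    censoring_months: tuple[float, float] | None = None,
    covariate_prevalence: float = 0.5,
) -> pd.DataFrame:
    """Exponential survival data with independent binary covariates.

    Each covariate in ``hazard_ratios`` multiplies the hazard by its ratio
    when present; covariates absent from the dict (value 1.0) are pure noise.
    With no censoring window every time is an event — handy for checking the
    product-limit median against the closed form median = ln 2 / rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hazard_ratios = hazard_ratios or {}
    lam0 = math.log(2.0) / baseline_median_months
    lam = np.full(n, lam0)
    df = pd.DataFrame(index=range(n))
    for name, hr in hazard_ratios.items():
        if hr <= 0:
            raise ValueError(f"hazard ratio for {name!r} must be positive")
        x = (rng.random(n) < covariate_prevalence).astype(int)
        df[name] = x
        lam = lam * np.where(x == 1, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    if censoring_months is not None:
        lo, hi = censoring_months
        c = rng.uniform(lo, hi, size=n)
        df["os_months"] = np.minimum(t, c)
        df["event"] = t <= c
    else:
        df["os_months"] = t
        df["event"] = True
    return df
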
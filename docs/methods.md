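# Methods

## Problem and model

`psmatlp` implements early molecular-imaging response assessment for
PSMA-targeted radioligand therapy of metastatic castration-resistant
prostate cancer (mCRPC). A patient is scanned with a PSMA-ligand PET before
the first and after the second therapy cycle; on each scan the whole-body
viable tumor burden is quantified as **total lesion PSMA**

TLP = Σ_i V_i · SUVmean_i   [mL × SUV],

the sum over all segmented lesions of lesion volume times lesion mean
standardized uptake value. Response is the percent change
ΔTLP = 100·(TLP_post − TLP_base)/TLP_base, classified PERCIST-style
(PR: ΔTLP < −30%; PD: ΔTLP > +30%; SD otherwise), and compared with
biochemical response from serum PSA under simplified PCWG3 rules
(PR: ΔPSA < −50%; PD: ΔPSA > +25%; SD otherwise). Boundary values are SD in
both systems because the defining inequalities are strict. Downstream, the
cohort analysis relates the response dichotomy (PR vs SD/PD) and
dichotomized baseline covariates to overall survival.

## Segmentation

Tumor candidates are voxels with SUV ≥ 3.0 (body-weight SUV assumed; the
normalization is not configurable because nothing downstream depends on
it). Because liver parenchyma takes up PSMA ligands physiologically, voxels
inside a caller-supplied liver mask must instead exceed
1.5 × SUVmean of a healthy-liver reference VOI; the reference VOI is a
required input whenever a liver mask is given (an empty VOI is an error
rather than a silent fallback — SUV ≥ 3 inside the liver would flood the
organ). Other physiologic sites (salivary glands, vocal cords, spleen,
intestine, ureter, bladder) are removed with an exclusion mask whose
content is entirely caller-defined; no organ list is hard-coded.

Candidates are grouped into connected components. Connectivity defaults
to 26 (faces + edges + corners) and is configurable (6/18/26) because the
neighbourhood rule of commercial segmentation tools is unpublished; the
choice is recorded in the output provenance. There is no minimum lesion
size by default; `min_lesion_volume_ml` exists for noise robustness. All
threshold comparisons are inclusive (≥). A lesion straddling the liver
boundary is segmented with the per-voxel threshold map as-is; its
`in_liver` flag is determined by the rounded centroid only. Lesion ids are
assigned by descending volume with lexicographic centroid tie-break, making
the output independent of component traversal order.

Masks must share the exact voxel grid of the SUV image; no resampling is
performed. Input is assumed SUV-calibrated; negative voxels are rejected,
not clamped. Activity-to-SUV conversion and inter-timepoint registration
are out of scope.

## Statistics

* ΔTLP/ΔPSA are computed from exact stored values and never rounded before
  classification, avoiding boundary artifacts.
* Spearman rank correlation uses average ranks for ties and a two-sided
  t-approximation p-value (n > 2). Constant input raises.
* Kaplan–Meier curves use the product-limit estimator; the median is the
  earliest time the curve drops to ≤ 0.5, with a 95% CI from the log-log
  (exponential Greenwood) confidence band. An unreached median is reported
  as infinite / `"not_reached"`, never as a number.
* Median follow-up is the reverse Kaplan–Meier median (event indicator
  flipped).
* Cox proportional-hazards fits use Efron tie handling and per-coefficient
  Wald CIs and p-values (via lifelines). Perfectly collinear designs and
  non-convergence raise explicit errors.
* Covariate dichotomization uses fixed clinical cutoffs — age ≥ 65 years,
  ECOG ≥ 2, hemoglobin < 13 g/dL, ALP ≥ 220 U/L, baseline TLP ≥ 5710
  mL × SUV, baseline PSA ≥ 145 ng/mL, cumulative activity ≤ 14 GBq — with
  the indicator set to 1 on the risk level exactly as those labels read
  (so hemoglobin 13.0 falls in the "≥ 13" reference level, ALP 220 in the
  "≥ 220" risk level).
* The modeling workflow is a univariate Cox screen with entry at p < 0.1,
  then backward elimination at a removal threshold of p ≥ 0.05. The removal
  threshold is a design choice (only the entry rule is standard); both the
  full entry model and the pruned final model are reported, together with
  the step-by-step elimination trace, because published multivariable
  tables often print coefficients for eliminated variables.

## Synthetic data

No patient data ship with the package; generators provide inputs with
exact, recorded ground truth.

**Phantoms** are rasterized axis-aligned ellipsoids with uniform uptake on
a low background: a liver at physiologic SUV 4.0 containing the reference
VOI, a bladder (SUV 30) and salivary gland (SUV 12) destined for the
exclusion mask, and tumor lesions (default bone SUV 12, nodal SUV 15,
liver metastasis SUV 20 — the liver lesion is hotter so that deep response
targets keep it above the 6.0 liver threshold). Uniform uptake keeps the
analytic lesion table exact: with zero noise, segmentation must recover
every ground-truth voxel set identically, and measured TLP equals
Σ V·SUVmean to floating-point precision. Lesions may not overlap or touch
(they would merge into one component). Optional Gaussian noise (clipped at
0) is added after rasterization; Poisson reconstruction physics and
anatomical realism are non-goals. Paired baseline/post phantoms freeze the
geometry and scale every lesion's uptake by 1 + ΔTLP/100, so the true
change equals the target exactly; targets that would push a lesion below
its applicable threshold are rejected as infeasible.

**Cohorts** emulate the summary statistics of a 66-patient PSMA-therapy
registry population. Baseline TLP and PSA are log-normal with medians 5710
mL × SUV and 145 ng/mL. (ΔTLP, ΔPSA) are generated through a Gaussian
copula whose normal scores carry Pearson correlation 2·sin(π·ρ_S/6), making
the population Spearman correlation exactly the target (default 0.7);
marginals are 100·(R − 1) with R log-normal (medians −44% and −53%, log-sds
0.8 and 1.0), which keeps deltas above −100% and yields response fractions
near the observed ones (molecular PR/SD/PD ≈ 0.61/0.25/0.15 vs observed
0.61/0.29/0.11). Overall survival is exponential per molecular response
group — median 24.6 months for PR, hazard multiplied by a true HR (default
2.76) for SD/PD — censored by an independent Uniform(6, 42)-month follow-up
window (≈ 40% censoring, median follow-up ≈ 24 months). Covariates (age,
ECOG, hemoglobin, ALP, visceral metastases, prior chemotherapy, cumulative
activity) are drawn independently from clinically plausible distributions;
they carry no survival effect of their own, so the generator's only true
prognostic factor is the response group. Seeds are mandatory and all
generation is deterministic given the spec.

What passing tests show — and don't: the phantoms demonstrate correctness
of the segmentation/TLP arithmetic, not robustness to real PET texture,
partial-volume effects or registration error; the cohorts demonstrate that
the estimators recover known generating parameters, not that the clinical
effect sizes themselves generalize.

## Verification strategy and problem sizes

Segmentation is validated voxel-exactly against an independent brute-force
oracle (exhaustive threshold scan + BFS flood fill, pure Python) on 50
random grids up to 20³. Survival routines are checked against closed forms
and hand computations: the product-limit median of an uncensored odd
sample, the exponential median ln 2/λ at n = 10 000 (±0.5 months), reverse
KM on a six-subject toy dataset, Cox recovery of a true HR 2.0 at n = 5000
(within [1.9, 2.1]; the estimator is unbiased, with ≈ 3.5% standard error
at this size), and a 100-replicate backward-elimination study (n = 1000
each) in which the true HR-3 effect must be retained and the noise
covariate dropped in ≥ 95% of runs — the noise covariate is retained with
probability ≈ 0.05 by construction, so this bound sits at the nominal
type-I level. Copula correlation recovery uses n = 5000 (sampling sd of
rho ≈ 0.007 at ρ = 0.7). These sizes keep the full suite around a minute
on one CPU while leaving comfortable statistical margins.

## Known limitations

* No DICOM input, no SUV computation from raw activity, no registration.
* New-lesion rules (full PERCIST), PCWG3 confirmation requirements, PSMA
  PET Progression criteria and RECIST are intentionally not implemented.
* A patient with baseline TLP of 0 (no segmentable disease) has undefined
  ΔTLP and is rejected upstream rather than classified.
* ECOG enters the survival analysis only as the dichotomy ≥ 2; no ordinal
  modeling.
* Time-varying covariates, competing risks and propensity adjustment are
  out of scope.
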
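# psmatlp

Whole-body tumor-burden quantification and response assessment for
PSMA-targeted radioligand therapy of metastatic castration-resistant
prostate cancer (mCRPC), from PET volume to survival model.

Patients under PSMA radioligand therapy are monitored with PSMA-ligand PET
before the first and after the second cycle. `psmatlp` quantifies each scan
by **total lesion PSMA**,

```
TLP = Σ_i V_i · SUVmean_i        [mL × SUV]
```

summing volume × mean uptake over all lesions found by SUV-threshold
segmentation (SUV ≥ 3 globally; 1.5 × healthy-liver SUVmean inside the
liver; physiologic-uptake organs excluded by mask). Molecular response is
the percent change ΔTLP classified PERCIST-style (PR < −30% < SD < +30% < PD),
compared against biochemical PCWG3 PSA response (PR < −50% < SD < +25% < PD),
with per-patient concordance, Spearman correlations, Kaplan–Meier /
log-rank comparisons, and univariate-then-backward-eliminated Cox models
for overall survival. Because registry imaging data are not public, the
package ships generators for SUV phantoms and cohort tables with exact
ground truth. It is aimed at nuclear-medicine researchers evaluating
PET-derived response biomarkers.

## Worked example

```python
import psmatlp as p

# baseline / post-cycle-2 phantom pair with a true TLP decline of 67%
base, post = p.generate_paired_phantoms(p.default_phantom_spec(seed=1), -67.0)

record = p.run_patient_assessment(
    p.ScanInputs(base.image, base.exclusion_mask, base.liver_mask, base.liver_ref_voi),
    p.ScanInputs(post.image, post.exclusion_mask, post.liver_mask, post.liver_ref_voi),
    psa_baseline=100.0, psa_post=16.0,
)
print(record.tlp_baseline, record.tlp_post)
print(record.dtlp_percent, record.molecular)
print(record.dpsa_percent, record.biochemical, record.concordant)
```

prints

```
100.16 33.0528
-67.0 PR
-84.0 PR True
```

The baseline scan holds 100.2 mL × SUV of tumor burden across three
lesions (bone, node, liver metastasis; the liver lesion is segmented
against the 6.0 = 1.5 × 4.0 liver threshold). TLP falls by exactly the
generated 67%, a decline > 30%, so molecular response is partial remission
(PR); the PSA drop of 84% exceeds 50%, so biochemical response is also PR
and the two assessments are concordant.

The same stages are available from the shell:

```sh
psmatlp simulate-phantom --out phantom/ --seed 1
psmatlp segment phantom/suv.nii.gz --exclusion-mask phantom/exclusion.nii.gz \
        --liver-mask phantom/liver.nii.gz --liver-ref-voi phantom/liver_ref_voi.nii.gz \
        --out lesions.csv
psmatlp tlp lesions.csv
psmatlp simulate-cohort --out cohort.csv --n 66 --seed 1
psmatlp survival cohort.csv --out report.json
```

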
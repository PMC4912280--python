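# neckquant

Volumetric neck anthropometry from CT, for radiology and body-composition
researchers: **neck adipose tissue volume (NATV)**, **airway volume (AWV)**,
**neck cross-sectional areas (NCSA)**, and the prognostic **NAT:AWV** ratio
— plus the complete cohort statistics used to validate and apply them
(interobserver agreement, correlation with BMI, WHO-class comparison,
quartile-stratified survival).

Because real neck CTs of a study cohort are not distributable, the package
ships a first-class **synthetic phantom generator** whose fat, airway, and
body geometry have closed-form volumes, so every stage of the pipeline is
validated against analytic ground truth.

## The measurements

On a calibrated HU volume with landmark levels (mm) supplied as JSON:

* **NATV** — volume (cc) of voxels with HU in the closed adipose window
  **[−150, −30]** (centre −90 HU), inside the anatomic crop box: roof of
  the orbits → sternal angle cranio-caudally, mid-clavicular lines
  laterally.
* **AWV** — volume (cc) of the 26-connected air component (HU ≤ −500)
  grown from a seed in the lumen, clipped from the hard palate down to and
  including the first tracheal ring.
* **NCSA** — mean filled body-contour area (mm²) over a 5 mm axial slab at
  the soft-palate and thyroid-cartilage levels (largest 8-connected
  component after hole filling, so the airway and enclosed fat count and
  ear-like satellites do not).
* **NAT:AWV** = NATV / AWV, the prognostic index; cohorts are stratified
  into the upper quartile vs the lower three, compared by Kaplan–Meier /
  log-rank, and quantified by Cox regression (Breslow ties, Newton
  iteration), crude and age/sex-adjusted.

See `docs/methods.md` for conventions, parameter defaults, and limitations.

## Worked example

Generate an "obese-class" phantom, measure it, and compare with its
analytic ground truth:

```bash
neckquant phantom --size-class obese --seed 42 --out phantom42
neckquant quantify --ct phantom42/volume.nii.gz \
    --landmarks phantom42/landmarks.json --id obese42 --out results.csv
cat results.csv
```

```
patient_id,natv_cc,awv_cc,ratio,ncsa_upper_mm2,ncsa_lower_mm2
obese42,896.714,23.232,38.6,22172.0,22172.0
```

The phantom's manifest (`phantom42/ground_truth.json`) lists the analytic
values: fat 889.36 cc, airway 22.99 cc, body cross-section 22 154.9 mm².
The measured NATV (896.7 cc) is within 0.9 % of the analytic fat volume,
AWV within 1.1 %, NCSA within 0.1 % — voxelization error only.

Cohort analysis on a simulated 519-patient table with a hazard ratio of 2
planted on the upper NAT:AWV quartile:

```bash
python -c "import numpy as np, neckquant as nq; \
  nq.simulate_cohort(n=519, seed=11, planted='quartile', \
  log_hr=np.log(2.0)).to_csv('cohort.csv', index=False)"
neckquant analyze --cohort cohort.csv --out report
cat report/report.txt
```

```
neckquant cohort analysis (n = 519)

Correlations (Spearman):
  natv_vs_bmi: rho = 0.608, p = 8.79e-54
  awv_vs_bmi: rho = 0.0312, p = 0.4781

NAT:AWV upper-quartile threshold = 37.74
  upper: 130 patients, 12 deaths
  lower: 389 patients, 18 deaths
  log-rank chi2 = 3.446, p = 0.0634

Cox proportional hazards:
  ratio_per_unit_crude: HR = 0.9973 (95% CI 0.9822..1.013), p = 0.7306
  ratio_per_unit_adjusted: HR = 0.9987 (95% CI 0.9832..1.014), p = 0.8656
  upper_quartile_crude: HR = 1.972 (95% CI 0.9496..4.094), p = 0.06857
  upper_quartile_adjusted: HR = 2.085 (95% CI 1.002..4.34), p = 0.0495
```

The upper quartile holds 130 of 519 patients; the crude quartile hazard
ratio (1.97) recovers the planted effect of 2 within its confidence
interval.  NATV correlates strongly with BMI while AWV does not — the
pattern the ratio exploits.

The same measurements are available as library calls (`quantify_scan`,
`run_cohort_analysis`, ...); the CLI is a thin wrapper and produces
identical numbers.

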
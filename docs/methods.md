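# Methods

## The measurement problem

Neck adipose tissue volume (NATV) is a compact CT-derived proxy for visceral
adiposity, and its ratio to the airway lumen volume (AWV) — NAT:AWV — has
been proposed as a prognostic index for all-cause mortality.  `neckquant`
implements the whole measurement and analysis chain as deterministic,
testable code: tissue segmentation by Hounsfield-unit (HU) thresholding,
volumetry inside anatomic margins, cross-sectional areas on thick slabs, and
the cohort statistics (interobserver agreement, correlation, stratification,
survival).

## Tissue definitions

* **Adipose tissue** is the closed HU interval **[−150, −30]** (centre
  −90 HU).  Both boundaries are inclusive: a voxel at exactly −150 HU is
  fat, one at −151 HU is not.  The interval reading is the only one
  consistent with a stated window centre of −90 HU.
* **NATV crop box**: fat is counted only where the voxel centre lies between
  the roof of the orbits (cranial) and the sternal angle (caudal) in z, and
  between the two mid-clavicular lines in x.  Landmarks are physical mm
  coordinates supplied as JSON; automatic landmark detection is out of
  scope.
* **Airway lumen**: the 26-connected component of {HU ≤ −500} containing a
  user-supplied seed point, clipped to slices whose centres lie in the
  closed interval [first tracheal ring, hard palate].  −500 HU separates
  lumen (≈ −1000 HU) from every soft tissue with a wide margin on both
  sides; the clip alone realises the exclusion of the oropharynx and of the
  trachea below the first ring.  A seed outside air density is an error, not
  a silent empty mask.
* **Body contour (NCSA)**: per axial slice, threshold at −20 HU, fill
  interior holes, then keep the largest 8-connected component.  Filling
  *before* selecting the component is deliberate: subcutaneous fat enclosed
  by skin, and the airway lumen, are interior regions and must count toward
  the neck's cross-sectional area, while small disconnected components
  (ear-like satellites) are dropped — the automated counterpart of manually
  excluding ear cartilage.  The alternative reading (exclude internal air)
  was rejected; the filled-contour semantics is flagged as a convention.

Threshold ordering is enforced globally:
`air (−500) < fat low (−150) < fat high (−30) < tissue (−20)`.

## Quantities

* Volumes are `true-voxel count × voxel volume`, reported in cc
  (1 cc = 1000 mm³).
* **NCSA** on a slab of thickness 5 mm (default) is the **mean** per-slice
  contour area in mm² — an areal quantity read from a thick slice, not a sum.
  A slab is the set of slices whose centres fall in the closed interval
  `[level − t/2, level + t/2]`.
* **NAT:AWV** is NATV/AWV, full precision internally, 1 decimal in formatted
  output rows.  AWV = 0 is an error, never a silent infinity.
* A failed stage aborts the whole per-scan measurement (`StageError` naming
  the stage); partial rows would silently corrupt cohort tables.

## Axis and file conventions

Arrays are `(x, y, z)` with axis 2 cranio-caudal, increasing index =
cranial.  NIfTI files are reoriented to closest-canonical RAS+ on load,
which guarantees that convention; the header zooms give spacing in mm.
DICOM series are read-only; HU = `RescaleSlope × stored + RescaleIntercept`,
and missing rescale tags are a calibration error rather than a guess.
Voxel *centres* sit at `origin + index × spacing`; all interval tests
(crop, clip, slab) are closed with a 1e-9 slack so landmarks placed exactly
on a boundary behave predictably.

## Synthetic phantoms

Phantoms stack analytic solids into a −1000 HU background, innermost last:
a soft-tissue (+40 HU) elliptic-cylinder body, fat compartments (−90 HU) —
a subcutaneous annular shell plus posterior and perivertebral ellipsoids —
an optional bone cylinder (+700 HU), and a straight airway tube (−1000 HU)
along z.  A straight tube was chosen over a curved one because its volume is
exactly `π r² L`; curvature adds realism but no additional test power for
threshold-plus-connectivity segmentation.

* **Membership is by voxel-centre inclusion** (no partial-volume
  weighting), so closed-form volumes (ellipsoid 4/3·π·abc, cylinder
  π·a·b·h, shell π·(a_o b_o − a_i b_i)·h) are exact oracles up to a surface
  term.  Empirically, at 1 mm isotropic spacing and structure radii
  ≥ 20 mm, the worst relative voxelization error across the validation
  suite is ≈ 1.2 % (the airway disc cross-section; lattice-count
  fluctuation), fat ellipsoids ≤ 0.1 %, body cross-sections ≤ 0.1 %.
* **Noise** is additive Gaussian on the HU grid, clipped to [−1024, 3071]
  (the CT representable range), seeded and reproducible.  Ground-truth
  masks are geometric and therefore unchanged by noise.  The default noise
  for cohort-like phantoms is 15 HU, a typical soft-tissue noise level for
  neck MDCT; the validation suite is also exercised at 20 HU, where fat at
  −90 HU sits 3 SD from both window edges and volume errors stay below 2 %.
* **Cohort phantoms** (`default_cohort_spec`) target the median NATV per
  WHO BMI class observed clinically — 444 / 689 / 864 cc for
  lean / overweight / obese — drawn within ±5 % of the anchor and split
  65 / 20 / 15 % across the subcutaneous shell and the posterior and
  perivertebral ellipsoids; shell thickness and ellipsoid z-extents are
  solved in closed form so the analytic total is exact.  Body girth
  (±5 %) and airway calibre (7–9 mm radius, AWV ≈ 18–30 cc around the
  clinical mean of ~24 cc) vary per subject so that cohort-level
  correlations (NATV–NCSA, ratio spread) are non-degenerate.  The body
  cross-section (~2.2·10⁴ mm²) matches the reported upper-neck NCSA scale.
* What the phantoms do **not** emulate: partial-volume blur, beam
  hardening, metal artifacts, contrast enhancement, anatomic curvature, and
  inter-slice motion.  Passing the phantom suite therefore demonstrates
  correctness of the geometry, thresholding, connectivity, clipping, and
  unit arithmetic — not robustness to scanner physics.

## Statistics

* **ICC** is fixed to the two-way random, absolute-agreement,
  single-measures form ICC(A,1) (McGraw & Wong):
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + k/n (MS_C − MS_E))`, with the
  F-based 95 % CI.  A fully degenerate table (all values identical) reports
  ICC = 1 by convention with a warning.
* **Bland–Altman**: bias = mean(obs1 − obs2), limits of agreement
  bias ± 1.96·SD; fixed bias tested by one-sample t (p = 1 at zero-variance
  zero bias, 0 at zero-variance nonzero bias, by convention).  The percent
  discrepancy is defined here as `100 × |bias| / grand mean of all
  measurements`; the source reports such percentages without a formula and
  with mutually inconsistent values, so the definition is fixed and
  documented rather than reverse-engineered.
* **Group comparison** is Mann–Whitney U for two groups (exact p where
  SciPy's exact method applies, tie-corrected asymptotic otherwise) and
  Kruskal–Wallis for three or more; an all-tied sample reports statistic 0,
  p = 1 by convention.
* **Quartile split**: threshold = 75th percentile with linear
  interpolation; values ≥ threshold are "upper quartile".  At n = 519 this
  puts 130 subjects in the upper group.
* **Log-rank** is the classic observed-minus-expected chi-square with
  hypergeometric variance, implemented directly (and equal to `lifelines`'
  statistic to machine precision in tests).
* **Cox regression** maximises the Breslow-ties partial likelihood by
  Newton iteration with step halving; Breslow was chosen because it is the
  simplest fully specifiable tie convention, and the tie method is recorded
  in the fit metadata.  Diverging coefficients (monotone likelihood /
  perfect separation) raise a convergence error; Wald CI bounds that would
  overflow (a group with no events) are reported as infinity.  Estimates
  match `lifelines` (Efron) on tie-free data to ≤ 1e-5.  Crude and
  age/sex-adjusted models are reported for the ratio per unit and for
  upper-quartile membership.
* **ICC sample size** searches for the smallest n whose *expected* 95 % CI
  width at the target ICC, via the F-based interval
  (`F_exp = (1 + (k−1)ρ)/(1−ρ)` with (n−1, (n−1)(k−1)) df), is at most the
  requested width.  For ICC 0.9, width 0.1, k = 2 this yields **n = 62**;
  legacy planning software prints 61 for the same inputs with an
  unspecified formula — the one-subject difference is a method artifact,
  and the method used is recorded in the output.
* All tests are two-sided; α = 0.05 is reported but never used to suppress
  or gate any output.

## Cohort simulation

`simulate_cohort` draws BMI and NATV from a shared latent factor (latent
correlation 0.672, Spearman ≈ 0.6), AWV independent of BMI
(N(23.6, 8.1) cc, floored at 5 cc), ages N(57, 18) clipped to [18, 95], and
54.8 % male.  Survival is exponential with the hazard planted on nothing,
on the ratio per unit, or on upper-quartile membership; the baseline hazard
is solved by root finding so the expected event fraction under
Uniform(250, 670)-day censoring matches the target (default 35/519), making
the event rate a controlled condition rather than a tuning knob.

## Problem sizes used in validation

The volume-recovery suite uses ten 180×160×180 phantoms at 1 mm isotropic
spacing (noiseless and at 20 HU noise).  The end-to-end determinism check
uses seventy cohort phantoms voxelized at 2 mm isotropic spacing — byte
identity is a property of the code path, not of resolution — quantified and
analysed twice through the CLI.  Cox calibration uses 20 recovery
replicates and 200 null replicates at n = 1000 with ~40 % events.  The
recovery acceptance band (|β̂ − 0.7| ≤ 0.15 in ≥ 18/20 runs) is
intrinsically tight: with ~400 events the sampling SD of β̂ is ≈ 0.11, so
0.15 is ≈ 1.4 SD and the expected hit count is ≈ 17–18 of 20; the band is
kept as specified rather than widened.

## Known limitations

* No automatic landmark detection; landmark quality bounds measurement
  quality exactly as manual level selection does on a workstation.
* Segmentation is pure thresholding + connectivity; contrast-filled vessels
  within the fat window, brown/white fat discrimination, and metal-artifact
  recovery are out of scope.
* DICOM support assumes one axial series with consistent orientation;
  gantry-tilted or multi-frame series are not handled.
* The phantom validation bounds quantify voxelization error only; clinical
  accuracy additionally depends on scanner calibration and patient factors
  the phantoms do not model.
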
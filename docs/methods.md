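# Methods

`netmtv` implements the quantitative chain used to prognosticate peptide
receptor radionuclide therapy (PRRT) outcomes in somatostatin-receptor
(SSTR) positive neuroendocrine tumors: PET-based molecular tumor volume
(MTV) quantification, volumetric response classification, a composite
MTV / chromogranin A tumor-burden score, and the survival models that
link these markers to overall survival (OS). Because no patient data
ship with the package, every stage is exercised on synthetic inputs
with known ground truth; this note records the models, the defaults and
the reasoning behind the open design choices.

## MTV segmentation

A PET volume is a 3D grid of body-weight-normalized standardized uptake
values (SUV, dimensionless; tissue density taken as 1 g/ml, inputs
assumed decay-corrected). Healthy-liver uptake is measured in a 5 ml
spherical VOI; pathologic SSTR expression is any voxel with

    SUV > 1.5 * SUVmean_liver + 2 * SD_liver

The inequality is strict ("higher than"): voxels exactly at the
threshold are background. Supra-threshold voxels are grouped into
connected components and the surviving components' volumes sum to the
total MTV.

Numerical choices:

- **VOI membership** — a voxel belongs to a sphere iff its *center* is
  inside the radius. No partial-volume weighting: the rule is exactly
  reproducible and its voxelization error (one surface shell,
  `4*pi*r^2*spacing`) is quantified in the tests instead of hidden.
- **SD convention** — sample SD (n−1) inside VOIs and in z-scores,
  matching common workstation and statistics-package behavior; the VOI
  statistic records its `ddof` so the choice is auditable.
- **Connectivity** — 26-neighborhood by default (a single seed click on
  a workstation grows through diagonal contacts), 6-neighborhood
  available. Component labeling is delegated to `scipy.ndimage.label`;
  a brute-force flood fill in the test suite confirms agreement.
- **Physiological exclusion** — the physician who removes kidneys,
  pituitary and other physiological uptake is emulated by a
  caller-supplied mask; a component is dropped when more than 50% of
  its voxels fall inside the mask (fraction configurable). Dropped
  components are counted, not silently discarded.
- **Minimum lesion size** — default 0 (no minimum). Analyses on noisy
  phantoms pass `min_lesion_ml=0.5` to suppress isolated
  noise voxels that survive the ~3.9-sigma liver threshold; with
  roughly 10^5 liver voxels a handful of such specks is expected.
- **Largest-lesion tie-break** — by volume, then higher SUVmax, then
  lexicographically smallest voxel index: deterministic across runs.
- **Coordinates** — physical mm, origin at the corner of voxel
  (0,0,0), axis order = array axes. NIfTI-1 is the interchange format
  (spacing from the header).

One deliberate simplification: the clinical tool grew regions from
user clicks, whereas `segment_mtv` thresholds globally and labels
components. On phantoms the two coincide; on real data global
thresholding can pick up foci a reader never clicked, which is why the
exclusion mask and `min_lesion_ml` exist.

## Response classification

Early response is the relative MTV change between baseline and the
interim scan after two therapy cycles:
reduction of more than 73% → partial response (PR); increase of more
than 63% → progressive disease (PD); otherwise stable disease (SD).
Both boundaries belong to SD (the criteria say "more than"); the
boundary behavior is pinned by tests. PR and SD are responders, PD is
the non-responder class. A zero-baseline MTV raises an error rather
than returning a label — relative change is undefined there and the
caller must decide.

## Composite biomarker

MTV and chromogranin A (CgA) both measure tumor burden — one by image,
one by blood — and are strongly correlated; individually their hazards
are not proportional over follow-up. The composite averages their
z-standardized natural logs:

    composite_i = 0.5 * [ z(ln MTV_i) + z(ln CgA_i) ]

- Natural log: the base is irrelevant (a base change is an affine map
  absorbed by the z-step), which the tests verify.
- Log before z: both markers are right-skewed over orders of magnitude;
  standardizing raw values would let a single large tumor dominate the
  cohort SD. The skewness rationale only makes sense applied to the
  log scale.
- Consequences, both tested: the composite is invariant to the units of
  either marker, symmetric in its arguments, and has cohort mean 0.
  Its cohort SD is `sqrt((1+rho)/2)` < 1, so hazard ratios for the
  composite are reported per SD where comparability matters.

## Survival layer

- **Cox regression** (`lifelines.CoxPHFitter` behind `fit_cox`): Efron
  tie handling, Wald CIs and p-values, α=0.05 two-sided throughout, no
  multiplicity correction. Degenerate designs (no events, constant
  covariates, separation) raise typed errors. A warning is logged when
  events < 10 per covariate.
- **Proportional-hazards diagnostics** — implemented in-package: at
  each event time the Schoenfeld residual is the covariate of the
  failing subject minus the risk-set weighted mean; scaled residuals
  `d * S V` (V the coefficient covariance) are score-tested against
  centered event times (identity transform),
  `T_j = (g' S*_j)^2 / (d V_jj g'g)`, chi-squared with 1 df. The
  implementation is cross-checked against an independent one
  (`lifelines.statistics.proportional_hazard_test`) to 1e-6 in the
  tests. Under proportional hazards the test rejects at ~5%; against a
  sign-reversing effect at n=500 its power exceeds 80% (both measured).
- **Kaplan-Meier / log-rank** via lifelines; `survival_at` uses the
  right-continuous step convention. With no censoring KM equals the
  empirical survival function exactly (tested).
- **Fixed-horizon ROC** (default horizon 60 months = 5-year OS): death
  at or before the horizon is a case, follow-up beyond it a control,
  censored-before-horizon patients are excluded — the simplest
  dichotomization consistent with "5-year survival" grouping, at the
  cost of discarding early-censored patients (a time-dependent ROC
  estimator is out of scope). AUC is the empirical rank statistic
  (ties count 1/2), so it is exactly invariant under strictly monotone
  marker transforms. The operating cutoff maximizes Youden's J with
  ties broken toward higher specificity. The AUC CI is DeLong
  (implemented in-package, placement-value form); arms smaller than 10
  fall back to a 2000-rep seeded percentile bootstrap.
- **Mann-Whitney U** via `scipy.stats.mannwhitneyu`, two-sided.

## Synthetic data

The generators define the study conditions; fixtures never ship as
files.

**Phantoms** (`generate_phantom`): background SUV 1.0; a liver block
filled with Gaussian uptake, mean 4.41 / SD 1.14 (the cohort liver
scale); spherical lesions at SUV 12 (the cohort tumor SUVmean scale);
optional physiological spheres (e.g. SUV 20, kidney-like) flagged in
the exclusion mask; negative noise clipped at 0. The default lesion has
radius 25 mm = 65.45 ml. `generate_interim_phantom` scales each
lesion's radius by `factor^(1/3)` so its volume scales by `factor`,
enabling end-to-end response tests (factor 0.2 → PR, 1.0 → SD,
2.0 → PD, with margin to the −73/+63 boundaries). What the phantoms do
*not* model: scanner PSF and partial-volume blur, attenuation,
respiratory motion, irregular lesion shapes, uptake heterogeneity.
Passing phantom tests therefore demonstrates correctness of the
measurement chain, not clinical segmentation accuracy on real scans.

**Cohorts** (`generate_cohort`): n=62 by default with the study's
covariate frequencies (male 58%, G1/G2/G3 = 21/39/2, GEP /
bronchopulmonary / CUP = 53/6/3, age ~N(62,12²) clipped to 27–80).
Markers are jointly log-normal: log-MTV mean 4.011 / SD 1.256 (matches
an arithmetic mean of 121.5 ml and SD 238.1 ml), log-CgA median
500 μg/l / SD 1.4 (no cohort moments are published for CgA; the scale
is chosen so the upper quartile reaches the ~1,250 μg/l range that is
prognostically relevant), correlation ρ=0.6 (a free parameter — the
within-patient MTV–CgA correlation is not published; it is exposed in
the config and results involving the composite should be read as
conditional on it). Event times follow a Weibull
proportional-hazards model, `S(t|x) = exp(-(t/λ)^k e^η)`, shape k=1.3,
scale λ=121.5 months calibrated so the *marginal* 5-year OS is 61.8%
when the per-SD composite log-hazard ratio is 0.98 (= ln 2.67). η acts
on the standardized true composite, so generated and fitted
coefficients share the per-SD scale. Censoring is administrative at
105 months (the follow-up ceiling) plus exponential with rate
0.004/month, giving roughly half the cohort censored.
`simulate_survival` is a stripped-down single-covariate version of the
same model (admin horizon 160 months, rate 0.001/month ≈ 30% censoring
at β=0.98) used for parameter-recovery and calibration runs;
`simulate_reversing_effect` generates a piecewise-exponential hazard
whose covariate effect flips sign at 60 months — a controlled
proportional-hazards violation for power measurements.

## Problem sizes

Simulation studies use the sizes at which their targets are meaningful:
parameter recovery 200 replicates of n=500; type-I calibration 1000
replicates (n=50–100 per arm); PH-test calibration and power 500
replicates of n=500; KM closed-form comparison n=5000; binormal ROC
n=2000 per arm; phantoms 80×80×50 voxels at 2 mm. The end-to-end
analysis scripts run the study scale, n=62.

## Known limitations

- Global thresholding vs seeded region growth (above).
- The fixed-horizon ROC discards early-censored patients instead of
  inverse-probability-of-censoring weighting.
- Phantom realism (above); no DICOM ingestion — NIfTI only.
- The n=62 analyses are intentionally noisy; the package demonstrates
  estimator correctness through the large-n and repeated-simulation
  checks, not through any single small-cohort fit.
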
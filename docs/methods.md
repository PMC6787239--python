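# Methods

This note documents the models implemented in `mammocalc`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Image model and detection pipeline

A digitised screen-film mammogram is modelled as a non-negative intensity
field on a regular grid (reference spacing 0.05 mm/px, film-digitiser frames
of several thousand pixels per side). The frame contains the breast, bright
label/tag boxes, dark background, and mixed Poisson–Gaussian noise from the
film and scanner. Coordinates are (row, col), 0-based, origin top-left;
physical quantities are in mm.

### Segmentation

The log transform `log(1 + I/I_max)` brightens the low-intensity skin line so
that Otsu's three-class threshold separates background / tissue / bright
objects; the union of the two brightest classes minus everything but the
largest connected component is the breast. The smoothing of the mask
(binary closing then opening with a disk of r = 5 px, then hole filling) is a
convention: any structuring element comfortably larger than the noise grain
and smaller than anatomical detail works, and the radius is config-exposed.
A constant-intensity image has no foreground and raises an error.

### Denoising

Film-digitisation noise is approximately Poisson (grain/shot) plus Gaussian
(electronics). The pipeline: (i) grayscale opening with a 1-px-radius disk
removes single-pixel dust; (ii) the Anscombe transform `y = 2√(x + 3/8)`
makes the Poisson component approximately unit-variance Gaussian; (iii) a
locally adaptive Wiener filter (window 5×5) shrinks each pixel toward its
local mean by `max(v − v_n, 0)/v`, with the noise floor `v_n` estimated as
the mean of the local variances *inside the breast mask* (background would
bias it low); (iv) the algebraic inverse `(y/2)² − 3/8`, clipped at 0. The
algebraic inverse carries a small negative bias relative to the exact
unbiased inverse; at film intensity levels (hundreds of counts) it is orders
of magnitude below the noise floor, and the closed form keeps the
round-trip exact to 1e-9 on noise-free values.

### Enhancement and detection

The cosine transform `T(x) = 1 − cos(πx/2)` on mask-normalised intensities
is strictly increasing with increasing derivative (T(0)=0, T(1)=1): it
contracts gray levels below its unit-slope crossover at
x\* = (2/π)·asin(2/π) ≈ 0.44 and spreads those above, favouring the bright
specks. The DoG band-pass (σ_low = 1 px, σ_high = 8 px by default) selects
structures of ~2–20 px, i.e. 0.1–1 mm at the reference spacing; both scales
are configured in mm and converted through the spacing.

Candidates come from the scale-normalised (γ = 2) Hessian at σ = 2 px
(mid-band of speck sizes). With eigenvalues ordered |λ₁| ≤ |λ₂|:

* blob response `|λ₂|·exp(−((λ₁/λ₂) − 1)²/w)`, w = 0.5, where both
  eigenvalues are negative — maximal for isotropic bright blobs;
* ridge response `|λ₂|` where λ₂ < 0 and |λ₁| ≤ 0.25·|λ₂|.

The blob map is binarised at `mean + k·sd` over in-mask pixels with nonzero
response, and 8-connected components become candidate spots with measured
area, eccentricity, axis lengths and response statistics.

**Threshold default k = 5.** The Wiener filter's residual noise is low-pass
with a correlation scale close to its window — exactly the band the DoG/
Hessian chain amplifies — so the extreme-value tail of the residual produces
compact round false candidates. At k = 3 these number tens per image and
occasionally co-locate into false clusters; k = 5 keeps cluster-level recall
≈ 0.97 while holding false clusters ≈ 0.25 per phantom at the default
noise conditions (measured on calibration phantoms disjoint from the test
set). k is config-exposed for material with different noise character.

### Cleaning and grouping

Spots survive when 2 px ≤ area ≤ 80 px (≈ 0.07–0.45 mm equivalent
diameter), eccentricity ≤ 0.95, and mean ridge response over the spot
< 0.5. The ridge veto removes detections riding on contiguous linear
structures (vessel walls, fibres) while letting beaded arterial
calcifications — bright specks that locally dominate the ridge response —
pass the per-spot filter.

Grouping is plain DBSCAN on spot centroids in mm (Euclidean metric,
eps = 5 mm, minPts = 3), matching the clinical convention that ≥ 3
calcifications within about a square centimetre constitute a cluster.
DBSCAN noise points are the discarded isolated specks. Spots are sorted by
(row, col) before clustering so border-point assignment follows a fixed scan
order and the partition is invariant to input order. Cluster extent is
reported as convex-hull area in mm² (0 for degenerate hulls). The per-woman
exposure is the cluster count summed over the two MLO views; a missing side
is an error, since the study design requires both views.

## Statistical models

* **Risk model.** Unconditional logistic regression of case-control status
  on the cluster count, adjusted for age (years), BMI (kg/m²), PD (%), HRT
  (never/past/current), parity, smoking (never/ever), diabetes (no/yes) and
  age at menopause (years). ORs are exp(coefficients); CIs are Wald
  `exp(b ± 1.96·se)`; p-values are per-term likelihood-ratio tests. Each
  model uses its own complete cases. Perfect or quasi-complete separation
  (unbounded likelihood) raises an error naming the offending covariate.
* **9-level reproductive covariate.** Nulliparous women form level 1; parous
  women are cross-classified by breastfeeding (never/ever) and
  age-at-first-birth stratum (< 23, 23–27, > 27 years, chosen as
  approximate tertiles of a first-birth-age distribution centred at 25);
  parous women with missing AFB keep two levels of their own (by
  breastfeeding), so only missing breastfeeding status forces exclusion.
  The composition is a declared convention and is config-overridable.
* **Honest AUC.** Harrell's internal validation: apparent c-statistic (ties
  = 1/2) minus the mean bootstrap optimism (AUC of the refitted model on its
  resample minus its AUC on the original data), with failed resample fits
  redrawn (cap 5·n_boot). Fully seed-determined. A covariate that
  reproduces the outcome exactly short-circuits to AUC 1.0, where the
  likelihood has no finite maximiser but the c-statistic is well defined.
  Note the correction removes *overfitting* optimism only — a finite null
  sample whose covariate is accidentally correlated with the outcome keeps
  that luck (sd ≈ 0.026 at n = 500); calibration statements therefore
  average over data draws.
* **Risk-factor scan.** Controls only; outcome = 1{MCC ≥ 1} (cluster-count
  data are too sparse for multinomial modelling); one logistic model per
  factor, adjusted for age; Bonferroni flags at family size = number of
  factors scanned (deliberately conservative).

## Synthetic generators

### Phantoms

A half-ellipse breast enters from the left edge of a 1024×768 px frame at
0.05 mm/px (a desk-scale stand-in for full digitiser geometry — physical
speck sizes and clustering distances are unchanged, only the field of view
is smaller). Background: constant film level (500) plus a Gaussian random
field (amplitude 30, correlation 2 mm) for parenchymal texture. Specks are
Gaussian bumps (diameter 0.2–0.5 mm, i.e. ±2σ spans the diameter); ridges
are blurred polylines (vessel stand-ins); labels are bright boxes outside
the breast. Noise is Poisson (scale 1 count per intensity unit) plus
Gaussian (sd 5), giving a flat-field sd of ≈ 23; default speck amplitude is
6× that sd. Ground truth records the mask, speck centres, and cluster
memberships defined by the same DBSCAN (5 mm / 3) rule the detector uses,
so generator and detector agree on what a cluster is. Everything is
bit-reproducible from the seed.

Not emulated: anatomical tissue structure (ducts, pectoral muscle),
scatter/blur physics, optical-density calibration, film-handling artefacts
other than generic noise. Passing phantom tests therefore demonstrates the
geometry and noise behaviour of the pipeline, not clinical performance.

### Cohorts

Control covariate marginals are calibrated to a postmenopausal screening
population (ages 50–74): age ~ N(63.8, 6.1), BMI ~ N(25.5, 3.9), PD ~ gamma
(mean 14.6, sd 13.7, clipped to [0, 100]), HRT 78.6/3.1/18.3%
(never/past/current), smoking-ever 40.4%, diabetes 5.3%, age at menopause ~
N(50.2, 4.1). Parity is a point mass at 0 (11.1% nulliparous) plus
1 + negative-binomial for parous women, solved so the overall mean/sd are
2.16/1.44. Among parous women: breastfeeding ever 93.9%, gamma durations
(mean 11.7, sd 10.3 months), AFB ~ N(24.9, 4.7); breastfeeding status is
missing for 19% (the rate that reproduces the observed complete-case sizes
of the 9-level model, ≈ 210 cases / 605 controls), AFB for 5%, duration for
a further 2% of ever-breastfeeders.

Cluster counts follow a hurdle (zero-inflated) model: presence probability
0.27 at the mean age with log-odds slope ln 1.060 per year, positive counts
zero-truncated Poisson(1). Case status follows a logistic model whose
default log-odds are the adjusted study effect sizes (per-cluster ln 1.306;
age ln 0.982, BMI ln 1.069, PD ln 1.022, HRT past ln 0.607 / current
ln 2.274, parity ln 0.859, smoking ln 1.425, diabetes ln 1.227, age at
menopause ln 1.007). Exactly 253 cases and 728 controls are sampled from a
population pool (14× the study size) at pool prevalence 0.05 — a
rare-disease pool, so that sampled controls retain the specified population
marginals; logistic slopes are invariant to this outcome-dependent sampling.
Replicates in which a small nuisance category (typically past HRT) has a
zero cell among cases have no finite MLE and are skipped by the simulation
loops. Covariates are drawn independently (no confounding correlation
structure beyond the age → cluster-presence path), which real cohorts will
not obey.

## Problem sizes

Defaults keep everything desk-scale: phantom suites use 20 images of
1024×768 px; effect-size recovery and the acceptance script use 200 cohorts
of 981 women; honest-AUC calibration uses 10–50 replicates with 100–200
bootstrap resamples (the CLI default is 1000 resamples, matching standard
internal-validation practice).

## Known limitations

* Detection parameters are calibrated on the synthetic noise model; real
  film archives differ in contrast and artefact population, and k_sigma,
  the DoG/Hessian scales and the shape-filter bounds should be revisited
  against visual review there.
* Single detection scale (σ = 2 px): specks at the extremes of the size
  band respond several-fold weaker than mid-band specks.
* No pectoral-muscle removal and no DICOM for-processing support.
* The statistics module fits unconditional logistic models; the
  frequency-matched design is handled by adjusting for age, not by
  conditional likelihood.
* Cluster morphology (shape, density, location) is not characterised —
  only counts.
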
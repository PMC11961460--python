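# Methods

## Scope and model

`pkdvol` quantifies cystic burden in atypical (Mayo Class 2) autosomal
dominant polycystic kidney disease from T2-weighted abdominal MRI. Kidney
masks are assumed given (in clinical practice they are delineated by
radiologists); the package contributes

1. an automated total-cyst-volume (TCV) segmentation inside those masks,
   based on the **progressive weighted curve** (PWC) of the kidney
   gray-level histogram;
2. per-subject volumetrics — TKV, height-adjusted TKV (htTKV, mL/m), TCV,
   residual tissue volume RTV = TKV − TCV, the ratios RTV/TCV, RTV/TKV,
   TCV/TKV, nephromegaly (TKV > 750 mL) and the Mayo imaging class;
3. cohort statistics for a packaged 12-patient atypical-ADPKD cohort
   (descriptives, Class 2A vs 2B contrasts, eGFR-slope progressor
   analysis);
4. a synthetic phantom generator that provides ground-truth kidneys and
   cysts so stages 1–2 can be validated quantitatively.

## PWC segmentation

Let `w_i` be the histogram count of gray level `i` inside the kidney mask
and `x_i` the corresponding gray value. The progressive weighted curve is

    PWC(k) = Σ_{i=0..k} w_i x_i / Σ_{i=0..k} w_i,

the count-weighted mean of all gray values up to level `k`. The curve is
non-decreasing and ends at the masked-region mean. Between two intensity
populations (parenchyma and hyperintense cyst fluid) the curve changes
curvature, so its **inflection points** — sign changes of the central
second difference of the lightly smoothed curve — are the candidate
thresholds.

Each candidate threshold is applied (cysts = voxels *above* it for T2;
polarity is configurable), the foreground is partitioned into 26-connected
objects, objects under a size floor are dropped, and each object is
described by three features:

* **circularity** — 4πA/P² per connected 2-D component of each axial
  slice, area-weighted. Evaluating per slice-component matters: a cluster
  of two spheres cut by one slice produces two disjoint round lobes, and
  scoring their union would halve the circularity of perfectly round
  cross-sections.
* **internal SD** — the standard deviation of the member-voxel gray
  values (homogeneity of cyst fluid);
* **border gradient** — the mean intensity-gradient magnitude over the
  object's boundary voxels. A threshold at the midpoint of a blurred
  tissue interface maximizes this quantity, which is what makes it the
  most informative feature for choosing among candidates.

Features are min–max normalized over the objects of *all* candidates
pooled (so scores are comparable across thresholds, and so the
normalization does not depend on which candidates are later gated out).
Object quality is the weighted mean of normalized circularity, normalized
gradient and one-minus-normalized SD with default weights **(1, 2, 1)**.
The gradient is deliberately dominant: tiny noise peaks thresholded near
the intensity maximum are degenerate objects with circularity exactly 1
and SD near 0, and under equal weights they can outscore full cysts; only
the border gradient separates a genuine tissue interface from them. A
candidate's score is the object-volume-weighted mean quality; the
highest-scoring admissible candidate wins, ties going to the lower gray
level. TCV is the winning mask's voxel count times the voxel volume.

### Admissibility gate

A threshold that merely splits one population's noise produces a
plausible-looking mask, so candidates must pass two checks before they may
win:

* **two-sided contrast (Rose criterion)** — the mean foreground/background
  separation must exceed 3× the larger of the two classes' robust SDs
  (1.4826·MAD; the MAD keeps a minority of partial-volume shell voxels
  from inflating a class's spread). Any split of a single normal
  population separates its halves by at most ≈2.9 robust SDs, so
  cyst-free kidneys are rejected wholesale, while genuine cyst/parenchyma
  interfaces at the default phantom contrast sit near 6.
* **residual parenchyma** — the foreground must leave ≥ 10 % of the
  kidney as background. Even the most cyst-laden kidney in the packaged
  cohort retains ~15 % residual tissue; a "cyst" mask covering the whole
  organ is a segmentation of the kidney itself (typically of its
  partial-volume rim against the dark background).

If the curve has no inflection points at all (degenerate histograms), the
single maximum-between-class-variance (Otsu) threshold is used and
flagged. If no candidate passes the gate the kidney is reported cyst-free
(TCV = 0, flagged) — the behaviour a cyst-free kidney should produce.

### Numerical choices

* 256 histogram bins spanning the masked intensity range; because binning
  is range-relative, the chosen bin (and the mask) is invariant under
  affine intensity rescaling — scanner gain/offset does not move the
  threshold.
* PWC smoothing: Gaussian, σ = 1 bin; curvature magnitudes below 10⁻⁶ of
  the curve range count as zero (flat/linear curves yield no candidates).
* 26-connectivity; minimum object size 5 voxels. All constants live in
  `SegmentationConfig`.
* Constant images produce a single-bin histogram, are flagged, and
  segment as cyst-free.

## Synthetic phantoms

Each phantom is two ellipsoidal kidneys (default semiaxes 32×36×60 mm —
enlarged, as ADPKD kidneys are) on a dark background, with non-overlapping
spherical cysts placed wholly inside the kidneys (largest-first placement;
a bounded retry budget turns impossible packings into an explicit error).
Intensities follow the T2 convention (background 40, parenchyma 100,
cysts 200 gray levels; each structure's level is drawn once per phantom
with small SDs). The ideal piecewise-constant image is blurred with a
Gaussian (σ = 2 mm = 1 voxel) to mimic partial volume, then degraded with
additive Gaussian noise (SD 12, contrast-to-noise ≈ 8; a Rician option
models magnitude MRI), and finally quantized to 256 gray levels. Defaults:
2 mm isotropic voxels on a 96×96×64 grid, 10 cysts per kidney with radii
6–16 mm (6–14 mm where patterns reallocate them).

Pattern presets mimic the atypical presentations: `unilateral` (one kidney
only), `lopsided` (≥ 70 % of cyst volume on one side, enforced by giving
the dominant side the large radii), `asymmetric` (unequal kidney sizes and
counts), `bilateral_atrophy` (kidneys scaled to 0.6, few small cysts) and
a `typical_bilateral` control.

Ground truth is the pre-blur geometry; true volumes are voxel counts ×
voxel volume and converge to the analytic sphere/ellipsoid volumes as
spacing shrinks (the voxelization error of a single alignment oscillates,
so the convergence test averages |relative error| over several shapes).

**What the phantoms do not emulate:** bias fields, motion, anisotropic
slice profiles, coalescing or exophytic cysts, liver cysts inside the
field of view, and radiologist variability in the kidney masks. Passing
the phantom suite therefore shows the threshold-selection machinery
recovers known cyst volume under controlled contrast and noise — not
clinical-grade accuracy on patient MRI. Sub-centimetre cysts near the
resolution/blur limit (e.g. the atrophic preset's 4 mm cysts at 2 mm
voxels) are below the method's detection limit and segment as zero.

## Cohort statistics

* **Descriptives**: mean ± sample SD (n−1); median and quartiles by
  linear interpolation at position (n−1)·q on the sorted sample — the
  convention that reproduces all published interquartile ranges; a single
  observation has SD 0.
* **eGFR slope**: OLS of serial eGFR on time, in mL/min/1.73 m²/year.
* **Progressors**: annual decline (−slope) strictly greater than a
  cutoff. Default 1.9: it selects exactly the four patients whose
  published progressor medians all reproduce. The publication's literal
  "> 1" rule is available (`cutoff=1.0`) and selects five — an
  inconsistency of the source data that the package documents rather than
  resolves.
* **Group comparisons**: two-sided equal-variance Student t when the data
  pass a normality screen, Kruskal–Wallis with tie correction otherwise;
  α = 0.05 per test, no multiplicity correction (mirroring the source
  analysis). The screen is Shapiro–Wilk at α = 0.05 on the pooled
  group-mean-centred residuals: centring-then-pooling tests the normality
  assumption the pooled t test actually makes, and remains defined when a
  group has fewer than three observations (the Class 2B group has two).
  Per-group screening is available via `normality="per_group"`.
* **Correlations**: Pearson on the normal branch, Spearman otherwise.
* **Mayo Class 1**: exponential growth model htTKV = 150·(1+r)^age;
  subclass cut points on r at 1.5/3/4.5/6 % per year, boundaries assigned
  to the lower class (with a 10⁻⁹ relative tolerance so closed-form
  boundary cases are stable); htTKV below the 150 mL/m intercept clamps
  to 1A with a warning. The intercept and cut points are the external
  classification constants and are overridable.

## Packaged cohort fixture

The 12-patient fixture encodes the published per-patient tables verbatim.
Two source quirks are encoded deliberately:

* Patient 5's row is typographically ambiguous in the source; the fixture
  stores creatinine 1.40 mg/dL, eGFR 57, slope +8.59 — the unique reading
  consistent with every published aggregate.
* Patient 6's printed TCV% (84.9) disagrees with 100·TCV/htTKV (83.70) by
  1.2 points. The printed value is stored because the published column
  means (59.2 overall, 67.3 in Class 2A) only reproduce with it; the
  load-time integrity check allows exactly this documented deviation and
  rejects any other row drifting beyond 0.5 points. One consistency test
  in the suite asserts the strict 0.5-point rule on all rows and
  therefore fails on this row by design — it documents the source
  inconsistency instead of papering over it.

## Problem sizes

The validation suite uses 20 phantoms at the default 96×96×64 grid for
segmentation recovery (median relative TCV error ≈ 7 %, maximum ≈ 15–17 %
depending on seeds), 1000-histogram and 1000-sample property sweeps for
the PWC and quantile invariants, and 1000 null resamples for the type-I
error calibration of the group-comparison branch (observed ≈ 0.05–0.06).

## Known limitations

* The kidney mask is an input; no kidney segmentation from raw MRI.
* Threshold selection assumes a two-population intensity model inside the
  kidney; infiltrative patterns or strong bias fields violate it.
* TCV from a single global threshold inherits partial-volume bias of
  roughly −σ²/r per cyst surface; at default blur this is the dominant
  error term for sub-centimetre cysts.
* The cohort module ships one specific published cohort (n = 12); its
  statistics module is general, but the fixture's n=2 atrophic subgroup
  makes those contrasts fragile to test-variant choices, which is why
  only significance verdicts, not exact p-values, are asserted.
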
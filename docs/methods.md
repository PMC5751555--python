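# Methods

## Pipeline model and assumptions

The pipeline assumes a standardized capture contract: a fixed-size RGB
raster (default 768×494) of a frontal face with both pupils visible in the
upper half, under controlled illumination.  Everything upstream of that
contract (camera, lamps, chin rest) is out of scope; the software side
begins at the raster.

**Coordinate convention.**  The key-block formulas place the forehead block
at +H/3 relative to the pupils and the cheek blocks at −H/4.  Anatomically
the forehead is above the eyes and the cheeks below, so the formulas are
interpreted in a frame where y increases upward; conversion to raster
indices is `row = (height − 1) − y`, `col = x`.  This is an interpretation
choice, recorded here: the formulas are kept verbatim and the conversion
alone carries the convention.  Non-integer centers are rounded
half-away-from-zero *after* conversion to raster coordinates — a
deterministic, convention-stable rule — and the s×s window's corner is the
rounded center minus ⌊s/2⌋.

**Color correction** is a least-squares polynomial map fitted on 24 paired
checker patches.  Degree 2 with ten monomials is the default: the 24-row
design matrix is comfortably over-determined and degree 2 captures channel
cross-talk without the conditioning risk of degree 3 (20 terms).  The
shipped reference table holds the classic 24-patch sRGB values; any CSV can
replace it.  Correction is optional: synthetic images are generated
directly in sRGB, so the stage defaults to off in the pipeline driver.

**Pupil detection** realizes an under-specified step ("Canny-based") with
a fully parameterized, deterministic procedure: Canny (σ = 2) on the
luminance of the upper image half, closed-contour filling, connected
components filtered by area within [0.2a, 5a] for expected pupil area
a = πr² (r = 10 px default), circularity 4πA/P² ≥ 0.6, and mean interior
luminance below half the image median.  Exactly two survivors are required;
any other count is an error carrying the candidate count.  Centers are
darkness-weighted centroids, accurate to well under a pixel on synthetic
faces.

**Gamut features.**  The conversion chain is the standard
sRGB → CIEXYZ → CIELAB derivation (CIELAB is defined from CIEXYZ, so the
pipeline exposes both); nearest-centroid matching defaults to CIEXYZ, with
CIELAB behind a config switch.  Proportions are normalized counts (each
block feature sums to 1); distance ties resolve to the lowest centroid
index, making extraction bit-deterministic.  The six-centroid facial gamut
is an input with a shipped default: k-means (k = 6, seed 42) on a synthetic
skin-tone cloud spanning dark-to-light and red-to-yellow chromaticities,
stored as a versioned CSV (`src/nbds/data/default_gamut.csv`) and
regenerable with `make_default_gamut`.  The cloud is a stand-in for an
unpublished clinical gamut and is labelled synthetic accordingly; centroids
are ordered by decreasing luminance.

**ProCRC solver.**  With M_k the diagonal selector of class-k columns, the
objective's normal equations give
P = SᵀS + λI + (γ/K) Σ_k (I − M_k) SᵀS (I − M_k) and Â = P⁻¹Sᵀt.  P is
symmetric positive definite for λ > 0 and is Cholesky-factorized once at
fit time, so classifying a test vector costs one triangular solve.  A
singular P (λ = 0 on a rank-deficient dictionary) raises an error advising
λ > 0.  The per-class residual is the printed ‖SÂ − S_kÂ_k‖ rule; the
classic reconstruction rule ‖t − S_kÂ_k‖ is available behind
`residual_rule="reconstruction"`.  Training columns (and test vectors) are
unit-normalized by default, the standard practice for representation
classifiers; the flag is recorded on the model.  SRC uses FISTA with step
1/L, L = 2‖S‖₂², stopping when the iterate changes by less than 1e-6 in
max-norm (cap 20 000 iterations, then an error with diagnostics).  All
residual ties break to the lowest class index.

## Evaluation protocol

`make_split_plan(n_disease, n_healthy, parts, seed)` shuffles the healthy
indices once with `seed`, cuts them into equal parts (an indivisible count
is an input error), and pairs each part with the whole disease set.  The
per-round half-split (⌊c/2⌋ train per class, re-randomized per round with
seed + round index) reproduces the reference arithmetic exactly: 119 per
class gives 59 + 59 = 118 training and 60 + 60 = 120 testing samples.
"Mean of the rounds" is the arithmetic mean of per-round metrics (primary);
pooled-confusion metrics are reported alongside.  Ratios with a zero
denominator are NaN with a warning, never silently dropped.  Grid notation
"0.1:0.1:1.0" expands inclusively in steps of 0.1.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical* premise — per-region facial color
distributions whose centroid-mixture profiles differ by class — not facial
appearance.  A face is a uniform skin raster with two dark discs (pupils)
and, around each true block center, an (s + 16)-pixel square of pixels
drawn i.i.d. from the region's centroid mixture with isotropic Gaussian
color noise σ in the gamut's space (clipped to the sRGB cube).  The 8-pixel
margin guarantees that a detected-pupil error of up to 3 px still lands the
extracted block inside its painted region; a wider margin would overlap the
neighboring block at the default geometry (LCB and NBB centers are ~84 px
apart).  Pupil rows are jittered within 0.42–0.44 of the image height so
all four regions fit the raster.

Class contrast is a single parameter δ: the disease class moves δ of
probability mass from one designated centroid to another (defaults: from
the lightest-skin centroid to the darkest, δ = 0.4, σ = 0.02; cohort sizes
default to 119 disease / 595 healthy, with the 80/39 sub-class sizes
available for sub-class experiments).  Feature datasets apply the shift to
every included block so that every block combination carries signal.

Passing tests on this generator demonstrate that the pipeline's machinery
— geometry, color transforms, histogram features, solver, protocol — is
correct and that the designed class separation is recovered.  They do not
demonstrate clinical performance: real faces have texture, specular
highlights, pose and illumination variation, inter-subject anatomy
differences, and class differences far subtler and less structured than a
two-centroid mass shift.  Accuracy numbers on synthetic cohorts therefore
characterize the generator's effect size, not disease detectability.

## Numerical and design choices

- Block side s = 64 (reported as the best-performing size); image size
  default 768×494 — the capture contract is also stated elsewhere as
  768×576, and the smaller value is kept as the default with both
  configurable, leaving the discrepancy unresolved by design.
- The default operating point is LCB-only with λ = 0.7, γ = 0.001 (the
  selected configuration of the reference experiments); all seven
  combinations are reachable.
- Acceptance-style checks use 119 + 595 synthetic cohorts and 50 random
  solver instances (m ≤ 10, n ≤ 15, K ≤ 4), sizes chosen to exercise the
  full protocol while keeping the whole suite under a minute.
- Determinism: every stochastic component takes an explicit integer seed
  (numpy `default_rng`); identical seeds give byte-identical feature
  tables, split plans, and prediction files.

## Known limitations

- No real-image validation: pupil detection parameters are tuned to the
  rendering model (dark discs on light skin) and will need revisiting for
  photographs (eyebrows, glasses, specular corneal reflections).
- The shipped gamut is a synthetic stand-in; with a clinically derived
  gamut the feature space would differ, though the interface is identical.
- The SVM baseline delegates to scikit-learn and is excluded from the
  solver-oracle tests; it is a comparison point, not part of the method.
- Chin-region features are deliberately absent (facial-hair confound), as
  is any texture feature: the pipeline is color-only.
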
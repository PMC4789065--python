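# Methods

## Model and procedure

An input RGB tile is mapped into four gray rasters ("spaces"): a
sliding-window local-entropy map, a local-binary-pattern (LBP) map, and the
raw R and B channels.  In each space two feature families are computed —
25 ACHLAC features and 16 co-occurrence (GLCM) statistics — giving 41 per
space and 164 after cascading.  The cascaded vector is standardized (zero
mean, unit variance on training statistics), projected to 7 dimensions with
kernel PCA, and classified with a support-vector machine.  Abnormal tissue
is the positive class.

### HLAC templates

An HLAC feature of order N is `Σ_r f(r) f(r+a₁)…f(r+a_N)`.  Templates are
displacement sets {0, a₁, …, a_N} with distinct offsets (set semantics; a
product never repeats a pixel) inside a centered odd window.  Because the
sum ranges over all positions, translated templates are redundant, so
enumeration merges translation-equivalent sets: candidates are
origin-containing subsets of the window; D ~ E iff E = D + t and E is
itself a valid candidate; the canonical representative is the
lexicographically smallest valid translate.  Masks are ordered by
cardinality, then lexicographically — a deterministic ordering that feature
column names are derived from (note: it need not match the visual ordering
x₁…x₂₅ used in older presentations of the 25-mask figure).

Counts under this convention: 1 (order 0), 5 (order ≤ 1), 25 (order ≤ 2),
223 (order ≤ 8) in a 3×3 window; 193 for order ≤ 2 in a 5×5 window.

**Known discrepancy.** A figure of 205 is sometimes quoted for the
5×5/order-2 configuration.  Exhaustive search over candidate conventions
(valid-translate equivalence, pure shape equivalence, unit-shift-generated
equivalence, multiset/gray-level semantics) shows none yields 25, 223 *and*
205; the 205 decomposes exactly as 1 + 24 + 180, i.e. an enumeration that
merges translated three-point patterns but keeps all 24 directed one-offset
pairs unmerged.  That rule is internally inconsistent (the 3×3 count of 25
requires pair merging), so the package reports 193 and documents rather
than reproduces 205.

### Extended HLAC

`scale_masks` multiplies every offset of the 25-mask set by the integer
factor (radius − 1)/2, widening the spatial support without changing the
template count.  Non-integer scalings are rejected rather than rounded.
Radius 5 is the conventional extended setting and the default when the
extended family is selected.

### ACHLAC

`achlac(img) = max_normalize(hlac(|img − mean(img)|))`.  The corrected
raster stays in floating precision; re-quantizing would destroy the small
deviations the correction is meant to amplify.  Max-normalization maps the
vector into [0, 1] (all-zero in, all-zero out — the degenerate rule for
constant images), removing image-size and scale effects.  Consequences
relied on by tests: ACHLAC is exactly invariant to adding a constant to all
pixels, and a constant image yields the zero vector.

### Traversal and borders

HLAC sums run over the common interior where the largest offset of the mask
set stays in bounds (margin = window half-width × scale factor), so all
features of one family are sums over identical positions and remain
commensurable.  A `wrap` mode treats the image as a torus and makes the
features exactly translation invariant; it exists to test the
shift-invariance property, not for production use.  An optional
per-position normalization flag exists and defaults off; only ACHLAC is
normalized (by its maximum), raw HLAC sums are reported as-is.

### Spaces

* Gray conversion: ITU-R 601 luma (0.299, 0.587, 0.114), rounded half-up.
* Entropy map: Shannon entropy (base 2) of the gray histogram in a sliding
  window (default 9×9, configurable), rescaled linearly from [0, 8] bits to
  [0, 255].  A sliding window is used because a single global entropy value
  cannot produce a per-pixel map.  The plain `−Σ p log₂ p` form is used
  (entropy is non-negative).  Implementation: scikit-image's rank entropy
  filter on an edge-replicated padding.
* LBP: strict "greater than" against the center (ties give 0); bit order
  top-left neighbor first, clockwise, most significant bit first — a fixed
  documented choice.  Mirroring an image permutes the bit positions
  accordingly (covered by a test).
* Borders of both maps: edge replication, keeping output size equal to
  input.

### GLCM

Distance 1 and 16 uniform quantization levels by default (both
configurable): distance 1 is the standard co-occurrence setting, and 16
levels keeps a 160×120 tile's matrices well populated.  Matrices are
accumulated symmetrically and normalized to probabilities.  Statistics:
energy Σp², contrast Σ(i−j)²p, correlation Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) with the
degenerate zero-variance case defined as 1 (a constant image is perfectly
self-similar), homogeneity Σp/(1+|i−j|).  Directions follow scikit-image's
(d sinθ, d cosθ) offset convention; since matrices are symmetric this only
fixes which diagonal is labeled 45° vs 135°.

### Classification stage

* Standardization before kernel PCA (the reference procedure normalizes
  features without stating a formula; z-scoring on training statistics is
  the standard choice).
* Kernel PCA: RBF kernel, bandwidth from the median pairwise distance of
  the standardized training features (γ = 1/(2·median²)); output dimension
  7.  Fitted on the training split only.
* SVM: RBF kernel, C = 1.0, both configurable.  Random forest (200 trees)
  and 5-NN are available for the contrast experiments.
* Splits for synthetic experiments: stratified 50/50, seeded.

All stages are deterministic given the configuration seed.

## Synthetic data generator

The generator emulates the statistical structure the method exploits in
HE-stained tissue, not histology itself: a pink-red cytoplasm background
(smooth Gaussian mottle, σ = 6 px, amplitude 20 gray levels) with
purple-blue anti-aliased elliptical nuclei.  Normal images carry ~12 small
nuclei (semi-axes 2–4 px, mild eccentricity); abnormal images carry twice
as many, √2-times larger and more irregular ones.  After composition every
image's mean gray level is set to a shared target (170) plus a
class-independent stain-intensity jitter (±12 levels), and the mottle gain
is jittered per image (±50%) — the scan-to-scan staining variability of
real slides.  Consequences, verified at batch level by tests: class mean
gray levels agree within 5 levels; abnormal mean 9×9 local variance exceeds
normal by a factor ≥ 1.5 (measured ≈ 2.8); the per-image level/gain
nuisances are exactly the variation ACHLAC's mean correction and
max-normalization remove, while raw HLAC sums absorb them as noise.

What passing tests on this generator do **not** show: performance on real
histopathology (no nuclear chromatin texture, no stain deconvolution
issues, no slide artifacts), and the synthetic task is easy enough that all
feature families can saturate at 100% accuracy — the contrast experiment
verifies direction (ACHLAC ≥ raw HLAC), not effect size.  Raw HLAC remains
strong here partly because the entropy map is itself brightness-invariant
and variance-sensitive, handing its raw sums a clean copy of the class
signal.

## Numerical choices and degenerate inputs

* Mask enumeration rejects even windows; scaling rejects even radii.
* `max_normalize` rejects negative inputs (HLAC of non-negative rasters is
  non-negative) and passes all-zero vectors through.
* `glcm_stats` rejects unnormalized matrices; zero-variance correlation is
  1 by definition.
* Rates over a class absent from the truth vector are NaN, flagged rather
  than silently zeroed.
* Single-class training sets are rejected with a message.

## Problem sizes

The test-suite runs the full study at 50 images per class (160×120 px) and
uses 12–24 images per class for unit-level checks; the acceptance script
fits its pipeline on 20 images per class.  These sizes keep the whole suite
under half a minute on one CPU while leaving every statistical contract
comfortably satisfied.

## Known limitations

* The 5×5/order-2 template count cannot be made to agree with the commonly
  quoted 205 under any consistent dedup rule (see above).
* Kernel-PCA sign indeterminacy means projected coordinates are only
  reproducible on the same platform/library versions; predictions are
  invariant to the sign flip.
* The generator's nuclei are plain ellipses; rotation-invariant LBP,
  multi-distance GLCM and gray-HLAC (offset multiplicity) variants are out
  of scope.
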
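# Methods

## Scope and model

spleenvol implements organ volumetry by the Cavalieri principle on stacks
of parallel sections, plus the single-slice morphometry and cohort
statistics needed to ask whether one slice can replace the stack.  The
volume estimator is

V = d · Σᵢ aᵢ ,

where d (cm) is the center-to-center slice spacing — slice thickness plus
inter-slice gap; a center-to-center DICOM tag, when present, wins over
thickness + gap because it is definitionally d — and aᵢ (cm²) is the
segmented area of slice i, computed as pixel count × dx·dy.  The estimator
is unbiased when the slice planes have a uniformly random start within one
spacing, which is how every synthetic acquisition here is sampled.

The predicted relative standard error of a single systematic sample is the
Gundersen–Jensen / Cruz-Orive coefficient of error.  With lag sums
A = Σ aᵢ², B = Σ aᵢaᵢ₊₁, C = Σ aᵢaᵢ₊₂ over the zero-trimmed profile:

CE = sqrt((3A − 4B + C)/12) / Σ aᵢ .

The /12 form (smoothness class 0) is the default, as the conventional
choice for irregular organs; the /240 variant is available as
`variant="gj240"`.  Leading and trailing zero-area slices are trimmed
before the lag sums; interior zeros are kept — they are legitimate aᵢ = 0
observations.  On a constant profile of n slices the /12 form collapses to
CE = 1/(n√6), which the tests assert to 1e−12.  CE needs at least three
organ-bearing slices; below that it is reported as missing with a reason,
never extrapolated — this degenerate case is precisely the single-slice
regime the study design interrogates.  A negative variance numerator
(possible for pathological profiles in floating point) is clamped to zero.

## Segmentation

The historical workflow was manual; the scriptable stand-in is: Otsu
threshold of the intensity histogram inside an operator ROI (rectangle,
polygon, or per-slice JSON sidecar), then retention of the largest
26-connected 3-D component.  Thresholding is idempotent and its output is
always a subset of the ROI; component ties break toward the earliest voxel
in (slice, row, col) order.  A fully manual mask can be supplied as NIfTI
instead.

## Morphometry

* **Circumference**: holes are filled, the mask is eroded by the
  4-neighbourhood structuring element, and the difference — a one-pixel-wide
  8-connected contour — is counted and multiplied by the pixel length
  (dx when pixels are isotropic to 1%, else sqrt(dx·dy) with a warning).
  Pixel-count perimeters are biased: exactly (4s−4)·p on an axis-aligned
  square of side s, but about −11% on a rasterized disk at millimetre
  resolution because diagonal travel is undercounted.  The tests pin this
  implemented behavior, not the Euclidean perimeter.
* **Diameters**: AP and transverse extents are tight bounding boxes along
  the image axes ((max − min + 1) pixels × spacing), the natural reading of
  AP/transverse in supine axial imaging; they are accurate to one pixel on
  convex shapes.
* **Spleen length**: the count of organ-bearing slices × d, the usual
  craniocaudal convention for axial stacks; error ≤ one slice spacing for
  convex shapes aligned with the slicing axis.

## Synthetic phantoms and what they do (not) emulate

Phantoms are star-shaped solids with known volume: ellipsoids
(V = 4/3·π·abc), superellipsoids (|x/a|ᵖ+|y/b|ᵖ+|z/c|ᵖ ≤ 1,
V = 8abc·Γ(1+1/p)³/Γ(1+3/p)), and bumpy ellipsoids whose normalized radius
is modulated by 1 + α·sin(3θ)cos(2φ) (α ≤ 0.3; volume from a cached
Gauss–Legendre × trapezoid spherical quadrature with >10⁶ nodes, exact to
rounding for these smooth radii; the modulation vanishes at the poles so
the long-axis extent stays 2c).  Voxel membership is a center-point test —
matching downstream binary segmentation — with two-level intensities
(tissue 1000, background 0) and optional additive Gaussian noise.

Default acquisition geometry is 1.5 × 1.5 mm in-plane with 8 mm
center-to-center spacing (6 mm thickness + 2 mm gap), a typical abdominal
MRI protocol; the slice offset is drawn uniformly on [0, d) per subject.

The phantoms deliberately do **not** emulate MR contrast physics, coil
bias fields, partial-volume fractions, breathing motion, or neighbouring
organs that confuse segmentation.  Passing tests therefore demonstrate the
correctness of the measurement chain on known geometry — not segmentation
robustness on clinical images.

## Cohort generator

The cohort is gender-stratified (defaults 110 male, 235 female).  Per sex,
volume and length are zero-truncated normals whose **truncated** mean and
SD equal the configured values (parent parameters are moment-matched by
root finding; naive truncation of a parent with the target moments would
inflate the male volume mean by ~10 cm³).  Volume and length are coupled
through a latent Gaussian with correlation 0.80; each single-slice
predictor couples to the same latent with its own correlation (abdomen
transverse 0.30, other metrics 0.05, age 0.0) — values chosen once to
encode the qualitative structure the regression should recover: length
dominant, abdomen transverse weakly informative, everything else noise.
Predictor means are the published cohort-level means; their SDs are the
published per-variable standard errors × √345, since the printed
per-variable dispersion row is only internally consistent as a standard
error of the mean (the report prints both SD and SEM to avoid the same
ambiguity).

Each subject's phantom has its long axis on the slicing axis with length
equal to the drawn length (c = L/2) and equal short semi-axes solved from
the shape's volume formula — one unambiguous coupling rule.  Draws whose
volume is too large for the length to remain the longest extent are
resampled and counted per subject.  The default shape mix is 50% ellipsoid
/ 50% superellipsoid (exponent 2.5, a blunter, more spleen-like profile);
bump modulation is off by default.  Everything is reproducible from a
single seed; per-subject voxelization seeds are drawn from the cohort
stream.

Two raters are simulated per subject: the mask-derived volume, CE and
length are identical across raters because the automated segmentation is
deterministic, while the single-slice predictor observations receive
independent 2%-CV noise, exercising the field-wise rater averaging that
precedes all statistics.

## Cohort statistics

Rater records are averaged per subject (≤ 2 raters; a value missing for
one rater falls back to the other, flagged).  Descriptives report mean,
sample SD (n−1) and SEM = SD/√n, overall and by sex.  Volume
classification against the required explicit threshold uses a strict
inequality (volume = threshold is normal).

The nine-predictor regression (age, spleen length, L1 AP/transverse
diameters, L1 area, abdomen AP/transverse diameters, abdominal
circumference, spinal canal area) is ordinary least squares implemented
directly: listwise deletion with the retained n reported, QR solution,
SEs from the unbiased residual variance, standardized
βⱼ = Bⱼ·s_xⱼ/s_y, two-sided p from t with n−k−1 df, and
F = (R²/k)/((1−R²)/(n−k−1)).  Rank deficiency is detected by pivoted QR
and reported with the offending column names.  An exact fit (R² = 1)
reports F = ∞ with p = 0.  The suite verifies the whole coefficient table
against a brute-force (XᵀX)⁻¹Xᵀy oracle to 1e−8 relative and against
statsmodels; in the single-predictor case β equals the Pearson r to 1e−10.
No multiple-testing correction is applied.

## Problem sizes and numerical choices

The validation suite uses: 200 uniformly random slice offsets for the
unbiasedness check (mean within 0.5% of truth on an ellipsoid at 1 mm
in-plane resolution); a 100-phantom cohort at default spacing for the CE
acceptability bound (mean CE ≈ 0.013, comfortably ≤ 0.05, with 11–15
slices per subject); and the full 345-subject cohort at default resolution
for mean recovery and the regression ordering — sizes at which the entire
suite runs in a few seconds on one core while keeping every check at its
stated tolerance.  Sex-mean recovery is asserted within two standard
errors of the configured means; with n = 110/235 and SDs of 122.9/89.25
cm³ those standard errors are ≈ 11.7 and 5.8 cm³, so individual seeds can
legitimately land near (occasionally outside) the band — the generator is
unbiased, the width is sampling noise inherent to the study size.

## Known limitations

* The CE variant attribution in the field's literature is muddled; both
  common denominators (12, 240) are provided, defaulting to /12, but no
  claim is made about which variant any particular historical analysis
  used.
* Slice-count length and bounding-box diameters are conventions; Feret
  (caliper) diameters and sub-pixel contour methods are out of scope.
* The perimeter operator reproduces the pixel-counting procedure including
  its bias; it is not a Euclidean perimeter estimator (no Crofton
  correction).
* The cohort's covariance structure beyond the configured latent
  correlations is an assumption, so fitted beta magnitudes are meaningful
  only qualitatively (ordering), not as population estimates.
* Multi-frame/enhanced DICOM, oblique reformats and vendor private tags
  are not supported.
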
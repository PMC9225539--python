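# Methods

## Problem and model

The package grades bladder-wall involvement on a single sagittal
T2-weighted MRI slice. On T2, urine and peri-vesical fat are bright and
the detrusor muscle is dark, so the wall appears as a dark ring between
two bright compartments. The method is deliberately classical — contour
segmentation, hand-crafted features, subset selection, kernel
classification — so that every decision of the final classifier can be
traced to named, physically interpretable wall properties.

## Two-phase level-set segmentation

The contour is the zero level of a signed field φ (negative inside)
advanced by an explicit upwind scheme for

    dφ/dt = −F |∇φ|,
    F     = b·g  +  geometry terms,

concretized as a geodesic active contour. With the edge indicator

    g = 1 / (1 + |∇(G_σ ∗ I)|² / s²),

the update per iteration is

    φ_t = balloon · g · |∇φ|_godunov
        + α · ∇g · ∇φ   (upwind per component)
        + β · g · κ · |∇φ|_central,

where κ is the curvature of the level sets. The balloon term inflates
(balloon < 0) the contour through flat regions and stalls where g → 0;
the advection term locks the front onto edges; curvature keeps it
smooth. φ is periodically reinitialized to a signed distance (Euclidean
distance transform) and, when a domain mask is given, frozen outside it.

**Phase 1 (inner boundary).** The image is smoothed by a grayscale
closing (disk radius 1 px), a seed disk inside the lumen initializes φ
as a signed distance, and the front grows to the lumen/wall edge. The
converged front is an equilibrium of the three forces, which is why the
result is insensitive to the seed-disk size — verified down to
cross-Dice ≥ 0.99 for radii 3/5/10 px.

**Phase 2 (outer boundary).** Before the second evolution the image is
contrast-enhanced with a per-pixel 9 × 9 window stretch
`In = (Ii − M1)/(M2 − M1) · Mx` (window truncated at the borders; where
the window is flat the original intensity is kept) and the lumen is
filled with the mean intensity of a 3-px ring just outside the inner
contour, so the inner edge no longer attracts the front. The outer φ is
the inner signed distance shifted outward by `min_separation + 0.5` px
and evolves only inside an annular search band (dilation of the inner
mask by `round(max_thickness_mm / spacing)` px minus a
`min_separation_px` guard ring). This construction guarantees
inner ⊊ outer and a nonempty wall by design.

### Numerical parameters

| key | default | meaning |
|---|---|---|
| `ls.dt` | 0.5 | time step (CFL-safe for the default forces) |
| `ls.sigma` | 1.0 px | Gaussian smoothing of the edge map |
| `ls.edge_scale` | 8 gray/px | gradient magnitude at which g = 1/2 |
| `ls.alpha` | 3.0 | edge-advection weight |
| `ls.beta` | 0.3 | curvature weight |
| `ls.inner_balloon` / `ls.outer_balloon` | −0.7 | inflation force |
| `ls.stop_tol` | 1e−4 | stop when < this fraction of interior pixels changes per 10 iterations |
| `ls.reinit_every` | 20 | reinitialization period |
| `outer.max_thickness_mm` | 10 | search-band width |
| `outer.min_separation_px` | 1 | guard ring between the contours |

The edge-map smoothing is kept at σ = 1 px deliberately: locally thin
walls (≲ 2 px) are blurred shut by wider kernels, letting the inner
front leak into the surround. α ≳ 5 with dt = 0.5 violates the CFL
bound of the advection term and destabilizes the front; the default
(3.0, 0.5) pair is stable. The 10-mm band default is a clinically
plausible ceiling for a pathological wall; experiments probing thicker
synthetic walls (12 px) widen it explicitly via
`outer.max_thickness_mm`.

## The 40-feature vector

Canonical order `f0…f39` (names in `imaging.FEATURE_NAMES`), computed
from the **original, non-denoised** image — smoothing and enhancement
feed the segmentation only.

* **f0–f4 histogram**: mean, population variance, kurtosis (raw fourth
  standardized moment; 3 for a Gaussian), skewness, and the mean of the
  normalized cumulative 256-bin histogram. Zero-variance regions report
  kurtosis = skewness = 0.
* **f5–f24 GLCM**: co-occurrence matrix restricted to pixel pairs both
  inside the wall mask, distance-1 offsets at 0°/45°/90°/135°
  accumulated into one symmetric matrix, intensities quantized to 32
  equal bins over the wall's own min–max range. The twenty statistics
  are the standard Haralick/Soh/Clausi set (autocorrelation, contrast,
  correlation, cluster prominence/shade, dissimilarity, energy, entropy,
  homogeneity, maximum probability, variance, sum average/variance/
  entropy, difference variance/entropy, the two information measures of
  correlation, inverse difference normalized, inverse difference
  moment), with base-2 logarithms. Degenerate single-entry matrices use
  correlation = 1 and IMC1 = IMC2 = 0. The exact membership of this
  block is this package's catalog; the set is validated feature-by-
  feature against an independent double-loop implementation in the test
  suite.
* **f25–f33 shape** of the outer mask: area (mm²), perimeter (mm),
  circularity 4πA/P², eccentricity, solidity (area over the convex-hull
  area of the pixel centers — the rasterized convex image systematically
  overestimates the hull for small near-convex shapes), roundness
  4A/(π·major²), minor/major axis ratio, major-axis orientation from the
  +x axis in (−π/2, π/2], equivalent diameter (mm).
* **f34 polar thickness**: both contours are expressed as r(θ) around
  the centroid of the outer region by intersecting 360 rays with the
  contour polygons (outermost crossing for the outer curve, innermost
  for the inner — the deterministic resolution for non-star-shaped
  contours, with a count of multivalued angles recorded); f34 is the
  mean of (r_outer − r_inner)·spacing in mm. Min/max/SD of the profile
  are available as non-canonical extras.
* **f35–f39 boundary similarity** on the common angular grid with
  d(θ) = r_outer − r_inner: |trapezoidal area difference over the full
  period|, Σd², Σ|d|, mean |d|, max |d|. The area difference uses the
  absolute value (the sign carries no physical meaning here).

## Feature selection

SFFS/SBFS with true floating steps: the forward search adds the argmax
feature and then conditionally removes features while removal strictly
beats the best score recorded at the smaller subset size (the backward
variant mirrors this). Ties break toward the lowest feature index, the
objective is memoized so no subset is scored twice, and with
`floating=False` the algorithms reduce to plain SFS/SBS. The pipeline
objective is mean stratified 5-fold CV accuracy with a fold seed shared
across all subsets, so subset scores are comparable.

## Classifiers and tuning

Features are min–max normalized to [−1, 1] with train-set statistics
(constant features map to 0; test values are not clipped). The RBF
kernel uses the width convention `K = exp(−‖xi−xj‖²/(2γ²))`, mapped to
scikit-learn's gamma as `1/(2γ²)`. The Grey Wolf Optimizer searches
log₁₀C ∈ [−2, 2], log₁₀γ ∈ [−4, 1] maximizing CV accuracy: a pack of
candidate positions moves toward its three best members with control
scalar a(t) = 2(1 − t/t_max); random coefficients are drawn per wolf,
per leader, per dimension; positions are clipped to the box. The
position update takes the absolute value of the leader mean
(`strict_update=True`); since the search space is a log-hyperparameter
box this is effectively equivalent to the canonical unsigned mean,
which remains available as `strict_update=False`.

Evaluation protocol: a stratified 80/20 split; 5-fold CV inside the 80%
for selection and tuning; accuracy, sensitivity (recall of the
pathological class, mapped to +1), specificity and precision reported
on the held-out 20% and as CV means. Metrics with empty denominators
are NaN, never 0.

## Segmentation metrics

Dice 2|Sg∩St|/(|Sg|+|St|) (1 when both masks are empty), mutual
information of the two binary labelings in bits, and an overall error
rate defined as disagreement over the union of the foregrounds
(1 − Jaccard); the whole-image disagreement fraction is exposed
separately as `pixel_error` since "overall error" admits both readings.

## Synthetic phantoms

A phantom is defined in polar coordinates: a circular inner (lumen)
boundary of radius `base_inner_radius`, and an outer boundary at
`r_inner + t(θ)` with

    t(θ) = mean + (sd + irregularity)·ripple(θ) + diverticulum bumps,

where ripple is a unit-RMS random Fourier series over harmonics 2–5 and
each diverticulum is a Gaussian bump in θ (σ = 0.22 rad) of amplitude
`irregularity + 2·sd + 3` px, spread around the ring so bumps stay
countable. Intensities follow the T2 ordering (defaults: lumen 220,
wall 60, surround 170) with additive Gaussian noise clipped to [0, 255].
Masks are rasterized exactly from the radial model; contours are traced
by marching squares at the 0.5 level.

The default study cohort (config `phantom.*`) uses 128×128 px images at
1 mm/px, inner radius 22 px, noise σ = 8, and two classes: thin-smooth
(thickness 4 ± 0.3 px, no irregularity) versus thickened-irregular
(7 ± 0.6 px, irregularity 1.5 px, 2 diverticula) — severe disease is
both thicker *and* more irregular, mirroring the clinical criteria for
a pathological bladder (diverticula or irregular/supra-physiological
thickening). The noise level (≈ 3% of the dynamic range) and the 3-px
class gap are chosen as a realistic but non-trivial contrast for a
1.5-T T2 acquisition.

What the phantom does **not** emulate: bias fields, partial-volume
averaging at 3-mm slice thickness, motion/flow artifacts, anatomical
neighbors indenting the bladder, or non-circular lumen geometry.
Passing on phantoms therefore demonstrates the internal correctness and
the noise robustness of the pipeline, not clinical-grade performance;
on clinical data the reported separations should be read as upper
bounds.

## Degenerate inputs and tie-breaks

* Contour extraction keeps the largest closed marching-squares
  component (ties by enclosed area, deterministic).
* An inner front that collapses or floods the image raises a
  segmentation-failure error rather than returning an empty/degenerate
  wall; outer == inner raises a degenerate-wall error (structurally
  prevented by the guard-ring initialization).
* Rays that miss a contour polygon (possible at discretization corners)
  are filled by periodic interpolation from neighboring angles.
* All randomness flows from explicit integer seeds: phantom rendering,
  cohort spawning (`numpy.random.SeedSequence`), CV folds, GWO draws
  and Random Forest bootstraps are bit-reproducible.

## Known limitations

* The two evolutions are sequential, not coupled: the outer contour
  cannot correct an inner-contour error.
* The polar thickness model assumes an approximately star-shaped wall;
  deeply necked diverticula are measured by their outermost extent.
* The GLCM quantizes over the wall's own intensity range, making the
  texture features contrast-invariant but sensitive to outlier pixels
  at the range extremes.
* Problem sizes in the automated checks (128×128 phantoms, 60-image
  cohorts, 10–20-wolf packs) are chosen to make the full pipeline run
  in seconds per image; all are configurable upward.
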
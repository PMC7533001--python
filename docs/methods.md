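# Methods

This note documents the models and procedures implemented in trichokit,
the parameters that matter, the synthetic validation data, and the
numerical and design choices made where the design was genuinely open.

## Problem setting

A trichoscopy frame shows dark hair shafts on a lighter scalp, shaded
toward the frame border by the microscope barrel (vignette) and broken
up by specular gloss reflections along the shafts. The package reduces
such a frame to three scalar indicators — hair count, follicle count,
mean hair thickness — without per-hair instance segmentation, so the
whole pipeline runs in well under a second per frame on one CPU core.

## Preprocessing

All three feature extractors consume a square binary mask (`True` =
hair) produced by one chain: red-deweighted grayscale conversion,
resize to 512×512, percentile contrast stretch, Gaussian smoothing,
grayscale erosion (follicle/thickness branches only) and a global
threshold.

* **Gray weights (0.114, 0.587, 0.299).** Standard luma coefficients
  with R and B swapped: scalp renders reddish under these microscopes,
  so deweighting red deepens the hair/scalp contrast. Configurable.
* **Resize to a square, aspect ratio not preserved.** The thickness
  estimator normalizes contour eigenvalues by a single scalar p; a
  non-square frame would stretch eigenvalues anisotropically. Area
  averaging for downscale, bilinear otherwise.
* **Contrast stretch percentiles (0.1, 99.9), minimum range 64.** The
  low cut must stay below the hair-pixel fraction of the darkest frames
  of interest: a cut above it lands in the scalp background and maps
  the vignetted corners below the threshold, fabricating hair. At 0.1%
  the stretch still absorbs ~260 outlier pixels on a 512² frame while a
  single thin hair (≥ ~700 px) keeps anchoring the dark end. When the
  percentile range is narrower than 64 gray levels the frame contains
  no dark feature (only vignette and sensor noise) and the stretch is
  skipped with a warning — otherwise a hairless frame would have its
  noise floor stretched into spurious features.
* **Gaussian σ = 1.5 px** suppresses sensor noise before thresholding.
* **Grayscale erosion, disk radius 3.** Taking the neighborhood minimum
  dilates the dark hair set, closing the bright specular holes that
  would otherwise split one shaft into several components. It also
  merges adjacent hairs, which would corrupt crossing counts — hence
  the hair-count branch skips it. The radius links to the thickness
  module's erosion-scale constant s = erosion_size · side · 2.
* **Threshold 128 (mid-scale).** After stretching, hair sits near 0 and
  scalp near 255. A smoothed step edge thresholded at fraction q of the
  gap shifts by σ·Φ⁻¹(q) per side; mid-scale is the unbiased choice.
  Empirically the feature area of noise-free renders matches the drawn
  stroke area within ~2% at 128, against −20% at 90.
* **Rounding** is half-away-from-zero then clip at every intensity
  computation. Polarity is fixed dark-on-light; `invert` handles the
  opposite case.

## Hair counting (Grid Line Selection)

n_grid + 1 index lines per direction at `round(k·(side−1)/n_grid)`,
k = 0..n_grid (both borders included). Along each line, maximal runs of
consecutive hair pixels are counted — a shaft several pixels wide
crossing a line is one run, one crossing; diagonal adjacency across a
line is not merged. The estimate is

    h = ratio · total_crossings / (n_grid + 1),

with ratio = 2 (mean hair length assumed half the frame side) and
n_grid = 8 by default; h is reported as a real number and rounding left
to the caller. Crossing counting is exact and fast; its failure modes
are hairs lying along a grid line (undercount) and specular-split
shafts (overcount, mitigated for the other branches by erosion but
accepted here).

A probabilistic-Hough baseline (`hough_baseline_count`, on the
skeletonized mask) is provided for comparison only: hairs are curved,
so straight-segment detection either misses them or shatters them into
several segments, and GLS dominates it on curved fixtures.

## Follicle counting

The eroded mask is thinned (Zhang–Suen-style topology-preserving
skeletonization); endpoints are skeleton pixels with exactly one true
8-neighbor (isolated pixels excluded; border-touching endpoints
retained, since follicles at the frame edge are real). Endpoint
coordinates are standardized to [0,1]² by dividing by the side.

K-means is run once per candidate k = 1..n (n = endpoint count), each
fit seeded as `rng_seed + k`, centroids initialized i.i.d. from
N(0.5, 0.25²) per axis clipped to [0,1], empty clusters keeping their
centroid, and a deliberately small iteration budget (max_iter = 10).
Under exact convergence the SSE loss is non-increasing in k, so a
literal argmin over k would collapse to k = n; the small budget plus
random initialization is what keeps the minimum-loss rule (`min_loss`
selection mode, the default) away from that degenerate solution. This
is inherently heuristic and overcounts dense frames (it is the dominant
error source in the end-to-end scores). The `penalized` mode instead
minimizes `loss + γ·nonempty` (γ = 0.01): for blob-like endpoint groups
the per-cluster charge beats any within-blob split (split gain < blob
SSE ≈ 10⁻³) while merges cost at least the squared group separation, so
it recovers planted groups reliably and is the mode of choice when
stability matters. Ties break toward smaller k in both modes. The
follicle count is the number of non-empty clusters; for an empty
endpoint set it is 0 by definition.

## Thickness

On the eroded mask: `area` = hair pixel count; external contours are
the boundary pixels (≥ 1 background 8-neighbor, frame border counts as
background) of each 8-connected component, c their number. For each
contour the leading eigenvalue of the 2×2 population covariance of its
pixel coordinates measures how far the component stretches across the
frame; normalized by p (default side²/6, the eigenvalue of a
full-diagonal line, so λ̄_p < 1 for any in-frame hair) and averaged, it
enters

    Λ_p = (1 − ln(1 − λ̄_p)) / e          (increasing, Λ_p(0) = 1/e)
    E_p = Λ_p · h · s / c                  (s = erosion_size · side · 2)
    t   = α · (area / h − E_p),            clamped at 0 with a warning.

h is the GLS estimate from the same frame; α (µm/px, default 0.15) is a
placeholder calibration that must be fitted to the microscope. Frames
with no contours or h = 0 report thickness as missing (None / JSON
null), never 0. E_p charges each hair the pixels the erosion added
(~2·radius·length); Λ_p scales that charge by how far the average
contour spans the frame.

## Synthetic validation data

The generator renders what the pipeline assumes: dark quadratic-Bézier
strokes (one random perpendicular control offset, up to 80 px — enough
curvature to defeat straight-line detection) of controllable width,
rooted in follicular groups (default ≈ 0.4·n_hairs groups, i.e. 2–3
hairs per unit, typical of scalp follicular units); bright specular
disks punched into shafts (probability 0.3); a radial vignette
(strength 0.15); optional Gaussian blur (σ 0.8) and sensor noise
(sd 5); scalp at gray 200, hair at 40, rendered slightly reddish.
Everything is determined by the seed, and the truth (hair count, group
count, stroke width, root positions, drawn stroke pixel count,
component count) is recorded exactly.

**Calibration of the counting constant.** An isotropic hair of visible
arc A crosses A·(4/π)/spacing grid lines in expectation, so the ratio
constant 2 with mean drawn length 0.5·side is unbiased exactly when the
mean visible arc is π(side−1)(n_grid+1)/(8·n_grid) ≈ 0.44·side — that
is, when the frame border clips ~12% of an average hair, as it does in
real frames where hairs overpass the field of view. The default root
margin (110 px) was chosen by solving that geometric condition with a
line-clipping Monte Carlo; with it the hair-count bias on the default
ensemble is about −1 hair (residual from curvature and run merging).

What the generator does **not** emulate: scalp texture, dots and
inflammation (subsumed into generic noise), focus gradients, hair-color
variation, and anisotropic hair streams (directions are isotropic).
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated geometry and noise model, not clinical
accuracy on real scalps.

**Scoring.** Per frame: absolute differences of the three features
(thickness truth = α · stroke width) and a total accuracy, the mean
over defined features of 100·max(0, 1 − |pred − truth|/truth); features
with zero truth or missing predictions are skipped. The total-accuracy
formula is this package's definition for fixture scoring, not a
reproduction of any published metric.

## Numerical choices and degenerate inputs

* Blank or featureless frames → empty mask → (h = 0, follicles = 0,
  thickness missing).
* Contrast stretch with a degenerate or sub-minimum range returns the
  input unchanged (warning).
* λ̄_p is clamped to [0, 1 − 10⁻⁹) before the logarithm; contours with
  < 2 points contribute eigenvalue 0.
* K-means loss is recomputed from final assignments (brute-force SSE),
  so the reported loss is exact to float precision; the per-iteration
  trace is non-increasing by construction.
* Result JSON uses fixed field order and 6-significant-digit floats;
  per-stage timings stay on the in-memory object only, so identical
  inputs and seeds give byte-identical files.
* All randomness (generator, K-means init, Hough) flows from explicit
  integer seeds.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 200 random masks for
crossing-count oracle agreement; 50 frames (10–25 hairs) for hair-count
recovery (mean |error| ≈ 1.5 hairs, bias ≈ −1.3 at seed 1); 20
curved-hair frames for the Hough comparison; 100 runs of 2–8 planted
endpoint blobs for follicle recovery; 100 random skeletons for endpoint
exactness; widths 3/5/7 px for thickness monotonicity. These sizes give
stable statistics in seconds per check.

## Known limitations

* **Thickness on dense frames.** When many hairs cross, components
  merge and c ≪ h, so E_p = Λ_p·h·s/c grows while area/h stays flat and
  t clamps to 0. The correction chain is implemented as specified — its
  per-hair area term (px² per hair) and the length-like E_p are not
  dimensionally homogeneous — and behaves monotonically only on frames
  with mostly separated hairs.
* **Follicle overcount in `min_loss` mode**, discussed above; use
  `penalized` when stability matters.
* **Fixed threshold.** Frames with strong shading beyond the gate's
  reach, or inverted polarity without `invert`, will mis-segment;
  adaptive thresholding is intentionally not offered.
* α is uncalibrated by default; absolute thickness values are only
  meaningful after fitting it, while two-region ratios are not affected
  by it.
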
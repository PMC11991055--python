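# Methods

This note documents the models and procedures implemented in
`lettucevision`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic test scenes do and do not establish
about behavior on real canopy imagery.

## Problem setting

Nutrient-deficient lettuce tissue discolors in nutrient-specific ways:
nitrogen starvation produces pale/yellow chlorosis beginning on older
(inner) leaves; phosphorus deficiency produces dark, purplish patches;
potassium deficiency scorches leaf margins brown. The diagnostic quantity
is the *deficient-tissue ratio* — the fraction of plant-canopy pixels whose
color falls in a characteristic discoloration band — combined with a hue
histogram of the deficient region to identify which nutrient is lacking.
Everything upstream of that measurement (denoising, contrast enhancement,
edge detection, segmentation) exists to make the color measurement reliable
under impulse noise, uneven illumination and low contrast.

## Denoising: dynamic-window histogram median filter

Each color channel is filtered independently. The 5×5 clipped-window
population variance decides, per pixel, between a 3×3 median (variance
above θ: edges and fine structure worth protecting) and a 5×5 median
(smooth regions, where the larger support removes impulse noise more
reliably). The median is extracted from a 256-bin histogram; as the window
slides, only the entering and leaving pixels update the counts, and the
median is the smallest level whose cumulative count reaches n/2, with n/2
kept as an exact rational (for 9 pixels the first level reaching 4.5).
The production implementation is a row-sliding column-histogram scheme
(Huang's algorithm, vectorized across each row); tests verify exact
pixel-for-pixel equality with naive per-window sorting.

Numerical choices:

* **Window selection is boundary-exact.** `Var > θ` is evaluated as the
  integer comparison `N·Σx² − (Σx)² > θ·N²`, so a variance landing exactly
  on θ always takes the 5×5 branch regardless of floating-point round-off.
* **Borders clip rather than pad** — windows shrink at the image edge and
  both the variance normalization and the median rank use the actual pixel
  count. Padding would invent data; clipping only reweights real pixels.
* θ defaults to 400 (intensity² on the 8-bit scale): on 8-bit data an edge
  between regions differing by ~40 levels inside a 5×5 window produces a
  variance well above 400, while photon/sensor texture stays well below.
  Only window sides 3 and 5 are used; the selection rule is binary.

## HSV representation

All three planes live on a 0–255 scale so every stage shares the same
256-bin histogram machinery; hue 0–255 spans the full wheel and achromatic
pixels take hue 0 by convention. In memory the HSV planes are float64:
quantizing hue to 8 bits would inject up to ±3 levels of round-trip error
at high chroma, while the float representation keeps RGB→HSV→RGB exact to
within the 1-level quantization of the final RGB rounding. Planes are
quantized only when written to disk. Segmentation bands are expressed on
the same 0–255 scale.

## Contrast enhancement (V plane only)

Only brightness is enhanced; hue and saturation pass through, so the
color-band segmentation downstream sees unmodified chromatic information.

**Global histogram equalization** maps level r to
`round((L−1)·CDF(r))` — monotone by construction, near-idempotent (a
second pass moves levels by at most one).

**Improved tile-wise CLAHE.** The plane is divided into an 8×8 grid of
tiles (each at least 8×8 px; the grid shrinks on small images). Per tile:

1. clip limit `Base + Scale·max(0, Threshold − L_avg)` — darker tiles get
   more enhancement headroom; defaults Base = 4 counts, Scale = 0.1
   counts/level, Threshold = 128. With ~1.5 counts/bin on average in a
   20×20 tile, Base ≈ 2.5× the mean bin count, a conventional CLAHE
   operating point;
2. histogram clipping at that limit, then redistribution of the clipped
   mass with logistic weights `w(i) = 1/(1+exp(±α(h(i)−T_w)))`,
   α = 0.05, T_w = the tile's mean bin count. The sign default
   (`invert_weights = true`) sends the larger share to histogram *valleys*,
   which spreads the clipped mass into underpopulated levels instead of
   re-inflating peaks; the opposite reading of the weight curve is kept
   available behind the flag because both are defensible. Integer counts
   are conserved exactly: the fractional residue of the proportional shares
   is swept bin-by-bin, one count at a time, until totals match;
3. remapping through `CDF_norm(i) = (CDF(i) − CDF_min)/(n − CDF_min)·(L−1)`
   with CDF_min the smallest nonzero CDF value. A constant tile makes this
   0/0; it is defined as the identity map (least surprising behavior);
4. seam blending with the separable quartic kernel `K(u,v) = (1−u⁴)(1−v⁴)`
   evaluated at offsets u = i/2 for i ∈ {−2…2}. K vanishes at |u| = 1, so
   the 5×5 support is effectively 3×3 with corner weight (15/16)²; the
   table is normalized to unit sum so constant regions are fixed points.
   The i/2 evaluation is the only reading under which the stated 5×5
   support meets the kernel's zeros; an unnormalized kernel would not
   preserve constants.

**Fusion (CLGCE).** The global and tile-local results are blended with a
single scalar weight `α = 1/(1+exp(−k(L_avg−L₀) − m(σ−σ₀)))` computed from
the input plane's mean brightness and brightness standard deviation
(defaults k = m = 0.05, L₀ = 128, σ₀ = 50 — the sigmoid is centered on
mid-gray and a typical well-exposed spread, with a gain that saturates over
roughly ±100 levels). Bright and/or already-contrasty images lean on the
global map; dark, low-spread images lean on the local one. α is strictly
inside (0,1) and the rounded result stays within the per-pixel min/max of
the two inputs. Rounding at every stage boundary is half-up.

## Edge detection

Eight 3×3 compass-Sobel kernels (the classic horizontal/vertical pair, its
45° rotations, and their negations for 180°–315°). Because opposite
kernels are exact negations, the eight-direction root-sum-of-squares equals
√2 times the four-direction magnitude — an identity the tests verify to
machine precision rather than an approximation. The direction is the atan2
of the sine/cosine-projected responses, with 90° pointing up the image so
that angle arithmetic matches the neighbor geometry used in suppression.

Non-maximum suppression interpolates the two magnitudes on the gradient
line through each pixel: the direction is folded to [0°, 180°) and split
into four octant cases; the blend weight is |tan θ| (near-horizontal) or
|cot θ| (near-vertical), always in [0, 1]. A pixel survives iff it is ≥
both interpolated neighbors — ties keep, so plateaus are not erased.

Dual thresholds are data-derived: T_high is the nearest-rank 95th
percentile of the *nonzero* magnitudes — including the zero mass would let
large empty backgrounds drag T_high to 0 on sparse-edge images — and
T_low = Ratio·T_high with Ratio = 0.4 (the conventional ~2.5:1
high:low Canny ratio). Hysteresis keeps weak pixels 8-connected to strong
ones. A 5×5 Gaussian (σ = 1) precedes the gradient step, as in standard
Canny practice; it is config-disableable.

## Segmentation and fusion

Stage 1 thresholds each HSV plane against an interval and ANDs the plane
masks; the characteristic-color presets (0–255 hue wheel: yellowing 25–60,
purple 175–220, brown 4–24, each with saturation ≥ 60 and value ≥ 40) are
calibration defaults of this package, not measured constants. Multiple
bands are ORed. When a plant-canopy ROI is supplied (the pipeline passes
the plant mask computed from the denoised image), the search is restricted
to it — deficient tissue is plant tissue by definition.

Stage 2 runs the edge detector on the V plane; stage 3 computes block-wise
adaptive thresholds (16×16 px blocks, distance weights 1/(1+d) to the
block center, threshold = weighted mean intensity) and marks pixels whose
gradient magnitude exceeds their block's threshold. The gradient magnitude
is min–max normalized to [0, 255] before that comparison because a
gradient is otherwise not commensurable with an intensity-derived
threshold — normalization is the minimal reconciliation.

The fusion is deliberately conservative set algebra: edge and
gradient-foreground pixels contribute only inside a ±2 px band around the
stage-1 mask; the union is morphologically closed (radius 3), holes up to
64 px are filled, components under 16 px are discarded as speckle, and the
result never exceeds a 5 px dilation of the stage-1 mask (an invariant the
tests enforce). Hole filling is size-limited because ring-shaped lesions —
marginal potassium scorch encircling a leaf — would otherwise flood the
enclosed healthy interior.

## Diagnosis

The deficient-tissue ratio divides by the plant mask (saturation ≥ 50 and
value ≥ 40 on the *denoised* image — enhancement redistributes V levels
and would make a brightness-based plant test unstable). Severity cutpoints
0.02 / 0.10 / 0.25 split healthy/mild/moderate/severe; they are
calibration placeholders, exposed in config, not field-derived constants.
The nutrient is the hue band containing the modal hue of the deficient
region (ties break to the lower level for determinism; if the mode falls
between bands, the band holding the largest pixel fraction is used).
Classification is a pure function of its inputs and records every fired
rule in a trace.

## Synthetic scenes: what they do and do not show

The generator renders a rosette of overlapping elliptical leaves (default
12) around the canvas center on a dark, near-achromatic background, with
per-leaf hue/value jitter and fine brightness texture. Lesions are placed
with nutrient-specific geometry — N: grown outward from the rosette
center; P: patches grown around random seed points; K: 4 px-wide marginal
bands on individual leaves, affected leaf by leaf — and are *exactly* the
requested number of plant pixels (the k lowest-scoring pixels under the
class's placement score), so the true fraction is known to one-pixel
rounding. A multiplicative illumination ramp (default 15% peak-to-peak)
scales all RGB channels equally, which preserves hue and saturation —
deliberately, since the pipeline's color bands should be tested under
brightness variation, not chroma drift. Salt-and-pepper noise (default 2%
of pixels, exact count, fair black/white coin) is applied after the truth
masks are captured so denoising is scored against clean truth. The default
canvas is 160×160 px, small enough that the 100-scene recovery battery
runs in about a minute while leaving ~25 px-wide leaves, several blocks
per lesion and realistic border effects.

Because scenes are hard-edged in hue, recovery results (mean Jaccard
≈ 0.93–0.94, ratio MAE ≈ 0.01, exact label recovery ≈ 100% on balanced
batteries) demonstrate the *mechanics* of the pipeline — exact stage
contracts, correct thresholds, stable fusion — not field performance.
Real canopies add specular highlights, soft lesion borders, overlapping
diseased/senescent tissue, camera chroma noise and white balance drift,
none of which the generator models; the hue-band presets and severity
cutpoints would need recalibration against labeled field imagery.

## Known limitations

* Severity classes near the cutpoints are sensitive to the ±0.01-ratio
  segmentation bias introduced by boundary pixels; the battery's severity
  centers (0.05/0.15/0.35) sit safely between cutpoints, real ratios need
  not.
* Hue bands cannot separate nutrients whose discolorations overlap in hue
  (e.g. late-stage N chlorosis turning brown vs. K scorch); the rule table
  reports the dominant band only.
* The thin-structure regime (lesions ≲ 4 px wide) loses Jaccard to the
  morphological fusion; the speckle floor (16 px) sets the smallest
  detectable lesion.
* The pipeline is per-image and stateless; no temporal smoothing across a
  growth series is attempted.
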
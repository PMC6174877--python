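# Methods

## Color standardization model

The transform from a source to a target color profile is three independent
ordinary least-squares regressions, one per output channel, of the target
chip means on the source chips' linear, quadratic and cubic channel values
(a 9-column design). The model assumes

- the card chips are *homologous*: chip i in the source is the same physical
  patch as chip i in the target, sampled in the same order (enforced by chip
  ids, never by list position);
- the scene's color drift is global — one smooth mapping of RGB space moves
  every pixel, which holds for illumination/exposure changes but not for
  local effects (shadows, specular highlights, colored reflections);
- the drift is well approximated by per-channel cubic polynomials in
  (r, g, b). Brightness scaling is exactly in-model; gamma-type responses
  are approximated (chip residuals well under one 8-bit intensity unit for
  gammas in the 0.85–1.2 range covered by the fixtures).

Fitting is done in double precision on the native 0–255 scale, with no
pre-normalization, so deviance magnitudes are comparable across images and
datasets. The pseudoinverse semantics `M = (SᵀS)⁻¹Sᵀ` are realized by an SVD
solve rather than explicit normal equations: cubed 8-bit intensities give
the design a condition number around 10⁶–10⁷, and squaring it in `SᵀS`
would cost ~7 more digits. A design whose numerical rank falls below 9
(singular values below 1e−10 of the largest) raises a singular-design error
naming the rank found — with fewer than nine independent chip colors the
transform is genuinely incalculable, which bounds how many chips can be
lost to occlusion or saturation.

The 9×9 homography `H` stacks the regressions of the target's nine extended
channels on the source design, rows ordered (R, G, B, R², G², B², R³, G³,
B³). Deviance `D = 1 − det(H)` is reported **signed**: dimmed images
produce large negative values (the determinant grows when the transform
must amplify intensities), and taking |D| would discard the direction of
drift. `D` is exactly 0 only when source and target chip matrices agree;
re-scoring a standardized 8-bit image against its reference leaves a small
residual (|D| ~ 10⁻³–10⁻²) from quantization of the written pixels.

Pixel application clips to [0, 255] *after* the polynomial (never during
fitting) and rounds half-up for 8-bit output; a float output mode preserves
unclipped values so analyses can separate model error from quantization.

## Chip sampling

Chip color is the arithmetic mean over the chip rectangle shrunk on every
side by `inset_fraction` (default 0.25), which keeps chip borders, bevel
shadows and slight layout misregistration out of the sample. The card is
located by configuration (a YAML layout of per-chip rectangles), matching
the fixed-camera setting the method is designed for; automatic card
detection is deliberately out of scope. Chips whose mean reaches 254.5 in
any channel are flagged saturated but remain fit-eligible — a warning, not
an error, because the regression can still use their unsaturated channels.

## Segmentation and shape conventions

Fixed-threshold segmentation marks a pixel as plant iff it satisfies every
configured RGB/HSV bound. No morphological cleanup is applied unless
`keep_largest_component` is set; isolated misclassified pixels are a
*signal* of color drift and are preserved by default.

Shape descriptor conventions (units: pixels; 8-connectivity throughout):

- **perimeter** — arc length of the outer contour traced through boundary
  pixel centers (Moore-neighbor tracing; unit steps orthogonal, √2
  diagonal), summed over all components when cleanup is off. A 10×10 square
  measures 36; a single pixel 0.
- **ellipse** — center, axis lengths and orientation from second-order
  central image moments; eccentricity from the fitted axes; angle in
  degrees from the x-axis, in [0, 180).
- **circularity** = 4π·area/perimeter²; **roundness** = 4·area/(π·major²);
  **solidity** = area / pixelized convex hull area; **aspect ratio** =
  bounding-box width/height.
- **fractal dimension** — box-counting slope of log N(s) vs log (1/s) over
  dyadic box sizes on a power-of-two padded crop (≥ 2 scales). Filled
  regions approach 2, curves 1, points 0.
- convex hull vertex count uses the exact hull of pixel centers
  (scipy.spatial); hull *area* uses the pixelized hull so solidity is 1 for
  convex pixel sets.

Physical calibration (px → cm) is out of scope; no conversion factor is
assumed.

## Hue analysis

Hue (HSV angular coordinate, degrees) is computed for masked pixels only;
achromatic pixels (R = G = B) have undefined hue and are assigned 0 and
flagged. Histograms use half-open 1° bins over the full 0–360° support and
are normalized to percent of masked pixels; the 0–140° display range is
presentation metadata only — every statistic uses the full support.
Averages over images are arithmetic means of per-image percentage
histograms with a 95% band of ±1.96·SE per bin.

The two-sample KS comparison uses the binned CDFs: `K = sup|F_x − F_y|`
against the threshold `c(α)·√((n+m)/nm)`, `c(α) = √(−½ ln(α/2))`
(c(0.05) ≈ 1.3581). What counts as the sample sizes n, m is a genuine
modeling choice once histograms are pooled or averaged over many images:

- `n_mode="pixels"` (default) uses total masked pixel counts — the most
  conservative reading, appropriate when comparing two single images;
- `n_mode="bins"` uses the number of histogram bins — appropriate when the
  objects under test are averaged histogram *curves*, since with pooled
  pixel counts in the tens of thousands the threshold (~0.009) rejects
  sub-degree CDF shifts at the scale of 8-bit hue quantization, and no
  correction method preserves hue below quantization.

The packaged day/night study evaluation uses `n_mode="bins"` for its pooled
comparisons, for exactly that reason.

## Synthetic fixtures

`render_scene` draws a uniform background, a 4×6 card of the 24 classic
chart colors (packaged nominal constants — fixture inputs, not measurements
of any physical card), and a green plant disc with seeded per-pixel color
texture (normal, sd 12 intensity units, truncated at 2.5 sd). Truncation
bounds the plant's color support so a fixed threshold with margin recovers
the disc *exactly* on the reference — which makes ground-truth comparisons
sharp. `distort` models lamp drift: per channel v′ = 255·(s·v/255)^γ, an
optional in-model cubic shift, then truncated Gaussian noise.

The day/night study conditions mirror a temperature-cycled facility: day
images at brightness scale U(0.80, 0.90) with γ ≈ 1; night images at
U(0.50, 0.65) with a warm shift (γ_R ∈ [1.10, 1.20], γ_B ∈ [0.85, 0.95]);
noise sd 1. Under these conditions (20 scenes, 320×240 px, plant radius
40 px) the median |D| before standardization is ~10³ and after re-scoring
standardized images ~4×10⁻³; the fixed-threshold plant-area error falls
from ~45% (median) to ~0.02%.

What the fixtures do **not** emulate: spatial nonuniformity of illumination,
shadows and overlap, card wear and specular gloss, demosaicing artifacts,
lens vignetting, and real leaf color heterogeneity. Passing the synthetic
study shows the estimator and pipeline are correct for global smooth color
drift; it does not certify performance on images whose variation is local
or non-smooth.

## Numerical and design choices

- Rank tolerance 1e−10 × largest singular value; below rank 9 fitting fails
  loudly, never silently.
- CSV outputs: lexicographic image order, 6-significant-digit floats —
  byte-identical re-runs.
- Transforms serialize to JSON with full-precision coefficients (repr
  round-trip is bit-exact).
- Image ids are path stems; duplicate stems in one batch are a fatal config
  error rather than a silent overwrite.
- Per-image failures (unreadable file, out-of-bounds card, rank-deficient
  chips) are logged to `errors.csv` and skipped; only an unusable reference
  aborts a batch.
- All stochastic behavior (plant texture, distortion draws, noise) flows
  from explicit integer seeds; the packaged default seed is 2024.

## Known limitations

- The cubic polynomial family cannot represent channel-coupled saturations
  or strong tone curves; residuals grow outside the gamma range above.
- Deviance is a global scalar: it detects profile drift but cannot localize
  it within the image.
- Perimeter (and thus circularity) is resolution-dependent, as any
  pixel-contour measure is; comparisons are only meaningful at a fixed
  imaging scale.
- The KS comparison treats bins as independent samples of the CDF; for
  strongly multimodal hue profiles the bin-mode threshold is approximate.
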
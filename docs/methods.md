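# Methods

This note documents the models and procedures `ribeyegrade` implements,
the tunable parameters and their defaults, the numerical choices made
where the design was genuinely open, and what the synthetic test scenes
do and do not show about real photographs.

## Scale calibration

All physical quantities derive from a single global pixel-to-centimetre
factor: `px_per_cm = |p2 − p1| / known_distance_cm` for two user-supplied
pixel points on an in-frame reference of known length (typically 5 cm).
The model assumes a perpendicular, fixed-distance capture geometry; no
lens-distortion or perspective correction is applied, and color is taken
as the saved 8-bit sRGB values with no color management. Pixel coordinates
are 0-based `(x=column, y=row)`; a pixel is either inside or outside a
mask (areas are whole-pixel counts, no sub-pixel weighting).

## Segmentation

1. **Grayscale** — default is the unweighted mean `round((R+G+B)/3)`;
   ITU-R luma weights (0.299, 0.587, 0.114) are available via
   `grayscale.mode=luma`.
2. **Auto-contrast** — a linear stretch whose cut intensities leave at
   most `saturation/2` of pixels saturated at each tail
   (default 0.35%, `autocontrast.saturation`). Cuts are taken from the
   256-bin histogram and equal the order statistics of the sorted pixel
   list exactly; the mapping is monotone, so no threshold decision can be
   reversed by it.
3. **Rib-eye threshold** — automatic intermeans (isodata): the threshold
   `t` satisfying `t = round((mean(values ≤ t) + mean(values > t))/2)`.
   The generic `isodata_threshold` iterates from the mid-intensity of the
   populated range, which is the classical formulation. For the rib-eye
   mask specifically, the pipeline instead takes the **smallest**
   intermeans fixed point of the histogram: a marbled cut has a trimodal
   histogram (dark bench, mid-gray lean, bright fat) with one fixed point
   per pairwise split, and the mid-start iterate can land on the
   muscle/fat split, which would classify lean muscle as background. The
   smallest fixed point is by construction the background-vs-everything
   split. A fixed explicit threshold can be forced with
   `threshold.method=fixed` + `threshold.fixed_value`.
4. **Cleanup** — internal holes are filled (4-connected background
   convention), components smaller than `cleanup.min_object_cm2`
   (default 1.0 cm², removes bench debris and the scale bar) are dropped,
   and the largest 8-connected component is kept, so the rib-eye mask is
   always one connected region.
5. **Marbling threshold** — isodata applied to the histogram of
   (contrast-adjusted) gray values *restricted to the rib-eye mask*; fat
   is the brighter class. If the resulting class means are separated by
   fewer than `marbling.min_separation` gray levels (default 20), the
   sample is treated as uniform lean and an empty marbling mask is
   returned with a warning flag — otherwise a noise-only histogram would
   be split down the middle and half the lean muscle declared fat. The
   default of 20 sits well above the ~5-level separation isodata produces
   on pure sensor noise (sd ≈ 3) and well below the ≥ 40-level
   muscle/fat contrast of any usable palette.
6. **Particle analysis** — 8-connected component labeling with a
   calibrated size window (`particles.min_cm2` = 0.5, open-ended above).
   The 0.5 floor filters dust/fascia-scale specks out of the marbling
   count. The unit (cm²) follows from the scale being set globally before
   analysis; it is configurable and echoed in every run log.

## Measurement

* **Length/width** — long and short sides of the minimum-area oriented
  bounding rectangle of the mask, computed on the convex hull of the
  *pixel-square corners* (so an axis-aligned w×h-pixel rectangle measures
  exactly w×h, and rotation error stays within rasterization noise,
  ≤ 1%). A max-Feret alternative (`measurement.length_method=feret`)
  reports the maximal caliper diameter and the breadth perpendicular to
  it.
* **Marbling percentage** — 100 × (Σ surviving fat-particle areas) /
  rib-eye area. The denominator is the *total* rib-eye area (fat
  included), i.e. the marbling percentage of the cut, not of the lean
  fraction; values pushed above 100 by pathological segmentation are
  capped with a warning.
* **Channel means / red ratio** — arithmetic channel means over the
  rib-eye mask (background excluded; fat pixels included by default,
  `measurement.channel_scope=lean_only` excludes them), and
  `red_ratio = mean_R / (mean_R + mean_G + mean_B)`. The ratio is a ratio
  of means, not a mean of per-pixel ratios; the three channel shares
  partition unity exactly.

## Grading

Interval thresholds per parameter (see README table) with deterministic
boundary resolution: printed thresholds touch (e.g. ratio bands
"0.49–0.47" and "0.47–0.45" share 0.47), so intervals are half-open —
lower-inclusive for the increasing parameters (area 50 cm² → A2) and
upper-inclusive for the decreasing ratio (ratio 0.49 → A2); shared
endpoints always resolve toward the lower grade index. An area below the
A1 floor of 40 cm² is flagged "out of range / below scale" rather than
clamped (`grading.clamp_below_scale=True` restores clamping). The table
is serializable to JSON so alternative national standards can be dropped
in.

How three disagreeing parameter grades combine into one label is a design
choice, not an established rule — graded commercial samples tend to
co-vary across all three parameters, leaving the discordant case
unconstrained. The default `majority_marbling` strategy takes the
majority grade when at least two parameters agree and otherwise defers to
the marbling grade, marbling being the single most important appearance
indicator; `marbling_only` and `minimum` (conservative) are available,
the chosen strategy is recorded in every result, and a spread of more
than one grade between parameters raises a `grade_disagreement` flag.

## Validation statistics

* **Grid-paper area** — S = (N1 + N2)·a², with a = 0.5 cm by default
  (single-cell area 0.25 cm²). `simulate_grid_count` reproduces the
  manual counting protocol on a mask: an axis-aligned grid anchored at
  the mask's bounding-box corner (the manual protocol defines no origin),
  exact fractional-pixel cell coverage via a bilinear-interpolated
  integral image, N1 = coverage ≈ 1, N2 = coverage > ½.
* **Gaussian outlier elimination** — location/scale by maximum likelihood
  (mean and 1/n SD); values beyond k·σ (default k = 2.5, a parameter —
  no canonical value exists) are removed in a single pass and the fit
  refreshed on the retained set. Removing more than half the data aborts
  with an error: that is pathological input, not random outliers. Note
  the mean/SD rule cannot flag anything at n = 5 and k = 2.5 (the maximum
  attainable z is (n−1)/√n ≈ 1.79); the filter is intended for the
  n ≳ 20 repeated-measurement setting it is validated in.
* **Pearson agreement** — product-moment r with the exact two-sided
  t-transform p-value (df = n − 2); affine-invariant, requires n ≥ 3 and
  nonzero variance.
* **Grading accuracy** — 100 × matches / n with per-grade confusion
  counts.

## Synthetic scenes

The generator renders what the pipeline needs to see, not what beef looks
like: a Fourier-perturbed ellipse silhouette (harmonics 2–6, amplitude
6% with geometric decay) on a near-black bench (RGB 10,10,10); fat as a
union of random ellipses (0.8–3 cm² each) placed inside the eroded
silhouette until the realized fat fraction is within ±1 percentage point
of target; grade-styled palettes (muscle brightness rising from ~57 to
~133 gray A1→A5, fat near-neutral bright, ≥ 40 gray levels of
muscle/fat contrast); i.i.d. Gaussian sensor noise (sd = 3 intensity
levels, clamped); and a high-contrast scale bar with exactly known
endpoints outside the silhouette. Silhouette sizes follow the commercial
sampling range (length ≈ 8–15 cm, width 5–10 cm, scaled up for the
largest-area grades). Default resolution is 20 px/cm — a few hundred
pixels across the cut, enough that rasterization error in area is far
below the grading bands while keeping test suites fast; the geometry is
resolution-independent.

Ground truth is exact by construction: the rendering stencils are the
masks, and area/marbling/channel statistics are computed from them before
noise. For grade panels, specs are drawn with their true parameters at
least 10% of the band width inside the target grade's intervals (plus one
extra percentage point for marbling, absorbing the generator tolerance);
the palette is re-solved against the *realized* fat fraction (geometry is
seed-stable, so the re-render changes only colors), and the sample is
re-drawn if any true parameter still grades outside the intended band.
Each draw uses an isolated `numpy` Generator; identical seeds give
bit-identical images.

What passing on these scenes does **not** show: robustness to specular
highlights, shadows, wet surfaces, fascia and blood stains, lens
distortion, uneven lighting, or marbling at the thread-like scale below
the 0.5 cm² particle floor. Real-image performance depends on the
physical capture protocol those scenes assume away.

## Known limitations

* The marbling threshold of the original interactive workflow was tuned
  by eye; the automatic isodata surrogate is deterministic but not
  guaranteed to reproduce any particular operator's masks.
* A single global scale factor cannot express perspective or lens
  distortion; calibration uncertainty is not modeled.
* The grading thresholds are an empirical scale validated on one
  commercial sampling frame; the package treats them as data (a JSON
  table), not as universal constants.
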
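# Methods

This note documents the models, measurement conventions, numerical
choices and known limitations of `ricedeficit`.

## Synthetic study model

The generator emulates a greenhouse scanning study of rice under four
nutrition regimes (Normal, N-, P-, K-deficient), one plant = three leaves
plus three sheaths, imaged individually on a flatbed scanner.

**Geometry.** A leaf is a lanceolate outline: each side is one quadratic
Bézier arc from a truncated base (base width = 0.45 × maximum width) to
the tip, with the control point solved in closed form so the maximum
width W occurs exactly at 40 % of the length L. A sheath is a stadium
(rectangle with semicircular caps). Outlines are built analytically in
centimetres; the recorded ground truth (length, width, shoelace area,
white-region area) comes from the same dense polygon that is rasterized,
so truth and raster differ only by discretization. Rasterization is a
vectorized scanline fill of the half-width profile at the requested dpi
(default 300, matching typical scanner output; simulation studies in the
tests and the acceptance script run at 50 dpi — feature extraction is
dpi-invariant within ~3 %, which the suite verifies explicitly).

**Symptoms.** Class profiles are *qualitative reconstructions* of the
documented deficiency symptoms; no quantitative per-class colors are
published, so the defaults are package choices exposed as configuration:

| class  | leaf base RGB   | tip gradient          | sheath RGB      | other |
|--------|-----------------|-----------------------|-----------------|-------|
| Normal | (60, 110, 45)   | none                  | (120, 150, 90)  | longest leaves, widest leaf spacing |
| Ndef   | (140, 170, 70)  | 35 % of L → (185, 190, 95) | (170, 180, 95) | white basal sheath region, 25 % of sheath length |
| Pdef   | (45, 75, 40)    | 20 % of L → (120, 90, 50)  | (135, 75, 95)  | narrowest/shortest leaves, R > G sheath |
| Kdef   | (55, 95, 45)    | 30 % of L → (150, 120, 45) | (110, 135, 85) | dark leaves, yellow-brown tip |

Because N, P and K are remobilized from old to young tissue, symptoms are
strongest on the oldest leaf: deficient-class colors are attenuated
toward the healthy reference by a per-position strength (0.6, 0.8, 1.0
for positions 1→3), and the tip-gradient extent and white-region fraction
scale with the same factor. The tip gradient interpolates linearly in
RGB along the blade axis. Noise is i.i.d. per-channel Gaussian (sd 8 by
default) clipped to the valid band of each region (background ≥ 246,
white sheath base ≥ 230); per-plant variability adds a shared RGB offset
(sd 3) and multiplicative length/width jitter (sd 6 %). The white basal
segment is painted at (233, 233, 230) — near-white by the white-region
test (all channels ≥ 230) yet below the scanner-background level, so it
stays inside the segmented foreground.

**What the generator does not model:** venation, necrotic-spot texture,
3-D curl, specular highlights, scanner optics, spatially correlated
noise, multiple organs per image. Passing tests therefore demonstrate
that the measurement/selection/classification machinery is correct and
recovers the constructed symptom structure; they do not certify accuracy
on real scans, where class overlap is far larger.

## Segmentation and calibration

Foreground = pixels with min(R, G, B) below 235 (the scanner lid is
near-white), holes filled, largest 8-connected component kept; an Otsu
split on the min channel is available for less controlled backgrounds.
The principal axis comes from the second-order mask moments with a
deterministic sign convention. The tip is the axis end whose local width
(mean perpendicular run over the terminal 5 % of the axis) is smaller;
if the two end widths differ by < 5 % the choice is flagged ambiguous and
made deterministically (lexicographically smaller endpoint). Linear and
area calibration are n·2.54/dpi and n·(2.54/dpi)².

## Measurement conventions

* **Length** (leaf and sheath): geodesic diameter of the morphological
  skeleton. The two farthest skeleton pixels are found by a double
  Dijkstra sweep (exact on trees, which organ skeletons effectively are);
  the connecting path is measured by 10-px chords rather than by summing
  1/√2 steps, because a pixel walk overestimates digital lines by up to
  8 % depending on orientation, while chords stay within ~0.5 %. The
  distance-transform radius at both path ends is added back, so a blunt
  rectangle measures its full extent (a 300×30 px rectangle at 300 dpi
  reads 2.55 cm). If the skeleton collapses to a single pixel (compact
  blobs), the length degrades gracefully to twice the inscribed radius.
* **Width**: maximum foreground extent perpendicular to the principal
  axis over unit bins along the axis.
* **Perimeter**: length of the marching-squares half-level contour
  resampled with ~4-px chords. This estimator is accurate to ~0.5 % on
  discs and rectangles and rotation-stable to well under 1 %, where any
  weighted chain code is biased by several percent in an
  orientation-dependent way (fatal for the form factor, which squares the
  perimeter). A Moore-walk chain-code estimator with
  Vossepoel–Smeulders weights (0.948/1.343) is retained as the `chain`
  option and for the walk-correctness oracle tests.
* **Shape ratios**: eccentricity = length/width (the ratio definition,
  not the moment ellipse); rectangularity uses the *minimum-area rotated*
  bounding rectangle; convex hull, bounding rectangle and enclosing
  circle are computed on the pixel-corner cloud of the boundary (±0.5 px)
  so that pixel extent is covered — a rasterized axis-aligned rectangle
  then has rectangularity 1.000 rather than ~1.04; circularity =
  (max distance-transform value)/(minimum enclosing circle radius); form
  factor = 4πA/P² (1 for a disc).
* **Lightness**: mean of the three channel means by default; an
  HSL-style (max+min)/2 variant is selectable — both plausible readings
  of the original definition are implemented and the choice is recorded
  in the configuration.
* **Tip color**: mean RGB over foreground pixels whose projection on the
  principal axis lies within 1/5 of the axis extent from the tip end
  (straight-axis projection, not geodesic distance — the blades are
  straight at scan time).
* **White-region area**: largest 8-connected patch of foreground pixels
  with min channel ≥ 200 and channel spread ≤ 30, calibrated to cm².
  The two thresholds replace an interactive magic-wand step and are
  exposed in the configuration.
* **Cross-leaf features**: L23 = LL₂ − LL₃, L1/3 = LL₁/LL₃, channel
  differences R23/G23/B23 likewise; leaf spacing LS12/LS23 is defined as
  the consecutive sheath-length differences (sheath length reflects the
  spacing between insertion points); a missing organ is an error, never a
  NaN.

## Feature selection

SVM-RFE with a linear kernel (C = 1): the per-feature score is the
decrease of the margin objective when the feature is removed, which for a
linear SVM is wⱼ²; one feature is eliminated per round (deterministic,
ties to the lower registry index; constant features are removed first
with score 0). Features are standardized before each fit; the
cross-validation curve standardizes inside each training fold to avoid
leakage. Redundant features (|Pearson r| > 0.95) are collapsed onto the
higher-ranked member before the curve is evaluated, and the chosen subset
is the smallest redundancy-filtered rank prefix within 0.01 of the best
stratified k-fold accuracy (k = 5, capped at the minority class size).
A linear kernel is the only choice under which "perturbing the SVM
objective" gives a well-defined per-feature score; C, k, the tolerance
and the correlation cut are all configurable.

On cleanly separable synthetic data the minimality rule legitimately
returns one- or two-feature subsets (a single perfect separator is
enough); the test suite therefore checks the *composition* claims (a mix
of leaf-color and sheath-color characteristics for stage 1; the
white-region area for stage 2) on the top ranks of the
redundancy-filtered ranking at the reference subset sizes, not on the
minimal subset.

## Fisher discriminants and the cascade

Two-class rule: w ∝ (S_w + εI)⁻¹(μ_A − μ_B) with S_w the pooled
within-class scatter and ε = 10⁻⁶·tr(S_w)/n by default (color channels
within a subset are strongly correlated, so the scatter can be
near-singular). The threshold is the midpoint of the projected class
means; scores at the threshold go to the first-listed class
(documented, deterministic). An optional prior shift subtracts
ln(n_A/n_B) from a covariance-scaled threshold; it is off by default
because the designs here are class-balanced. The multi-class variant
takes the leading generalized eigenvectors of S_b v = λ(S_w + εI)v and
classifies by the nearest class centroid in canonical space; with two
classes it is decision-equivalent to the two-class rule.

Cascade: stage 1 (Normal vs deficient, trained on all samples), stage 2
(N vs P∪K, trained on the deficient samples), stage 3 (P vs K). At
prediction time a sample stops at the first stage that claims it; a
deficient sample wrongly accepted as Normal stays Normal (no recycling),
which matches an accounting where only samples correct at every stage
count as correct. The stage-1 "non-normal" pool is the plain union of
the three deficiency classes (balanced by design). Default stage subsets
are the reference ones — {LG, LA, LSL, LTR, LTG, LSR, LSG, LSB},
{LG, LB, LSG, LSB, WRA} and {LG, LI, LSL, A/L, LS23, LTG, LSG} — with a
`text_variant` preset that replaces the stage-3 leaf-spacing term LS23 by
the leaf-length difference L23 (both appear in the original description)
and an `auto` mode that re-derives each stage's subset by SVFS. The flat
four-class baseline uses the 10-feature all-stage "universal" subset.
Models are independent per leaf position; the best position is the
accuracy argmax with ties to the older leaf.

## Problem sizes and determinism

Simulated studies in the tests and acceptance script use 50 plants per
class (25 for validation) at 50 dpi, with 20 independent seeds for the
statistical assertions (a claim must hold in ≥ 95 % of seeds);
single-organ oracle tests run at the native 300 dpi. All randomness
flows from explicit `numpy` generators; regenerating with the same seed
reproduces images and truth tables bit-identically.

## Known limitations

* The symptom profiles are qualitative reconstructions; absolute
  accuracies on synthetic data (typically ~100 % under the defaults) say
  nothing about accuracy on real scans.
* One organ per image; no multi-object scans, rulers or shadows.
* "Vein length" is approximated by the skeleton geodesic diameter; true
  venation is not imaged.
* The white-region segmentation is threshold-based; sheaths with glossy
  highlights could produce spurious candidates on real scans.
* Growth-stage-specific feature subsets are shipped as presets only and
  are not re-derived from real data.
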
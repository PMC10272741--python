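# Methods

This note documents the models and procedures implemented in
`orchardvision`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic test scenes do
and do not demonstrate.

## Scope and assumptions

The package targets single daylight RGB frames of row-crop orchards
(vineyards in particular) seen from a ground robot: a soil road in the
lower-central frame, green vegetation rows flanking it, sky at the top,
fruit that is darker and differently hued than foliage.  Everything is
classical image processing; there is no learned component.  The detector
stage is a *contract* — any callable mapping an RGB image to a list of
scored boxes — so a trained network can be plugged in later; the shipped
reference detector is a colour-blob detector for dark purple grape
clusters.

Two conventions hold throughout:

* images are `H x W x 3` uint8 RGB arrays; row 0 is the top of the frame;
* HSV uses the 8-bit machine-vision scale, H ∈ [0, 180), S, V ∈ [0, 255].
  The published segmentation thresholds are only meaningful on this scale.

## Preprocessing chain

Fixed stage order: ROI crop → bilateral smoothing → log V transform →
MSRCR → saturation gain.  Every stage maps constant images to constant
images, a property the tests rely on.

| parameter | default | meaning |
|---|---|---|
| `roi_fraction` | 5/6 | fraction of bottom rows kept (sky removal); `floor(roi_fraction * H)` rows |
| `bilateral_d` | 60 px | pixel-domain diameter of the bilateral filter |
| `sigma_space` | 120 px | spatial standard deviation |
| `sigma_intensity` | 60 | range (intensity) standard deviation |
| `log_gain_c` | 1 | gain of the V-channel log transform |
| `msrcr_scales` | 15, 80, 250 px | Gaussian surround scales (canonical three-scale retinex) |
| `msrcr_weights` | 1/3 each | scale weights, must sum to 1 |
| `msrcr_alpha`, `msrcr_beta` | 125, 46 | colour-restoration nonlinearity and gain |
| `msrcr_gain_G`, `msrcr_offset_b` | 192, −30 | output gain / offset |
| `msrcr_eps` | 1 | added inside every logarithm |
| `msrcr_stretch_pct` | 1 % | per-side percentile clip of the final dynamic-range stretch |
| `alpha_s` | 0.4 | saturation gain coefficient |

Numerical details and deliberate choices:

* **Bilateral filter.**  Implemented as a bilateral grid (splat into a
  coarse space × intensity grid, blur the homogeneous grid, slice back with
  trilinear interpolation).  Cost is independent of the kernel diameter,
  which makes the 60 px diameter affordable on 1024 × 473 frames.  Since a
  direct bilateral kernel is truncated at radius d/2 no matter how large
  σ_space is, the effective spatial sigma is `min(sigma_space, d/2)`.
  Constant images are reproduced exactly (the grid ratio is exact for
  constants).
* **Log V transform.**  The V channel is normalised to L ∈ [0, 1], mapped
  to `c · log(1 + L)` and rescaled by 1/log 2 so that L = 1 stays at full
  scale.  This keeps the output displayable without clipping and makes the
  transform monotone and endpoint-preserving.  H and S are untouched.
* **MSRCR.**  Base-10 logs with ε = 1 added to every intensity; the
  surround is a Gaussian blur per scale; the colour-restoration factor is
  computed per pixel from the channel's share of the pixel's channel sum.
  Large surrounds (σ > 20 px) are computed on a ~σ/10-decimated copy and
  resampled back — the error is far below quantisation for such smooth
  surrounds.  The raw gain/offset output `G(C·R + b)` spans thousands of
  units; following standard retinex practice the result is restored to
  [0, 255] with a per-channel percentile stretch (1 % per side).  When a
  channel has no dynamic range to restore (constant retinex output, e.g. a
  flat input channel) enhancement is undefined and the input channel is
  kept unchanged — this keeps flat frames intact instead of collapsing
  them to black.
* **Saturation gain.**  `T` is evaluated per pixel from that pixel's own
  R, G, B values (the only self-consistent reading of the formula), with
  T = 0 for black pixels.  For a neutral pixel T = 3, so α_s T = 1.2.
* **Quality metrics.**  PSNR = 10·log10(255²/MSE) over all channels, with
  identical frames flagged infinite rather than capped.  IE is the Shannon
  entropy (bits) of the 256-bin histogram of the *grayscale* conversion
  (Rec. 709 luma); AG averages `sqrt((dx² + dy²)/2)` with central
  differences over interior pixels of the same grayscale.  Whether the
  sources computed these on gray or per-channel images is not stated
  anywhere we could rely on; grayscale is the choice and it is fixed here.

## Dual-space road extraction

Vegetation is found twice, independently, on the fully preprocessed image
(per the serial flow of the pipeline):

* HSV box, inclusive at both ends: H ∈ [35, 77], S ∈ [43, 255],
  V ∈ [46, 255];
* optimised gray factor `gray = 1.84·G − B − R`, kept as signed reals
  (never clipped), binarised at T_B = 10 with the ≤ branch mapping to road
  candidate exactly as printed (a gray value of exactly 10 is road).

**Fusion** is the intersection of the two road complements — equivalently,
a pixel counts as vegetation if *either* route says so.  This is the
reading that "constrains" road edges and removes disturbances: each route
vetoes the other's false road pixels.

**Morphology.**  Closing then opening with a disk footprint (default
diameter 15 px), then connected components (8-connectivity) are filtered
by area (default ≥ 500 px²) and the largest component touching the bottom
image row is kept.  Closing runs *first* because the fused mask of a noisy
frame carries a few percent of salt holes; opening-first would erase the
entire road (no clean 15 px disk fits anywhere).  The final mask is
intersected with the input support, so cleaning never invents road pixels
and `morph_clean(m) ⊆ m` holds as an invariant.  An empty result is the
"no road" flag (`Mask.is_empty`).

**Otsu baselines.**  The in-package Otsu implementation min-max scales the
input onto [0, 255], histograms it into 256 unit bins and exhaustively
maximises the between-class variance (ties go to the lowest threshold;
the split is constrained so both classes are non-empty).  The saturation
baseline thresholds the HSV S channel, the ExG baseline thresholds
`2G − R − B`; in both, the *low* side (dull soil / low green dominance) is
labelled road.  That polarity is a documented choice — it is the only one
consistent with soil being less saturated and less green than foliage.

## Evaluation metrics

* `NWP` counts pixels claimed road by the algorithm that are not road in
  truth ("wrongly extracted"); a symmetric option adds misses but is off
  by default.  `RBP = 100·NWP/NRP` with NRP the ROI pixel count.
* Detection matching is greedy in descending confidence (ties keep input
  order); each ground-truth box is claimed at most once; a match requires
  IoU ≥ the threshold (default 0.5) and takes the highest-IoU unclaimed
  box.  P, R and F1 follow the usual count definitions, with degenerate
  denominators yielding 0.
* AP is the area under the all-point interpolated precision–recall
  staircase (precision envelope from the right); mAP averages per-class AP
  and equals AP for the single "fruit" class.  AP with no ground-truth
  boxes is undefined and returned as NaN.
* CIoU loss uses the standard weight `α = υ/((1 − IoU) + υ)`.  A widely
  circulated typeset variant shows `(1 + IoU)` in the denominator; that
  form breaks the analytic limit L = 0 for identical boxes and is treated
  as a misprint.  The 0/0 case (identical boxes) is defined as α = 0.
* BCE clamps confidences to [1e−7, 1 − 1e−7].
* Internally all rates live in [0, 1]; percent formatting (2 d.p. for RBP,
  1 d.p. for P/R/F1/mAP) happens only in report output.

## Synchronous detection

`synchronous_detect` runs preprocessing + road extraction once, then the
detector on the preprocessed ROI with the extracted road blacked out — the
road result is literally the input to recognition.  The crop-only variant
(`mask_road=False`) is kept because masking trades context for less
interference.  Detections with ≥ 90 % of their box area on the final road
mask are dropped (fruit hangs beside the road, not on it); the threshold
is configurable.  Per-stage wall time is recorded but never asserted in
tests — it is hardware-dependent.  `compare_protocol` runs a detector with
and without the pipeline over an image batch and reports detection counts,
mean per-frame time, and promotion ratios `(V_w − V_n)/V_n` for count and
speed.

The reference `hue_blob_detector` thresholds hue ∈ [118, 172] with
saturation ≥ 30, groups pixels by 8-connectivity, and keeps components of
at least 120 px (a full-frame default; scale it with the image, e.g. 20 px
for 256-px-wide test scenes).  Confidence is component area relative to
the largest component — a crude but monotone proxy.

## Synthetic scenes

`generate_scene` renders, deterministically per seed from a single
`numpy.random.default_rng` stream: a sky band (top 1/6), green vine rows
whose pixels are sampled *inside* the HSV green box (hue 40–72 on the
8-bit scale), a central soil road trapezoid (top width 18 % of the frame,
bottom 55 %) with low-frequency edge jitter, bare-soil "leaf gap" ellipses
near the road edge, grape clusters built from overlapping berry ellipses —
half of them hung at the road edge so they overhang the road the way real
fruit overhangs the row boundary — multiplicative elliptical shadows
(factor 0.5) on the road, and additive Gaussian noise (σ = 5).  Soil
colours are chosen so the optimised gray factor stays ≤ 0 on virtually all
road pixels before noise; shadows preserve that sign because darkening is
multiplicative.

What the scenes exercise: the colour logic of both segmentation routes,
fusion, morphology, shadow robustness, the interference of fruit and leaf
gaps at the road edge (which is what makes the with/without-preprocessing
ablation informative), and detector/geometry plumbing.  What they do not
show: performance on real photographs — there is no texture, no
perspective-correct foliage, no specular highlights, no weeds, no
inter-row road adhesion, and noise is i.i.d. Gaussian.  Passing the
synthetic suite demonstrates internal correctness and the expected
qualitative ordering of methods, not field accuracy.

Test problem sizes: unit tests use 256 × 156 scenes; the statistical
acceptance checks use 50 full-size (1024 × 473) scenes, which keeps the
whole suite around three minutes on one CPU.

## Known limitations

* The road component must touch the bottom image row; a road fully
  occluded at the bottom (e.g. by a fallen branch) is reported as absent.
* No inter-row disambiguation: two drivable corridors merging at the
  horizon are returned as one component if connected.
* The MSRCR stretch makes enhanced colours frame-relative; absolute colour
  thresholds downstream of it are robust only because both segmentation
  routes are re-applied to the same stretched frame.
* The blob detector is a stand-in: it knows nothing about occlusion,
  berries against purple-tinged soil, or cluster adjacency, and its
  confidence is not calibrated.
* Timing figures from `compare_protocol` depend on image size and CPU; only
  their ratio across arms is meaningful, and even that should be averaged
  over many frames.
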
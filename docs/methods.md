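# Methods

This note documents the models, numerical choices and known limitations
of `sporeseg`.  It covers the preprocessing pipeline, the attention-gated
UNet and its training, the particle-analysis stage, and the synthetic
scene generator that stands in for annotated microscopy data in the test
suite.

## Preprocessing

Brightness normalization is `I_norm = (I − µ)/σ` with µ and σ computed
over all pixels of the frame.  σ uses the population definition (divide
by N): the transform is a whitening of the empirical pixel
distribution, not an inferential estimate, so no sample correction is
applied.  A constant frame (σ = 0) returns all zeros with a logged
warning rather than raising, so unattended batch jobs survive blank or
saturated frames.

Histogram equalization is defined on discrete gray levels, while the
normalized image is real-valued; the composition is resolved by
re-quantizing the normalized image to `levels` bins (min–max to
0..levels−1, default 256) before building the cumulative transform
`T(r) = Σ_{k≤r} n_k/N` and mapping each level r to
`round((levels−1)·T(r))`.  The mapping is monotone non-decreasing, so
pixel rank order is preserved; the output CDF at every populated level
is within half a bin of the uniform ramp by construction.  Equalization
is global per frame (not per patch), which matches how illumination
artifacts vary.  Network inputs are finally rescaled to [−1, 1].

Patches are cut on a non-overlapping grid from the top-left corner
(right/bottom remainders discarded; the source data's patch counts
constrain the tiling only up to this choice), and kept only when the
foreground fraction of the mask strictly exceeds `min_occupancy`
(default 5%).  Augmentation applies the identical geometric transform
to image and mask: multiples of 90° rotation, horizontal/vertical
flips, and scaling in 0.8–1.2 (bilinear for the image,
nearest-neighbour for the mask so it stays binary), deterministic given
a seed.  The scale range is a conservative choice; spore size variation
in the generator already covers most of the realistic range.

## Network

A four-level encoder–decoder UNet with double 3×3 convolutions (same
padding, batch normalization + ReLU after each convolution), 2×2 max
pooling, bilinear 2× upsampling (half-pixel centres, edge clamp,
implemented as two small interpolation-matrix products so the adjoint
is exact), skip concatenation, and a 1×1 output convolution producing
one logit channel.  Design points that were genuinely open and how they
were fixed:

- **Base width 64** (classic UNet) with channels doubling per level;
  configurable, and the reduced test configuration uses depth 3 /
  base 16.
- **Attention is applied to skip features only**; the main encoder
  stream reaches the bottleneck unmodified.
- **Spatial gate**: θ_x from a 2×2 stride-2 convolution of the skip
  feature x; φ_g from a 1×1 convolution of the gating signal g
  (upsampled if its resolution is below θ_x's); ψ = σ(1×1·ReLU(θ_x +
  φ_g)); the gated product x⊙Up(ψ) is restored to C_x channels by a 1×1
  convolution + batch normalization.  The gating signal at each level
  is the decoder (or bottleneck, at the deepest skip) feature one
  resolution step deeper, taken *before* upsampling, so its spatial
  size is exactly half of x's.  C_int = C_x/2 by default
  (`inter_channels_ratio`).
- **Channel attention**: squeeze-excitation (global average pool →
  bottleneck with reduction 8 → sigmoid channel weights) on each skip,
  ON by default, with a config switch.  The design is under-determined
  by its description; SE is the standard minimal choice.
- **Gates at every skip, none at the bottleneck** (the bottleneck has
  no skip to gate).
- **Initialization**: He-normal for convolution weights, zero biases,
  unit/zero batch-norm affine parameters, all from one seeded
  generator, so construction and training are bit-reproducible on one
  device.

Full frames larger than the network input are segmented by tiled
inference: input-size tiles, 32 px overlap, sigmoid probabilities
averaged in overlaps, cropped back to the original size.  Frames
smaller than a tile (or not divisible by 2^depth) are reflect-padded
and cropped back.  Binarization threshold is 0.5 (strictly greater).

The network, reverse-mode autodiff and Adam are implemented directly on
numpy (`sporeseg.autograd`): im2col convolutions laid out so the slice
copies run near memory bandwidth, argmax-routed max-pool gradients, and
a batch-norm backward using the standard whitening derivative.  Every
operator's gradient is checked against central finite differences in
float64 in the test suite; training runs in float32.

## Training

Adam with learning rate 0.002, β₁ = 0.9, β₂ = 0.999 (the customary
values; only the learning rate is externally constrained), batch
size 16, a fixed epoch budget (50 by default; no early stopping).  The
loss is binary cross-entropy on the logits, optionally compounded with
a soft-Dice term (`loss_name="bce_dice"`); the original training
procedure does not name its loss, and BCE is the minimal choice
consistent with per-pixel accuracy tracking.  Validation loss/accuracy
are computed in evaluation mode (running batch-norm statistics).
Non-finite loss aborts with a diagnostic rather than training through
NaNs.

## Evaluation metrics

Pixel-level confusion counts (foreground = positive) pooled over a
split (micro-averaging), then

accuracy (TP+TN)/total, precision TP/(TP+FP), sensitivity TP/(TP+FN),
specificity TN/(TN+FP), F1 2TP/(2TP+FP+FN), IoU TP/(TP+FP+FN).

Undefined ratios (zero denominator) are reported as 0 with a logged
warning, keeping batch evaluation total.  The identity
F1 = 2·IoU/(1+IoU) holds algebraically and is asserted in the tests.
The confusion-matrix figure/CSV uses rows = truth, columns = predicted,
ordered [foreground, background].

## Particle analysis

Connected components under 8-connectivity (diagonal contact joins, the
ImageJ default).  Circularity is 4πA/P² clamped to [0, 1]; a
single-pixel particle (zero estimated perimeter) is assigned
circularity 1 by convention and is in any case removed by the 50 px
area floor.  The perimeter estimator is Crofton (4 directions): it is
asymptotically unbiased on smooth shapes — rasterized disks of radius
10/20/40 measure circularity 0.94/0.97/0.99 — whereas naive pixel-edge
counting would push even perfect disks far below 1 and distort the
circularity filter windows.  Filter bounds are inclusive on both area
and circularity (the printed ranges state no strictness).  Physical
areas are `area_px / px_per_um²` at ≈16.5 px/µm; note 750 px is
2.75 µm² at exactly 16.5 px/µm — a printed value of 2.7 µm² for the
same bound is consistent with a slightly different effective
resolution or display rounding.

Fused particles (2–3 objects joined by a pixel bridge) can be split by
a morphological opening (3×3 structuring element,
`split_fused_particles`); it is OFF by default because fusions affect
only fractions of a percent of particles and opening slightly erodes
sizes.

Germination quantification: particles passing the time-point filter are
partitioned by whether they still meet the pre-incubation spore window
(area 50–750 px, circularity 0.2–0.95 — the same settings as the 0-min
filter); the germination rate is germinated/total.  Distribution
summaries use linear-interpolation percentiles (median and 5–95%
range).

## Synthetic scenes

The generator emulates the germination assay's two time points: dried
spores only (t0) and a spore/cell mixture (t120), with defaults pinned
to the assay's measured morphometry at 16.5 px/µm — spores: area median
1.11 µm² (5–95%: 0.6–1.97), circularity median 0.86 (0.71–0.93); cells:
area median 3.73 µm² (5–95%: 0.33–10.06), circularity median 0.58
(0.30–0.90).  Areas are lognormal, parametrized so the median matches
and the 5–95% log-range matches (two parameters cannot also pin both
range endpoints independently; the induced endpoints agree with the
stated ones to ~2%).  Because the spore-area distribution is reported
as close to normal, a truncated-normal option is provided
(`spore_area_family="truncnorm"`).  Circularities are logit-normal
fitted the same way, which keeps draws in (0, 1).

Spores are rendered as ellipses whose axis ratio is solved (Ramanujan
perimeter) from the drawn circularity; cells as straight
capsules (rectangle + semicircular caps) solved the same way.  Bent
cells and dividing chains are not modelled.  Objects are placed
uniformly with bounded retries under a maximum-overlap constraint
(default: no overlap); `min_separation_px` additionally forbids contact
merges, which the closure tests use.  The scene image is mid-gray with
a smooth directional illumination ramp, objects darker than background
with a brighter rim (brightfield-like), additive Gaussian noise, and
debris (random-walk blobs) drawn into the image but excluded from the
ground truth so downstream false-positive behaviour is measurable.  The
mask is exactly the union of the rasterized polygon annotations
(pixel-centre, boundary-inclusive membership), so annotation → mask
closure is bit-exact by construction and asserted over many seeds.
Contrast inversion under focus drift is exposed only as a
`contrast_polarity` flag; point-spread/defocus optics and timelapse
frame-to-frame continuity are not modelled.

**What passing tests do and do not show.**  The generator's scenes are
easier than real micrographs: object contrast is consistent, debris is
morphologically distinct, and there are no overlapping or dividing
cells.  Learning-sanity results on synthetic data (validation IoU
far above trivial baselines) demonstrate that the architecture,
gradients and training loop work, not that the reported real-data
accuracy transfers.  Conversely, the worked-example arithmetic, metric
formulas, rasterization and morphometry checks are exact properties
that hold regardless of data realism.

**Morphology-window ambiguity.**  Under the assay's own measured
distributions, a substantial fraction of outgrown cells falls inside
the pre-incubation spore window (≤750 px ≈ 2.75 µm²), so a
morphology-based germination rate is not a consistent estimator of the
true cell fraction when populations overlap.  The pipeline's closure is
therefore tested in two forms: (a) the reported rate equals the same
classification rule applied to the generator's truth table, exactly;
and (b) when the cell population is drawn well above the spore window,
the rate recovers the true cell fraction within binomial error.

## Problem sizes

The reduced end-to-end configuration used by the demo, the acceptance
script and the learning-sanity tests: depth 3, base 16 channels, 64×64
patches from 256×256 scenes (~170–200 training patches, ~45
validation), 15 epochs, batch 16 — chosen as the smallest configuration
that cleanly separates a trained network from trivial-predictor
baselines on one CPU.  Morphometry recovery uses 5000 sampled shapes;
rasterization closure 50 seeded scenes.
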
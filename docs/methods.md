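# Methods

## Problem and pipeline

Cone photoreceptors appear in AOSLO images as bright, roughly isotropic
spots (confocal channel) or as horizontally bipolar bright/dark lobe
pairs (split-detector channel, the difference of two horizontally
offset detectors). The detector works in two decoupled steps: a fully
convolutional network produces a per-pixel cone-probability map, and a
morphological localization chain reduces that map to sub-pixel cone
coordinates. The two steps are fitted separately and in order: the
network is trained first; the localization parameters are then selected
by exhaustive sweep on the probability maps of the *training* images;
only afterwards are held-out images inferred, localized and scored.
Test data never influences either fit.

## Network

A modified U-Net with, per resolution level, a single block of
zero-padded 3×3 convolution → ReLU → batch normalization, followed by
2×2 stride-2 max pooling on the encoder side. Channel counts start at
`base_filters` and double per level. The bottleneck block applies
dropout at rate 0.5 (training only). The decoder mirrors the encoder
with 2×2 stride-2 transposed convolutions; at each level the upsampled
features are concatenated with the same-level encoder features (skip
connection) before the level's conv block. A 1×1 convolution to two
channels and a per-pixel softmax yield class probabilities; the
cone-class channel is the probability map. Zero padding makes the
output spatially identical to the input for any input size divisible by
`2^depth`.

Inputs are min–max normalized per image to [0, 1]; a constant image
normalizes to all zeros with a warning. Targets are binary label maps
made by stamping a diamond (Manhattan ball) of radius 0–3 px around
each truth cone, rounded to the nearest pixel (half away from zero);
the dilation counters the extreme sparsity of single-pixel labels.
Radius 3 is the default. For the rotation-invariant confocal modality
the training set is augmented with the four 90° rotations (image, label
map and coordinates transformed together; counter-clockwise by
convention); split-detector data is never rotated because its lobe
orientation is physically meaningful.

Training minimizes unweighted per-pixel two-class cross-entropy (an
optional class-weight pair is exposed but off by default) with SGD,
momentum 0.9, learning rate 1e-2, batch size 8, for a fixed number of
epochs (default 50; no early stopping, no validation split). Weights
use He-scaled small random initialization. Weight init, per-epoch
shuffling and dropout all derive from a single seed, so a training run
is bit-reproducible in a fixed environment. The network is implemented
directly on numpy (im2col convolutions via `sliding_window_view` +
BLAS `tensordot`, hand-written backward passes, verified against
numerical differentiation in the test suite).

Architecture defaults are depth 4 with 64 base filters (U-Net
heritage); a `tiny` preset (depth 3, 8 base filters) trains on one CPU
in about a minute per ten epochs at 96 px and is what the test suite
and acceptance script use. At inference, dropout is off and batch norm
uses its frozen running statistics, so prediction is a pure function.

## Localization

Given probability map `P`:

1. `smooth = gaussian(P, sigma)` — kernel truncated at radius
   `ceil(4*sigma)`, reflective boundary; `sigma = 0` skips smoothing.
2. Extended-maxima transform with tolerance `h`: morphological
   reconstruction by dilation of `P - h` under `P` (8-connected), then
   the regional maxima of the reconstruction, labeled as 8-connected
   components. A constant map is a single whole-frame plateau with no
   higher neighbor and therefore one region (the underlying library
   primitive returns no maxima for a constant image; this is the one
   special case handled explicitly, and the brute-force
   reconstruction-to-fixpoint oracle in the tests covers it).
3. A region is kept iff the maximum of the *original* map over its
   pixels is ≥ `t`. Maximum is the natural statistic for regions that
   mark maxima; `mean` is available as an option for sensitivity
   analysis.
4. Surviving regions are relabeled in scan order and reduced to
   unweighted pixel centroids (sub-pixel).

The sweep evaluates every (sigma, h, t) in an ascending grid — defaults
sigma 0:0.1:2, h 0:0.1:1, t {0, 0.05, …, 0.3, 0.4, 0.5}, 21·11·9 = 2079
combinations — scoring each by mean per-image Dice on the training
maps (images with undefined Dice excluded). Ties break toward the
lexicographically smallest triple, making the sweep deterministic. The
objective (Dice) is this package's choice; so is "max" as the filter
statistic — both points are deliberately exposed as options.

## Evaluation protocol

Cropping leaves partial cones at borders, so a band of `pad = 2` px
inside each border is a free zone; the rest is the testing area. A
sub-pixel point is in the free zone iff its floor pixel is in the band.
Free-zone *predictions* are disregarded. The remaining predictions are
matched one-to-one to truths anywhere in the frame, greedily by
ascending Euclidean distance among pairs within `max_dist` (default
4 px, about half a cone spacing at these scales; the matching criterion
is this package's declared convention), ties broken by (prediction
index, truth index). Matched predictions are true positives — including
matches to free-zone truths; unmatched testing-area predictions are
false positives; unmatched testing-area truths are false negatives;
unmatched free-zone truths are excluded. TPR, FDR and Dice follow from
the counts; a zero denominator yields NaN, which is flagged, excluded
from aggregation and counted, never silently zero. An optional greedy ↔
optimal-assignment switch is not provided; greedy was chosen for
auditability and determinism.

Repeat experiments retrain from scratch with fresh seeds (default four
runs) and report the pooled per-image mean and sample standard
deviation (ddof = 1; 0 for a single value) per metric.

## Synthetic mosaics

The generator emulates the *geometry and first-order appearance* of
AOSLO crops: a triangular (hexagonal-packing) lattice at mean spacing
`spacing` (default 9 px at 144 px frame scale), independent 2-D
Gaussian positional jitter (SD 0.8 px), optional site dropout,
rendered as isotropic Gaussian spots (SD 2 px, amplitude 0.8 on
background 0.1) for confocal or as a horizontal difference of two
Gaussians offset ±`blob_sigma` (bright left lobe, dark right lobe, on
mid-gray 0.5) for split detector, plus additive Gaussian noise
(SD 0.05) and clipping to [0, 1]. Every sample is deterministic per
seed; dataset seeds are spawned from a master seed.

What it does **not** model: optical blur and its field variation,
intensity vignetting, motion/scan artifacts, pathology-induced mosaic
disruption, inter-subject spacing variation, annotation noise. Passing
tests on these mosaics therefore demonstrate that the pipeline's
machinery — learning, localization, protocol — is correct and can
recover a mosaic of realistic scale from noisy renderings; they do not
certify performance on clinical images.

## Problem sizes and numerical choices

The test suite and acceptance script use the tiny network preset on
96-px mosaics: 100 training images, 10 epochs, a reduced sweep grid
(σ∈{0.5,1}, H∈{0.2,0.4}, T∈{0.1,0.2}) and 20 held-out images — sizes
chosen so a full run takes minutes on one CPU while still exercising
every stage end to end. Under these conditions the trained tiny network
reaches a mean held-out Dice of about 0.97, versus essentially zero for
an untrained network with the same localization parameters.

Degenerate inputs are handled explicitly: constant images normalize to
zero (warned); sigma = 0 smoothing and t = 0 filtering are identities;
empty cone sets round-trip through CSV; an empty map localizes to an
empty set; undefined metric ratios propagate as flagged NaN. Cone
coordinates are 0-based (x = column, y = row, origin top-left)
everywhere; 1-based annotation sources are converted once at read time
(`one_based=True`). Central cropping with an odd remainder puts the
extra row/column at the bottom/right.

## Known limitations

- The numpy network is CPU-bound; the default (depth 4, 64 filters)
  configuration is provided for completeness but is slow to train at
  scale — the design target is the tiny preset on synthetic data.
- Greedy matching is order-dependent in principle; the documented
  distance-then-index tie-break makes it deterministic, but it is not
  guaranteed to maximize the number of matches (optimal assignment
  could differ on pathological configurations).
- Dice values are only comparable across studies under the same
  matching distance and matcher, which published protocols often leave
  unspecified.
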
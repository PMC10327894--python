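# Methods

## Preprocessing model

Sentinel-2 Level-processed scenes carry 13 bands at 10/20/60 m. The three
60 m atmospheric bands (B1 coastal aerosol, B9 water vapour, B10 SWIR
cirrus) contribute little to crop discrimination and are dropped; the six
20 m bands (B5–B7 red edge, B8A narrow NIR, B11/B12 SWIR) are upsampled to
10 m by bilinear interpolation and fused with the four native 10 m bands
into a 10-channel stack in fixed ascending band order
B2,B3,B4,B5,B6,B7,B8,B8A,B11,B12. The order is a frozen convention: the
network's input stem is trained against it.

Bilinear resampling uses the half-pixel-center alignment convention
(output sample *i* maps to source coordinate `(i+0.5)*scale - 0.5`, borders
clamped). The convention is fixed by an independent brute-force oracle in
the test suite; any consistent convention would do, but it must not drift.

Cross-scene radiometry is aligned by a percentage linear stretch

    result = (DN - min_in)/(max_in - min_in) * (max_out - min_out) + min_out

per band, where the output bounds are the reference scene's band range and
the input bounds are the target scene's (optionally after clipping a
`clip_percent` fraction of each histogram tail; default 0, i.e. true
min/max). DN outside the input range map outside the output range and are
clipped to it — the degenerate cases (constant band) raise rather than
divide by zero. Stretched values stay in floating point internally and are
rounded half-to-even only on integer GeoTIFF export, to avoid compounding
quantization.

GeoTIFF I/O is a deliberately small tifffile-backed layer (ModelPixelScale,
ModelTiepoint, an EPSG-only GeoKeyDirectory, JSON metadata in
ImageDescription). It round-trips what this pipeline writes; it is not a
general GeoTIFF implementation.

## Dataset construction

Scenes are cut into non-overlapping 512x512 tiles in row-major order;
trailing strips narrower than a tile are dropped rather than padded, which
avoids label-padding artifacts at the cost of a sliver of area. Tiles whose
crop coverage (fraction of pixels labelled canola or wheat) is below 0.30
are removed; the boundary is inclusive (exactly 30 % is retained). The
surviving tiles are split uniformly at random 7:3 into train/validation
under a seed; the first `floor(0.7 n)` of the permutation train.

Augmentation is restricted to right-angle rotations and axis mirrors so
masks never need interpolation; masks are nearest-neighbour everywhere.
Additive noise is zero-mean Gaussian with sigma expressed as a fraction of
each band's within-tile range (default 0.01) and touches the image only.
Augmentation is applied on the fly with a per-epoch seed derived from the
global seed, giving reproducible yet unbounded augmentation streams.

## Network

Encoder: ShuffleNet v2 at width 1.0x (stage widths 24/116/232, repeats
4/8), truncated after Stage3. The truncation follows from the three decoder
taps (stem conv, max-pool, Stage3) and the 512→32 deep-feature scale, which
force output stride 16; Stage4 and Conv5 would never be consumed. The basic
unit splits channels in half, transforms one half through
1x1 → depthwise 3x3 → 1x1, concatenates, and channel-shuffles with two
groups (a pure reshape–transpose permutation). The downsampling unit drops
the split, strides both branches by 2 and doubles channels on
concatenation. Batch normalisation + ReLU follow every convolution except
depthwise convolutions (BN only, the ShuffleNet v2 convention) and the
final transpose convolution; inference uses running statistics.

Context head: ASPP with dilations 6/12/18 and 256 output channels — the
DeepLab v3+ defaults at output stride 16 — followed by a 3x3 refine
convolution to 240 channels at the deep scale.

Decoder: 4x bilinear upsample, CBAM (channel attention with a shared
two-layer MLP at reduction 8, then spatial attention with the fixed 7x7
kernel), concatenation with the 1x1-reduced (48 ch) mid-level skip, a 3x3
refine to 184 channels, 2x bilinear upsample, concatenation with the
1x1-reduced (48 ch) low-level skip, a 3x3 refine to 244 channels, and a
kernel-4 stride-2 padding-1 transpose convolution to the 3 class scores.
Weight init is Kaiming-normal for convolutions, zeros for biases, under a
seed carried in the configuration.

### How the free decoder widths were fixed

The architecture narrative pins the wiring but not every width. The deep
refine width (240), mid refine width (184), low refine width (244) and the
channel-attention reduction (8) were calibrated once, by exact search over
the per-convolution parameter/FLOP formulas, so that the assembled network
lands on the published complexity envelope of this design point:
3,886,866 weight parameters (3.89 M), 47.53 GFLOPs at 512x512, and
3,872,368 parameters (3.87 M) with CBAM removed. A reduction ratio of 16
was rejected because it makes the attention block too small for the
on/off parameter totals to differ at two printed decimals; 8 is the
smallest standard ratio consistent with both totals. These widths are
declared in `NetworkConfig`, recorded in every profiler report, and frozen
in the test suite.

## Training

Mean per-pixel softmax cross-entropy (the per-pixel sum form needs a
reduction once tiles are batched; the mean decouples the learning rate from
tile size), Adam with betas (0.9, 0.999) and eps 1e-8, and the polynomial
schedule `base_lr * (1 - epoch/max_epoch)^power` evaluated per epoch
(defaults 0.001 / 50 / 0.9, batch size 4). No class weighting or ignore
index: background is a legitimate class. Model selection keeps the
checkpoint with the best validation mIoU, evaluated every epoch. Non-finite
loss aborts with a diagnostic. With a fixed seed a run is reproducible on a
given machine (numpy kernels are deterministic; BLAS threading is the only
environmental variable).

## Metrics

All metrics derive from one aggregated confusion matrix over the evaluated
pixels (micro aggregation), rows true, columns predicted, background
included as a class. mIoU averages `TP/(TP+FP+FN)` over classes; overall
accuracy is the multi-class generalisation `trace/sum`; recall is the macro
average of per-class `TP/(TP+FN)` over classes present in the truth. 0/0
terms — classes absent from both prediction and truth — are excluded from
macro means rather than scored 0 or 1, which would bias small tiles; if
every class is absent the metric raises.

## Complexity accounting

Headline totals follow `K*K*(C_in/groups)*C_out` per layer and that times
`H_out*W_out` for FLOPs (one multiply-accumulate counted once), summed over
convolutions, transpose convolutions (with their own output size) and
fully-connected layers (K=1, unit output). Pooling, activations,
normalisation and elementwise work are excluded from the headline, and
bias/BN parameters are itemized separately, so the headline matches the
usual lightweight-network bookkeeping while the report remains reconcilable
with the framework's trainable-parameter tally (headline + itemized equals
it exactly; a test enforces this). GFLOPs are total/1e9. Output sizes come
from a symbolic shape trace of the forward pass, not from running it.

## Synthetic fixtures

The generator emulates the structure of winter-crop scenes: contiguous
fields (an irregular rectangular grid by default, optionally Voronoi cells)
labelled canola or wheat by a per-field Bernoulli prior, separated by thin
background roads, rendered as per-class 10-band mean DN signatures plus
i.i.d. Gaussian noise (default sigma 60 DN against signature contrasts of
several hundred DN, i.e. well separated but not degenerate). The default
signatures place the canola/wheat contrast in the red-edge/NIR bands as for
real vegetation, but are arbitrary constants — no radiometric, phenological
or atmospheric realism is claimed. Consequently, tests passing on fixtures
demonstrate that the machinery (pipeline, optimization, metrics) is
correct, not that the network reaches any particular accuracy on real
scenes. A raw-scene variant emits 13 bands at native resolutions (block
means of the 10 m rendering, plus junk 60 m bands) to exercise the full
preprocessing chain.

## Problem sizes in the tests

Functional tests use a reduced-width configuration (width 0.5x, repeats
2/4, ASPP 64, decoder 48/48) on 32–64 px tiles; the architecture is
unchanged, only widths shrink. The convergence check trains that
configuration for 30 epochs on 40 easy 64x64 tiles (28 train / 12 val) and
requires validation mIoU > 0.9; the run reaches ≈ 0.99. The full-width
network is exercised once at 10x512x512 to verify the 256/128/32 feature
scales and the 512 output, and profiled symbolically at 512x512 for the
complexity totals. These sizes are the package's choice of smallest
configurations that still exercise every code path.

## Known limitations

* The numpy backend is single-node and CPU-only; it exists to make the
  method self-contained, not to compete with a GPU framework.
* No atmospheric correction, cloud masking or SAFE-archive parsing; inputs
  are assumed already exported as GeoTIFF digital numbers.
* The GeoTIFF layer writes/reads only the tags this pipeline uses.
* Per-epoch (not per-iteration) interpretation of the poly schedule; with
  few epochs the decay is correspondingly coarse.
* Boundary-quality metrics are out of scope; thin-road recovery is assessed
  only through the standard area metrics.
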
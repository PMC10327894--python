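# agrinet

Lightweight attention-based semantic segmentation of winter crops in
10-band multispectral satellite imagery.

## The problem

Winter wheat and winter canola share a planting cycle (sown September to
October, harvested April to May) and must be told apart pixel by pixel in
Sentinel-2 scenes to map planting structure over large areas. Accurate
segmentation networks are usually heavy; equipment in agricultural settings
often is not. This package implements an encoder-decoder network that keeps
the DeepLab v3+ decoding idea (atrous context + low-level skip fusion) while
cutting the backbone down to a ShuffleNet v2 feature extractor and adding a
convolutional block attention module (CBAM), together with the full
surrounding pipeline: Sentinel-2 preprocessing, dataset construction,
training, evaluation metrics and parameter/FLOP accounting.

Because no deep-learning framework is assumed, the network and its training
loop run on a small reverse-mode autodiff engine over numpy
(`agrinet.nn`), with convolutions evaluated as BLAS matrix products.

## The model

The encoder is a ShuffleNet v2 (1.0x, stage widths 24/116/232, stage
repeats 4/8) truncated after Stage3, giving output stride 16. Three taps
feed the decoder: `low` (stem conv, input/2, 24 ch), `mid` (max-pool,
input/4, 24 ch), `deep` (Stage3, input/16, 232 ch). The deep features pass
through ASPP (1x1, three 3x3 atrous convolutions at rates 6/12/18, image
pooling; 256 ch), a 3x3 refine to 240 ch, a 4x bilinear upsample and CBAM:

    M_c(F) = sigma( MLP(AvgPool(F)) + MLP(MaxPool(F)) )        (channel gate)
    M_s(F) = sigma( f_7x7([AvgPool_c(F); MaxPool_c(F)]) )      (spatial gate)

applied in series, each multiplicatively. The gated features are fused with
the reduced `mid` skip (3x3 to 184 ch), upsampled 2x, fused with the
reduced `low` skip (3x3 to 244 ch), and a stride-2 transpose convolution
restores full resolution with one score map per class
{0 background, 1 winter canola, 2 winter wheat}.

Training minimizes mean per-pixel multi-class cross-entropy with Adam under
the polynomial schedule `lr = base_lr * (1 - epoch/max_epoch)^power`
(defaults 0.001, 50, 0.9; batch size 4), with on-the-fly right-angle
rotation / mirror / additive-noise augmentation. Evaluation reports mean
intersection-over-union, overall accuracy and macro recall from an
aggregated confusion matrix.

Complexity accounting follows the per-convolution convention
`params = K*K*C_in*C_out` and `FLOPs = K*K*C_in*H_out*W_out*C_out`
(depthwise layers use `C_in/groups`); bias and batch-norm parameters are
itemized separately. At the defaults the assembled network has
**3.89 M parameters and 47.5 GFLOPs** at 512x512 input, and **3.87 M**
with CBAM removed.

## Worked example

Profile the default network and its attention-free ablation:

```sh
$ agrinet profile --input-size 512 --out report.json
       model  params(M)  GFLOPs   input
        full       3.89   47.53 512x512
no-attention       3.87   47.53 512x512
```

Train a reduced-width configuration on 40 synthetic 64x64 tiles (two crop
classes with distinct red-edge/NIR signatures, thin background roads):

```python
from agrinet import DeepAgriNet, NetworkConfig, TrainConfig, FixtureSpec
from agrinet.synthetic_fixtures import generate_ds_like
from agrinet.training_engine import train

spec = FixtureSpec(scene_hw=(320, 320), field_size_px=(48, 96),
                   road_width_px=3, seed=7)
tiles, manifest = generate_ds_like(spec, 40, tile_size=64)
cfg = NetworkConfig(encoder_width_scale=0.5, stage_repeats=(2, 4),
                    aspp_out_channels=64, deep_refine_channels=64,
                    cbam_reduction=8, skip_reduce_channels_low=24,
                    skip_reduce_channels_mid=24, refine_channels_mid=48,
                    refine_channels_low=48, seed=1)
history, _ = train(DeepAgriNet(cfg), tiles, manifest, TrainConfig(max_epoch=10, seed=3))
print(history.to_frame().round(4).to_string(index=False))
```

which prints (abridged):

```
 epoch     lr  train_loss  val_miou  val_oa  val_recall
     0 0.0010      0.8693    0.1922  0.4888      0.3103
     3 0.0007      0.2703    0.7221  0.9117      0.7833
     5 0.0005      0.1537    0.9100  0.9799      0.9402
     9 0.0001      0.1309    0.9661  0.9927      0.9812
```

The loss falls as the poly-scheduled learning rate decays and the
validation mIoU climbs past 0.9 within a few epochs — the fields are
spectrally easy by construction, so this checks the optimization machinery,
not real-world accuracy.

The other pipeline stages are the `preprocess`, `build-dataset`,
`make-fixtures`, `evaluate` and `predict` subcommands of the `agrinet` CLI;
each is a thin wrapper over the library modules.

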
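# octlayers

Order-constrained retinal layer-height regression and drusen quantification
for optical coherence tomography (OCT).

Drusen — deposits between the retinal pigment epithelium (RPE) and Bruch's
membrane (BM) — are a hallmark biomarker of age-related macular degeneration.
Quantifying them from OCT volumes requires locating retinal layers in every
image column (A-scan) of every cross-sectional slice (B-scan).  `octlayers` is
aimed at researchers who need reproducible, scriptable layer segmentation and
drusen load measurements on OCT volumes, without manual grading.

## The method

**Layer head.**  Instead of pixel-wise semantic segmentation followed by a
shortest-path decoding, the network regresses the height *h_k(x)* of each
layer *k* directly: if a channel map holds 1 at every pixel above a layer and
0 below, the height is the column-wise sum of that channel.  For *N* layers
the head applies, in order,

1. non-negativity: `a = max(z, 0)` on the raw maps,
2. channel cumulative sum: `c_k = a_1 + ... + a_k`,
3. unit clipping: `m_k = min(c_k, 1)`,
4. column sums: `h_k(x) = sum_rows m_k(., x)`.

By construction `0 <= h_1(x) <= ... <= h_N(x) <= H` for *every* real-valued
input — the anatomical ordering of the layers is a hard guarantee, not a
learned tendency — and the stage is differentiable, so the model trains end to
end against a summed-squared-error height loss with sub-pixel accuracy.

**Backbone.**  A fully convolutional stack at constant resolution: an
initialization block (3x3 convolutions widening 1 -> 16 -> 32 -> 64), nine
residual dilated-convolution blocks DB(filters, d1, d2) whose (d1, d2, d1)
dilation patterns grow the receptive field to exactly 721 px without any
pooling, and a sigmoid-gated swish self-attention block.  The default
configuration has 393,923 trainable parameters; both numbers are computed
analytically from the config and serve as self-checks of the transcription
(`octlayers inspect-arch`).  The network core (dilated convolutions via
im2col, batch norm, dropout, Adam with norm/value clipping, manual backward
passes) is implemented in numpy and runs on any CPU.

**Drusen quantification.**  From per-A-scan RPE and BM heights: rectify
(`e(x) = bm(x) - rpe(x)`), estimate the healthy RPE-to-BM offset *d* as the
mean elevation within the mode of the elevation histogram and its two
neighboring bins, voxelize the area between the RPE and the healthy RPE line,
and remove en-face connected components whose maximum height is below 2 px.

A synthetic OCT generator with closed-form ground truth (smooth BM, RPE at
offset *d* with Gaussian drusen bumps, EZ above RPE, bright noisy bands)
makes every stage testable without clinical data.

## Worked example

```python
import numpy as np
from octlayers import (SyntheticConfig, generate_volume, quantify_drusen, dice)

cfg = SyntheticConfig(n_bscans=16, drusen_per_bscan=2.0)   # 128 x 128 B-scans
vol = generate_volume(cfg, np.random.default_rng(3))

# quantify drusen from the (here: exact) RPE and BM heights
result = quantify_drusen(vol.heights[:, 1], vol.heights[:, 2],
                         height=cfg.height, spacing=cfg.spacing)
print(f"healthy RPE offset: {result.offset.d:.2f} px")
print(f"drusen voxels: {result.voxel_count}, volume: {result.volume_um3:.0f} um^3")
print(f"dice vs ground truth: {dice(result.mask.voxels, vol.drusen):.3f}")
```

prints

```
healthy RPE offset: 10.09 px
drusen voxels: 1872, volume: 9905596 um^3
dice vs ground truth: 0.991
```

The recovered offset is the generator's planted 10 px healthy RPE-BM distance
(to within histogram-bin resolution); the Dice of 0.99 against the exact
drusen mask shows the rectify/offset/filter pipeline loses almost nothing
beyond voxel discretization.  The `examples/` directory walks through each
capability, including training the reduced CPU-scale model on synthetic
B-scans and predicting layers for new volumes; the `octlayers` command
exposes the same steps as `simulate`, `train`, `predict`, `drusen`,
`evaluate` and `inspect-arch` subcommands.

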
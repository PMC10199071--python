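# Methods

## Model

### Layer head

The head converts `N` real-valued channel maps of shape `H x W` into `N`
per-column layer heights.  Writing `z_k` for raw channel `k` (channel 0 is
the anatomically topmost layer), the stages are element-wise
non-negativity `a_k = max(z_k, 0)`, channel-axis cumulative sum
`c_k = sum_{j<=k} a_j`, unit clipping `m_k = min(c_k, 1)`, and column sums
`h_k(x) = sum_r m_k(r, x)`.  Non-negativity makes the cumulative stack
pixel-wise non-decreasing in `k`, hence the column sums — the heights — are
non-decreasing in `k`: a later (deeper) layer can never be placed above an
earlier one.  Clipping after the cumulative sum bounds every height by the
image height `H`.  Heights are real-valued (sub-pixel); a height `h` means
the column sum equals `h`, with row 0 at the image top.

All stages are differentiable almost everywhere.  The backward pass uses the
convention that the clip stage passes gradient where the cumulative map is
strictly below 1 and the clamp where the raw value is strictly positive;
saturated units receive zero gradient, exactly as in a ReLU.

The default non-negativity is the hard clamp — the literal reading of the
constraint.  A smooth sigmoid squashing of the raw maps onto (0, 1) is
available via `head_nonnegativity="sigmoid"` for experiments, but is not the
default.  Raw channels are not bounded above before the cumulative sum; only
the post-sum clip is applied.

### Backbone

Three stages at constant spatial size (stride 1, zero-padded "same"
convolutions, no pooling):

* **Initialization block**: three 3x3 convolutions widening 1 -> 16 -> 32 ->
  64 channels, each followed by swish, element dropout (rate 0.1), and batch
  normalization — in that textual order.
* **Refinement block**: residual dilated-convolution blocks
  `DB(filters, d1, d2)`: 1x1 entry convolution, spatial dropout (rate 0.1,
  whole feature maps), three dilated 3x3 convolutions with dilations
  `(d1, d2, d1)`, 1x1 exit convolution; the branch output is added to the
  block input and the sum batch-normalized.  Swish follows the entry and the
  dilated convolutions; the exit 1x1 is linear so the residual branch ends
  linearly before the addition (standard residual practice; the stage order
  inside the branch is otherwise fixed by the block description).
* **Self-attention block**: `sigmoid(U x) * swish(V x)` with `U, V` bias-free
  1x1 convolutions ("linear combinations" of the feature maps), 64 channels
  in and out.

A 1x1 convolution projects the 64 features to the `N` output maps — the
minimal parameterized reduction consistent with the block diagram.

The default full-size stack is

```
DB(40, 3, 9)  DB(40, 6, 18)  DB(40, 9, 27)
DB(36, 12, 36) DB(36, 15, 27) DB(36, 12, 36)
DB(32, 9, 27)  DB(32, 6, 18)  DB(32, 3, 9)
```

i.e. internal widths tapering 40 -> 36 -> 32 with dilations rising and
falling symmetrically from the (3, 9, 3) pattern of the first block.  The
stack is pinned by two analytic self-checks that the test suite asserts
exactly: the theoretical receptive field — starting at 1, each `k x k`
convolution with dilation `d` adds `(k-1)*d`; 1x1 convolutions add nothing —
composes to **721 px**, deliberately overshooting a 512 x 512 input because
the effective receptive field of a trained CNN is smaller than the
calculated one; and the model has exactly **393,923** trainable parameters
at `N = 3` (convolution kernels and biases plus batch-norm scale/shift).
Any edit to the configuration that breaks either number fails the suite.

Ablation presets are expressible in the same config: `no-layer-order`
(cumulative sum removed from the head), `no-attention` (refinement output fed
directly to the projection), `no-shortcuts` (residual additions replaced by
pass-through).  They construct and train but ship without trained weights.

### Numerical core

The network runs on a compact numpy engine written for this package:
channels-last (NHWC) feature maps, dilated convolutions as im2col plus a BLAS
matmul (the input gradient of a dilated convolution is again a dilated
convolution with the spatially flipped, channel-transposed kernel, so forward
and backward share one code path), batch normalization with moving-average
eval statistics (momentum 0.99, eps 1e-3), inverted dropout, and Adam
(beta1 0.9, beta2 0.999, eps 1e-7).  Convolution weights use Glorot-uniform
initialization, seeded; biases start at zero.  Every layer's analytic
gradient is verified against central finite differences in the test suite.
Float32 is the working precision; float64 is available for gradient checks.

## Training

Summed squared error over annotated (layer, A-scan) pairs — a sum, not a
mean, so sparsely annotated B-scans carry proportionally less weight.  The
learning rate is `1e-3 * exp(-0.1 * epoch)`; Adam applies per-tensor gradient
norm clipping at 1 followed by element-wise value clipping at 0.5 (norm
before value, the classic framework order).  Batch size 2, data reshuffled
every epoch.

Augmentation: random horizontal flips (probability 0.5 — image columns and
height columns mirror together), and a vertical repositioning that makes the
retina's vertical position uniformly distributed: the B-scan is shifted so
the row `center_offset_above_bm` pixels above the mean annotated BM height
lands at the image middle, then an integer shift drawn uniformly from
`[-vshift_range, vshift_range]` is added.  Shifts are integer (no
interpolation); vacated rows are zero-filled; heights move rigidly and lose
their annotation when pushed outside `[0, H]`.  The full-size defaults are
75 px and ±180 px; CPU-scale runs on 128-px images use proportionally
smaller values (20 px, ±10 px).

Images are normalized to zero mean and unit variance per B-scan — robust to
inter-scan brightness variation and standard for OCT; a constant image maps
to zeros with a log message.  Model selection keeps the best-validation-SSE
epoch.  Training is deterministic for a fixed seed on CPU: the config seed
drives shuffling and augmentation, the build seed drives weight
initialization and dropout.

## Drusen quantification

Per A-scan, the elevation `e(x) = bm(x) - rpe(x)` removes retinal curvature
and any rigid vertical offset (no polynomial fit is needed after this
rectification; a per-B-scan cubic-baseline variant is retained behind
`legacy_polynomial_fit=True` for comparison only).  The healthy RPE-to-BM
offset `d` is estimated once per volume: histogram all valid elevations
(bin width 1 px by default — annotations are pixel-quantized), find the
modal bin (ties resolve to the smallest elevation, favoring the healthy
baseline), and average the elevations in the modal bin and its two direct
neighbors.  Drusen height is `max(0, e(x) - d)`; voxels span rows
`round(rpe(x)) .. round(bm(x) - d) - 1` (round half away from zero, 0-based
rows).  The en-face projection holds per-position column heights; connected
components of its support (8-connectivity by default, 4 available) whose
maximum height is below 2 px are removed *entirely* — strictly: a component
peaking at 1 px is deleted, one reaching 2 px is kept including its 1-px
fringes.  The filter operates on the raw projection, without smoothing.
Volume is voxel count times axial x lateral x inter-B-scan spacing.

## Synthetic data

The generator emulates what the method needs from real OCT: a smooth BM
curve (tilt + low-frequency sinusoid, vertical jitter), RPE at constant
offset `d = 10 px` above BM with drusen as truncated Gaussian bumps
(amplitudes 4-16 px, lateral sigma 5-14 px, 2D footprints across B-scans in
volumes so en-face components are compact blobs), EZ at `g = 8 px` above the
RPE, and one bright band per layer (Gaussian cross-section, sigma 1.2 px,
intensities 0.8/1.0/0.6 for EZ/RPE/BM) over a dark background with
multiplicative speckle-like noise (sigma 0.1) and additive Gaussian noise
(sigma 0.02).  Band width and noise are calibrated together so that the
per-column intensity argmax of each band lies within 1 px of the true height
for at least 99% of columns — the invariant that makes the learning task
solvable by construction, asserted in the tests.  Defaults use 128 x 128
B-scans for speed; a 496 x 512 preset matches full-size scan geometry.

The true drusen mask is derived with the same voxelization as the
quantification pipeline using the true offset, so discretization is the only
disagreement source when the pipeline runs on exact heights (Dice >= 0.95 at
zero noise).

Not emulated: real speckle statistics, vessel shadows, motion artifacts,
atrophy, fluid, device-specific contrast.  Passing tests demonstrate that
the architecture, loss, and drusen pipeline recover planted structure under
these controlled conditions; they do not certify clinical accuracy on real
scans, which requires device-matched annotated data.

## Scaled-down experiment sizes

CPU-scale checks train the reduced architecture (init 8 -> 16 -> 32, four
DB(16) blocks, receptive field 141 px, ~41k parameters) on 200 synthetic
128 x 128 B-scans for 10 epochs, batch size 2 — enough for held-out MAE well
below 1.5 px on all three layers and drusen Dice >= 0.7 from predicted
layers.  The bootstrap confidence intervals resample volumes with
replacement, 10,000 draws, each 80% of the dataset size, 2.5/97.5
percentiles.

## Evaluation conventions

MAE is computed per volume and layer over annotated A-scans with predictions
rounded to integer pixels first (ground truth is already pixel-quantized);
the alternative — rounding the aggregate instead — is available via
`round_predictions=False`.  Dice of two empty masks is defined as 1
(agreement on absence; drusen-free B-scans are common).  Pearson correlations
of drusen volumes are accompanied by signed per-volume differences to a
reference (e.g. the mean of two readers) and the count of volumes where one
method is strictly closer.

## Known limitations

* The model does not flag regions where layers are absent (optic disc,
  severe atrophy); restrict the analysis domain upstream.
* The healthy offset is a single scalar per volume; eyes with strongly
  varying RPE-BM distance would need a per-region estimate.
* The numpy engine is single-threaded CPU code; full-size 512 x 512 training
  at 35 epochs is out of its intended scope (the configuration can express
  it, but expect long runtimes).
* Proprietary scanner formats are not parsed; convert to the TIFF/JSON/CSV
  interchange layout first.
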
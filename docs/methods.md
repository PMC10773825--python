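# Methods

## Model family

The package builds one four-stage U-shaped segmentation network from a
single configuration (`ModelConfig`) with two orthogonal switches: the
token mixer (`attention` or `pooling`) and SE recalibration (`use_se`).

**Encoder.** A 2×2×2 strided convolution embeds the input into C
channels at half resolution. Four stages follow, each with two
transformer-style blocks (pre-norm, token mixer, residual; pre-norm,
4× GELU MLP, residual) and a patch-merging step (concatenate each
2×2×2 neighborhood to 8d channels, LayerNorm, linear projection to 2d,
no bias). Stage widths are C, 2C, 4C, 8C; merging after stage 4 yields
the 16C bottleneck at 1/32 resolution, so input extents must be
divisible by 32. Each of the five hierarchy outputs passes through a
parameter-free per-token layer normalization before entering the
convolutional path.

**Attention mixer.** Windowed multi-head self-attention with window 7,
alternating plain/shifted blocks (shift = window/2), per-stage heads
(3, 6, 12, 24), biased QKV projection, output projection, and a
learned relative-position-bias table of (2·7−1)³ entries per head.
When an extent is smaller than the window, the window is clipped to the
extent and the shift is dropped on that axis; extents that are not
window multiples are zero-padded, and padded voxels are masked out of
attention on both the query and key side (they receive an off-grid
region label, so they only ever attend to each other).

**Pooling mixer.** The stride-1 average over a centered K×K×K
neighborhood (default K = 3, the smallest centered 3D neighborhood; K
is exposed in the configuration since no specific experimental value is
fixed by the published description). The stated operator is a 2D K×K
sum; since every feature map in this network is 3D and the operator is
a drop-in mixer replacement, it is applied over all three spatial axes.
Borders average in-bounds neighbors only (padded positions are excluded
from numerator and denominator), which makes constant fields exact
fixed points everywhere, including corners. Pooling is applied to the
full feature map without window partitioning: windows exist to localize
attention, and a local kernel is already local. The pooling-lineage
variant that subtracts the identity inside the residual branch
(pool(x) − x) is available behind `subtract_identity`; the default
follows the plain-averaging form of the printed operator.

**Convolutional path.** Residual blocks in the style of dynamic-U-Net
encoders/decoders: two 3³ convolutions (no bias), instance
normalization without affine parameters, leaky ReLU, and a 1³ shortcut
convolution when channel counts change. Encoder blocks sit on the raw
input and on the C, 2C, 4C and 16C hierarchy outputs; the 8C output
feeds the decoder directly. Decoder blocks upsample by a bias-free
2×2×2 transposed convolution, concatenate the skip, and refine with a
residual block. The head is a 1³ convolution with bias.

**SE blocks.** Squeeze (global spatial mean per channel), two biased
fully connected layers with reduction ratio 4 around a ReLU, logistic
gates, channel-wise rescaling. With `use_se` one SE block follows each
of the five encoder convolutional blocks and each of the five decoder
blocks (channels C·{1,1,2,4,16} and C·{8,4,2,1,1}).

## Reconciling the published parameter counts

The published per-configuration totals act as an architecture
checksum, and three families of differences between them pin down
details the prose leaves open. All 28 published totals are reproduced
exactly by the implementation; `architecture_checksum` re-verifies this
at run time.

* **Baseline booleans.** Enumerating {QKV bias, convolution bias,
  transposed-convolution bias, instance-norm affine, patch-embedding
  norm, merge-norm width} against the seven attention-baseline totals
  leaves exactly two consistent assignments; the one adopted (QKV bias
  on, bias-free convolutions and transposed convolutions, affine-free
  instance norm, no patch-embedding norm, LayerNorm over 8d in patch
  merging) matches the reference implementation family this
  architecture descends from, and is the only one also consistent with
  the mixer delta below.
* **Mixer swap.** The attention−pooling difference is 510C² + 90C at
  every size — exactly the parameters of the biased QKV projection
  summed over all 16 blocks, and nothing else. The published pooling
  variant therefore keeps the attention module's output projection
  (d² + d) and its relative-position-bias table (2197 per head) in the
  parameter budget. The implementation follows suit: the network-level
  pooling mixer applies pooling followed by the retained output
  projection, and registers the (functionally inert) position-bias
  table. `pooling_keeps_attention_budget=False` builds the strictly
  parameter-free mixer instead; the block-level default
  (`MetaSwinBlock`) is the parameter-free form.
* **SE placement.** The +SE delta is 182C² + 50C. Over channel
  multisets drawn from {1, 2, 4, 8, 16}·C there is a unique solution:
  reduction ratio 4, biased FC layers, and ten SE blocks at channels
  C·{1,1,1,1,2,2,4,4,8,16} — precisely the out-channels of the five
  encoder convolutional blocks and five decoder blocks. The deltas'
  independence from the input/output channel layout confirms there is
  no SE on the raw-input projection or the output head.
* **Channel layout.** The 4,645 difference between the 4-in/3-out and
  1-in/14-out configurations at C=48 decomposes as patch embedding
  (3·48·8) + first encoder block (27·3·48 + 3·48) − head (11·49),
  confirming the decoder/head decomposition above.

## Heads, loss and metrics

The MRI-regime head emits 3 sigmoid channels for the overlapping
regions WT = {1,2,4}, TC = {1,4}, ET = {4}, thresholded at 0.5 and
re-nested at decode time; the CT-regime head emits softmax channels for
all classes including background, decoded by argmax. The loss is the
soft Dice complement averaged over classes and batch, with a smoothing
constant (default 1e-5, added to numerator and denominator) guarding
the empty/empty case; `smooth=0` evaluates the bare formula. A
Dice-plus-cross-entropy variant is available behind `loss="dice_ce"`
but is not the default. The hard Dice score defines empty-vs-empty as
1.0 (configurable): an absent structure correctly predicted absent.
Metric aggregation over cross-validation reports per-class means over
folds, per-fold means over classes, and the grand average as the mean
of per-class averages; for the CT regime the background class is
excluded from reported means.

## Synthetic phantoms

The generator exists to exercise every pipeline stage with
controllable class structure — it models no imaging physics (no bias
fields, no anatomy, no partial-volume effects), so passing tests
demonstrate mechanical and statistical correctness of the pipeline,
not clinical performance. `brain4ch` places a brain-like foreground
ellipsoid and a nested lesion (edema shell label 2 ⊃ core shell label
1 ⊃ enhancing center label 4, radius ratios 1 : 0.65 : 0.38 of a
randomized whole-lesion radius at 14–20 % of the extent), with four
channels of distinct per-tissue mean contrast (unit scale) plus
Gaussian noise (default sd 0.05). `abdomen1ch` places up to 13
pairwise-disjoint organ blobs with evenly spread mean intensities on a
single channel. Everything is a deterministic function of the seed;
dataset generation spawns per-subject seeds from the master seed.

Desk-scale defaults used by the test suite: 32³ or 64³ extents
(32³ is the smallest volume the architecture accepts), one lesion,
10-subject datasets. These are the package's own choices for
exercising the method at laptop scale.

## Training

Defaults mirror the published recipe where stated — soft Dice loss,
batch size 1, base learning rate 1e-4, 128³ patches with C=48 for the
MRI regime and 96³ with C ∈ {24…84} for the CT regime — and
documented extrapolations elsewhere: AdamW with cosine decay (the
optimizer and schedule are not specified in the source description;
plain Adam and SGD are selectable), random-crop as the only
augmentation, z-scoring over nonzero voxels per channel for MRI and
window-clip-and-scale for CT. Epoch-count defaults (800 / 2,000) are
configuration values only; tests use step-bounded runs.

The learnability smoke check (a C=12 pooling network overfitting one
32³ phantom for 200 steps) uses constant-rate Adam at 5e-3: with the
soft Dice objective alone, the largest region channel initially keeps
a diffuse false-positive mass whose per-voxel gradient scales inversely
with the Dice denominator, and the conservative full-scale recipe does
not clear that plateau within 200 steps. Constant-rate Adam at 5e-3
does, consistently across phantom and initialization seeds (final loss
≈ 0.002).

Sliding-window inference tiles the volume with the training ROI at
overlap 0.5 (mean logit blending, a standard default); a window equal
to the volume reduces exactly to a direct forward pass.

## Numerical and implementation choices

* Networks run in float32; pooling is accumulated in float64 (separable
  box sums) and the Dice/metric arithmetic is float64.
* Weight initialization: truncated normal (sd 0.02, 2-sd resampling)
  for linear layers and bias tables, fan-out He for convolutions,
  zeros for biases, ones/zeros for norms. Parameter counts and shapes
  are seed-independent; values are reproducible per seed.
* Instance norm over a 1³ spatial field (the bottleneck at 32³ input)
  normalizes to zero; the residual shortcut keeps such blocks
  well-defined (full-scale 96³/128³ inputs do not hit this case).
* Attention masks use additive −10⁴ logits; softmax subtracts the row
  maximum before exponentiation.
* Patch merging pads odd extents with zeros before concatenating
  neighborhoods; patch embedding requires even extents outright, since
  the network contract already demands divisibility by 32.
* Checkpoints are single-file `.npz` archives embedding the full
  configuration as JSON next to every parameter array.

## Known limitations

* CPU-bound numpy execution: full-scale (128³, C=48) training is out
  of reach; the package targets architecture analysis and desk-scale
  experiments.
* The BTCV-style "96×96 input resolution" is read as a 3D 96³ region
  of interest, since the network is 3D and requires extents divisible
  by 32; 2D slice-based training is not implemented.
* Label conventions are configurable but default to the classic
  {1, 2, 4} tumor labels; datasets using renumbered enhancing-tumor
  labels need a remapped label set.
* No DICOM ingestion, resampling, registration, or augmentation beyond
  random cropping.
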
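# Methods

## The model

MSA-MaxNet is a U-shaped encoder–decoder for 2D medical-image
segmentation whose mixing operation is multi-axis self-attention
(Max-SA). Max-SA decomposes full self-attention into two sparse,
complementary forms applied in sequence:

- **Block attention** partitions the (H, W, C) feature map into
  non-overlapping P×P tiles and attends within each tile — local
  interactions at full resolution.
- **Grid attention** splits each spatial axis into G strided cosets, so
  the g-th group holds the tokens at positions `(a·H/G + r, b·W/G + s)`
  for fixed intra-cell offset (r, s) — a dilated lattice giving global
  interactions.

Both use softmax attention with a learned additive relative-position
bias B (one table entry per 2D offset, `(2P−1)²` entries per head) and
are wrapped in the standard pre-norm transformer layer:

    x ← x + Merge(RelAttention(Partition(LN(x))));   x ← x + MLP(LN(x))
    RelAttention(Q,K,V) = softmax(QKᵀ/√d + B) V

Because attention is always confined to groups of P² (or G²) tokens,
the largest attention matrix is P²×P² regardless of image size, so cost
grows linearly with area while the block/grid pair still spans the whole
image.

Convolutional components:

- **Stem**: 3×3 stride-2 convolution to 64 channels (+BN, GELU) then a
  3×3 stride-1 convolution — the convolutional equivalent of 2×2
  patchification.
- **MBConv**: pre-BatchNorm, 1×1 expansion to `4·out_dim` (+BN, GELU),
  3×3 depthwise (+BN, GELU), squeeze–excitation (bottleneck = a quarter
  of the expanded width), 1×1 projection, residual. The stride-2 variant
  downsamples in the depthwise convolution and uses an
  average-pool + 1×1-projection shortcut.
- **CBAM**: channel gate σ(MLP(avg-pool) + MLP(max-pool)) with a shared
  reduction-r MLP, then spatial gate σ(conv7×7[channel-avg; channel-max]).
- **MCBAM** (multi-scale CBAM) refines each skip connection from three
  adjacent encoder scales: the channel gate for the current features F0
  (C0 channels) comes from the deeper stage F2 (2·C0 channels, half
  resolution) through a shared 1×1 convolution on its avg/max pooled
  descriptors; the spatial gate comes from the shallower stage F1
  (double resolution) through a stride-2 7×7 convolution to one channel,
  BatchNorm and sigmoid. Output: `F0'' = Ms(F1) ⊗ (Mc(F2) ⊗ F0)`.

Topology: four encoder stages of (MBConv → MaxViT block) repeated
(2, 2, 5, 2) times at widths (64, 128, 256, 512); CBAM on the deepest
(H/32, 8C) features; three decoder stages of patch expansion (2× up,
half channels, realized as a linear expansion to 2C followed by
depth-to-space), concat+1×1 fusion with the MCBAM-refined skip, and
MaxViT blocks; a final 4× patch expansion and a 1×1 classification head
emit per-pixel logits at input resolution.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| img_size | 224 px | all stage extents (56, 28, 14, 7) divide P = G = 7 |
| P, G | 7 | MaxViT convention; divisibility of the 224 chain |
| head_dim | 32 | standard multi-head practice |
| mlp_ratio | 4 | transformer convention |
| MBConv expansion | 4 × out_dim | MaxViT-lineage inverted bottleneck |
| SE ratio | 0.25 of expanded width | MaxViT lineage |
| CBAM reduction r | 16 | CBAM convention |
| spatial kernels | 7×7 | CBAM convention; reused for MCBAM's shallow branch |
| decoder depths | (2, 2, 2) | see design choices |
| stem width C | 64 | stage widths 64…512, 8C = 512 |
| optimizer | AdamW, lr 2e-4, wd 1e-4, batch 8 | the training recipe of the benchmark setting |
| loss | 0.5·CE + 0.5·soft-Dice (all classes) | de-facto standard for these benchmarks |

The base configuration has 40.83 M trainable parameters (reported by
`count_parameters` and the acceptance script).

## Design choices where the design was open

- **Stage-1 widths.** The stem emits 64 channels at H/2 and stage 1's
  stride-2 MBConv maps 64→64; doubling starts between stages. The
  alternative (stage 1 → 128) yields 8C = 1024 and roughly doubles the
  parameter count, far from the ~40 M budget this configuration is
  designed around.
- **Decoder depth.** "Symmetric" is read as symmetric in block type and
  stage structure, not per-stage repeats: a 5-deep decoder stage would
  far exceed the intended model size. Each decoder stage runs 2 MaxViT
  blocks.
- **Expansion base in MBConv.** The hidden width is `expansion ×
  out_dim` (not in_dim), so the stride-2 block at a stage boundary
  expands to 4·out_dim. This is the MaxViT-lineage convention and is
  the reading consistent with the ~40 M parameter scale.
- **Skip fusion** is channel concatenation + 1×1 projection
  (element-wise addition is available via `skip_fusion="add"`).
- **MCBAM pooled descriptors** share one 1×1 convolution (mirroring
  CBAM's shared MLP); separate convolutions are available via a flag.
- **Stage 1's shallow features.** MCBAM at the first stage needs a
  preceding block; the stem output is the only candidate and is used.
- **Fusion order.** Decoder MaxViT blocks run *after* skip fusion, so
  skip features influence the stage's attention.
- **No padding.** Feature extents must divide P and G; non-divisible
  inputs raise an error instead of being padded, which keeps
  Unblock/Ungrid exact inverses and all tests deterministic.
- **Ablation flags.** `skip_mode` ∈ {mcbam, cbam, none} and
  `downsample_mode` ∈ {mbconv, plain_conv} reproduce the variant
  topologies (full model, CBAM-only skips, unrefined skips, and
  plain-convolution downsampling) purely by configuration.

## Numerical choices

- The package runs on a small reverse-mode autodiff engine over numpy
  (`msa_maxnet.nn`): exact erf-based GELU, im2col convolutions,
  float32 parameters. Gradients are verified against central finite
  differences in the test suite.
- Initialization: truncated normal (σ = 0.02) for attention/linear
  weights, He-scaled truncated normal for convolutions, zeros for
  biases and relative-bias tables. Zero bias tables make attention
  unbiased at initialization; zeroed gate weights make every sigmoid
  gate exactly 0.5, which several tests exploit.
- BatchNorm uses standard running statistics (momentum 0.1); tests that
  need exact determinism run in inference mode. LayerNorm ε = 1e-6,
  BatchNorm ε = 1e-5, soft-Dice ε = 1e-6.
- Softmax and log-softmax are computed with max-shifting; sigmoids use
  `scipy.special.expit`, so saturated gates cannot overflow.
- HD95: boundaries are mask pixels with a 4-neighbour outside the mask;
  directed boundary distances are taken from a Euclidean distance
  transform, pooled over both directions, and the 95th percentile uses
  linear interpolation. When either mask is empty the value is NaN by
  default (or the grid diagonal via `empty="diagonal"`); both-empty
  overlap metrics return 1. Pixel spacing defaults to 1.0.
- Dropout / stochastic depth are 0 (not part of the recipe).

## Synthetic data: what it does and does not emulate

`synthetic_data.FixtureSpec` draws, per sample, `n_shapes` random
ellipses (random centre, radii 6–22 % of the image side, orientation),
each assigned a random foreground class; later shapes overwrite earlier
ones (partial occlusion). The intensity image gives each class a fixed
base level (background 0.08, organs evenly spaced 0.35–0.9), adds
Gaussian noise (σ = 0.05 by default — mild relative to the ~0.27
inter-class separation), clips to [0, 1] and replicates to 3 channels.
Everything is a pure function of (seed, index).

This captures the pieces the pipeline must handle — multi-class label
maps, class-correlated intensity, noise, occlusion, augmentation-safe
geometry — but not the hard parts of real CT/MRI: textured organs,
low-contrast boundaries, anatomical shape priors, inter-slice context,
scanner artefacts. Passing the desk-scale learnability test shows the
architecture, gradients, loss and training loop work end to end; it
says nothing about clinical segmentation accuracy.

## Desk-scale problem sizes

The reduced configuration used throughout the tests is 64 px inputs,
widths 16–128, P = G = 2, encoder depths (1,1,1,1) (≈1.1 M parameters).
The learnability check trains this model on 16 fixtures with full-batch
AdamW (batch 16, lr 5e-3, β = (0.9, 0.95), 300 steps, no augmentation —
a memorization protocol, evaluated on the clean training images) and
requires macro-DSC ≥ 0.95 on the training set. Two protocol notes:

- β₂ = 0.95 rather than the 0.999 default: with only 300 full-batch
  steps, the slow default second-moment average is still dominated by
  the large early gradients and throttles late-stage progress on
  boundary pixels; a faster decay is the standard adjustment for short
  deterministic runs. (At benchmark scale, with tens of thousands of
  stochastic steps, the default is kept.)
- The training-set macro DSC is computed at the dataset level (per
  class over all pooled training pixels, then averaged over foreground
  classes). A per-image average is also reported by ``evaluate_model``
  but is dominated by a pathology of small fixtures: a class absent
  from an image scores 0 for that image if the model emits even one
  stray pixel of it, which measures the absent-class convention more
  than segmentation quality. Real benchmarks face the same issue and
  pool per case; remaining errors here sit within one pixel of the
  class boundaries.

The full-size model is built for parameter counting and a single
224 px forward pass.

## Known limitations

- Single CPU device, float32, no mixed precision or distributed
  training; throughput is far below a GPU framework's.
- 2D slices only; volumetric attention and anisotropic surface
  distances are out of scope (HD95 accepts a spacing scalar for future
  use).
- The published Small/Tiny variants have no public configuration; width
  and depth knobs exist but no claim of equivalence is made.
- Benchmark-scale results (multi-organ CT, cardiac MRI, polyp
  segmentation) require the corresponding datasets and GPU-scale
  training and are deliberately not reproduced here.
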
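# Methods

## Problem setting

The package segments a small, low-contrast organ (the motivating case is
the pancreas in contrast-enhanced abdominal CT) from 3D grayscale volumes.
The target structure typically occupies well under 2% of the volume, has
high anatomical variability, and blends into surrounding tissue, so both
a plain 2D slice-wise segmenter and a global intensity rule fail: the
former lacks through-plane context, the latter cannot distinguish the
organ from equally bright structures.

## Model

### 2.5D input

A volume is cut into ordered slices along each of the three anatomical
planes (sagittal = fixed width index, coronal = fixed height index,
axial = fixed depth index).  The network input for slice *i* is the
3-channel image `(S_{i-1}, S_i, S_{i+1})`; at either end of the stack the
boundary slice is replicated three times (no zero padding).  This gives a
2D network limited through-plane context at a fraction of a full 3D
model's cost.

### Encoder-decoder with dense blocks

The segmentation network is a U-shaped encoder-decoder.  Both paths are
built from *dense blocks*: 6 convolution layers (3×3, stride 1,
shape-preserving padding, ReLU) where each layer receives the
concatenation of the block input and all previous layer outputs, followed
by a 1×1 transition convolution to the block's output width.  Six stacked
3×3 layers give each block a receptive field of at least 13×13; the dense
skips counteract vanishing gradients.  Channel width starts at
`base_channels` and doubles per level; spatial resolution halves between
encoder blocks (2×2 max pooling) and doubles between decoder blocks
(factor-2 bilinear upsampling, half-pixel-centre convention).

The encoder has `n_blocks` blocks; the deepest block doubles as the
bottleneck, and the decoder mirrors the remaining `n_blocks − 1` levels
before a 1×1 convolution + sigmoid head emits the centre-slice foreground
probability map.  (A separate bottleneck block and a full-length decoder
were the main open layout choices; the shared-bottleneck U is the
smallest architecture consistent with symmetric 4-block paths.)

### 3D section

The first `n3d_blocks` encoder blocks treat the 3-channel input as a
depth-3, single-channel volumetric tensor and convolve with 3×3×3 kernels
(depth-preserving padding); pooling inside this section is spatial-only.
After each 3D block the depth is folded into channels (reshape) and a 1×1
convolution projects the 3·c folded channels to the level's nominal 2D
width.  This folding rule keeps every skip connection a plain 2D feature
map whose width exactly doubles per level, which the attention module's
shape contract requires.  The mechanism of depth folding was an open
design point; reshape + 1×1 projection is the cheapest choice that
preserves all depth information.

### Hybrid attention on skips

Each skip connection at level *k* is gated by a hybrid attention module
with inputs X (the level-k encoder feature, `w×h×c`) and Y (the level-k+1
encoder feature, `w/2×h/2×2c`):

- **Spatial branch** `SA = X · σ(conv(f(X, Y)))`: Y is upsampled ×2,
  matched to c channels by a 1×1 convolution and fused with X by
  addition; two 1×1 convolutions (c → c/2 with ReLU, c/2 → 1) and a
  sigmoid produce a single-channel weight map that multiplies X
  (broadcast over channels).
- **Channel branch**: X and upsampled Y are concatenated (3c channels);
  global average pooling `gap_c = (1/wh) Σ I_c(i,j)` and global max
  pooling `gmp_c = max I_c` each feed one shared 1×1 convolution
  (3c → c); the two outputs are summed and squashed by a sigmoid into
  per-channel weights that scale X.
- The two gated maps are **summed** (keeping skip widths unchanged;
  concatenation was the alternative).

With all attention weights at zero each branch reduces to `0.5·X`
(σ(0) = 0.5) and their sum restores X — this analytic identity is used as
a correctness check.  `attention="none"` bypasses the gates entirely (the
plain 2.5D U-net ablation arm).

### Normalisation

Each convolution is followed by instance normalisation by default
(configurable to none).  The reference training regime uses batch size 1,
under which batch statistics are degenerate; instance norm is the
batch-size-independent substitute.

## Loss and metrics

Training minimises the soft Dice loss
`L = 1 − (2 Σ y ŷ + ε) / (Σ y + Σ ŷ + ε)` with ε = 1e−6 on numerator and
denominator (the additive smoothing avoids 0/0 on empty targets and
stabilises gradients; the plain definition has none).  Evaluation uses
the Dice similarity coefficient `DSC = 2|A∩B| / (|A|+|B|)` on
reconstructed 3D masks; the both-empty case is defined as DSC = 1.
Per-case summaries report mean, population standard deviation
(configurable to sample), max and min.  The DSC-distribution histogram
uses the bins [0, 0.5] (closed) then (0.5, 0.6], …, (0.9, 1]
(half-open-left).

## Coarse-to-fine cascade

Two sets of three per-view models are trained (coarse and fine stage).
Per volume: each coarse model predicts its view's probability volume;
per-view maps are binarised at 0.5 and fused by per-voxel majority vote
(mean of the three votes ≥ 0.5, i.e. ≥ 2 of 3 views — the threshold
implementing "majority" on the three-view average).  A bounding box around
the fused mask, expanded by a safety `margin` filled with original image
intensities, defines a crop on which the three fine models predict and
are fused the same way; the fine mask is stitched back at the full shape.

Localisation uses the **largest 6-connected component** of the fused
coarse mask by default ("foreground" mode uses every voxel).  The organ
is a single connected structure; without this rule a handful of scattered
false-positive specks — exactly the failure mode the coarse stage
exhibits on hard volumes — expands the crop to nearly the whole volume
and pushes the fine stage far outside its training distribution.  The
fused coarse mask itself is never altered; the rule only selects the
crop.  An empty coarse mask triggers a whole-volume fine stage with a
logged warning.

One fused box serves all three fine views (per-view boxes were the
alternative).  Fine-stage training crops derive from the ground-truth box
plus the same margin (standard cascade practice; predicted-box training
is available via the coarse models).

## Preprocessing

CT intensities are clipped to the window [−100, 240] HU and mapped
affinely to [0, 255] (kept floating point; 127.5 is representable).
Slices are resized to the network input size — bilinear with
anti-aliasing for images, nearest-neighbour for masks (which therefore
stay binary).  Probability maps are resized back to the native in-plane
resolution bilinearly *before* thresholding.  Coordinates are 0-based
with half-open intervals, array order (width, height, depth), depth being
the axial stacking direction.

## Training regime

Defaults follow the reference recipe: 30 epochs of Adam at learning rate
1e−5, batch size 1, 10% of training *slices* held out for validation
(case-level splitting is available for leakage-averse use), final-epoch
weights kept (no model selection), no augmentation or schedule.
Coarse-stage training uses only slices with more than
`min_pancreas_pixels` (default 100) foreground pixels; the fine stage
keeps every cropped slice containing any foreground.  K-fold
cross-validation (default 4 folds) assigns cases by a seeded permutation
split into near-equal test sets; every case is tested exactly once.

All randomness — phantom generation, weight initialisation, slice
shuffling, fold assignment — flows from a single configured seed; runs
are bit-reproducible.

## Numerical engine

No deep-learning framework is used: the network, its gradients and Adam
run on a compact reverse-mode autodiff engine over numpy arrays.
Convolutions are evaluated by shift-and-matmul (one channel matmul per
kernel offset); the input gradient is a full correlation with the flipped
kernel, the weight gradient a per-offset tensordot.  Max-pool gradients
follow the argmax (first index on ties); the global-max pool shares
gradient equally among ties.  Bilinear ×2 upsampling uses half-pixel
centres with edge clamping; its adjoint is a strided 4-tap correlation.
Instance norm has a fused analytic backward.  Parameters are float32
(He-initialised, zero biases); every op's gradient is verified against
central finite differences in float64 in the test suite.

## Phantom generator

The generator produces the statistical situation the method assumes, on a
64×64×48 grid by default: a smoothly inhomogeneous background (±25 around
level 80), one organ — a randomly posed ellipsoid whose radius is
modulated by low-frequency sinusoids (irregular shape, case-to-case
variation), capped at 2% volume fraction, with its contrast (default +60)
Gaussian-blurred at the boundary (σ = 1 voxel) — plus 10 distractor blobs
whose intensities straddle the organ's (amplitude ~N(1.0, 0.2)×contrast),
placed off the organ, and additive Gaussian noise (σ = 5).  The mask is
the pre-blur organ voxel set, a single 6-connected component.
Intensities live on the post-preprocessing [0, 255] scale; an optional
HU-scale mode exercises the windowing step.

Because distractor and organ intensities overlap and the background
drifts, the best *global threshold* reaches only ~0.3 mean DSC on default
phantoms — the task is solvable only with spatial context, which is what
the network is supposed to supply.  What the phantoms do **not** emulate:
anatomical shape priors, inter-organ adjacency, CT physics (beam
hardening, reconstruction kernels), or the 512×512 native resolution.
Passing the phantom study therefore shows the pipeline learns
shape/context-based segmentation end-to-end at small scale; it does not
certify clinical-grade accuracy on real CT.

## Miniature study scale

The end-to-end study (test suite and `scripts/acceptance.py`) runs at
desk scale, chosen once: 12 training / 4 held-out phantoms of 64×64×48;
model with 3 levels, base width 6, 2-layer dense blocks, one 3D block;
6 epochs of Adam at lr 1e−3, batch 1; crop margin 8; coarse slice filter
25 pixels.  Two parameters are deliberately rescaled from the reference
values along with the problem size: the learning rate (1e−5 is matched to
~30 epochs over thousands of 224×224 slices and cannot move a fresh
network within a few hundred phantom-scale steps) and the coarse slice
filter (100 pixels of a 512×512 slice is a far smaller slice fraction
than of a 64×64 slice; 25 keeps partial-organ slices in training).  The
reference defaults themselves are unchanged.

## Known limitations

- Slice-level validation splitting lets neighbouring slices of one case
  appear in both train and validation; use the case-level option when
  that matters.
- The dense-block channel widths of the original architecture are not
  published; parameter counts are therefore reproducible only in ordering
  (hybrid attention adds parameters over the plain model), not in value.
- The engine is CPU-only and single-threaded by design of its BLAS calls;
  it is sized for the miniature study, not for 512×512×400 clinical
  volumes.
- The cascade runs the fine stage exactly once; no test-time augmentation.
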
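# Methods

This note documents the modelling and numerical choices behind `tunet`, in
the spirit of a model-description appendix: what is computed, under which
assumptions, which knobs matter, and what the synthetic experiments do and
do not demonstrate.

## Architecture

**Encoder.** Five stages at channel widths (64, 128, 256, 512, 1024), each a
residual block of two 3×3 convolutions with batch normalization and ReLU,
with 2×2 max pooling between stages.  Skip features are taken at strides
1, 2, 4 and 8; the bottleneck sits at stride 16.  We deliberately use a
compact residual stage stack rather than a full ResNet-50: the channel
contract (64→1024) is the architecturally binding property, the encoder
depth is not, and the compact form keeps CPU-scale experiments tractable.
The encoder is never pretrained.

**Transformer branch.** The bottleneck is tokenized so that each token
corresponds to one 16×16 input-image patch — i.e. one spatial position of
the stride-16 bottleneck — giving N = H·W/256 tokens (400 for 320×320
input).  Tokens are linearly projected to width D with learned position
embeddings added, then passed through L pre-norm blocks (multi-head
self-attention + GELU MLP, both with residual connections and layer
normalization) and a final layer norm.  Defaults are ViT-Base-like
(D = 768, 12 heads, MLP 3072, L = 12) and fully configurable; tests and
desk-scale runs use much smaller values.  Position embeddings are stored on
a reference token grid (`image_size`/16 per side, default 20×20) and
bilinearly resized to the actual grid, so one parameter set serves any input
size divisible by 16 — the standard ViT practice for variable resolution.

**Convolutional branch.** Four 3×3 dilated convolutions with rates
(1, 3, 5, 7) arranged as a cascade: each stage consumes the previous stage's
output, and all four stage outputs are concatenated and reduced by a 1×1
convolution (a DenseASPP-like reading of "cascade"; a classic parallel-ASPP
arrangement is available via `atrous_mode="parallel"`).  The result feeds
pyramid pooling over receptive fields (2, 4, 8, 16): average-pool with
kernel = stride = field, 1×1 convolution to C/4 channels, bilinear upsample
to the input size, concatenate with the input, reduce by 1×1 convolution.
Average pooling uses ceil mode with partial edge windows averaged over valid
pixels only, because the full-scale fields (8, 16) do not divide the 20×20
bottleneck of a 320×320 input.

**Fusion and decoder.** The token grid is projected to the bottleneck
channel width by 1×1 convolution, concatenated with the convolutional-branch
output and reduced by 1×1 convolution (`fusion="add"` is the lighter
alternative).  The fused bottleneck — not the pyramid output alone — feeds
the decoder; this is an interpretation of the "parallel" framing, chosen so
both branches remain live paths into the decoder.  The decoder repeats
(bilinear upsample ×2, concatenate the matching skip, two 3×3
conv-BN-ReLU), then a 1×1 convolution emits one logit per pixel; a sigmoid
maps logits to foreground probabilities.  Binary segmentation is therefore
single-channel; the two-class cross-entropy formulation maps onto
(p, 1−p).

**Ablation variants.** `no_attention` removes the whole bottleneck
attention (plain U-Net-style encoder–decoder); `no_transformer` keeps only
the atrous+pyramid branch ("AU-Net"); `transformer_only_bottleneck` keeps
only the transformer branch ("T-Net"); `patch_input_transformer` drops the
encoder/decoder entirely and runs the transformer on raw 16×16 image
patches with a per-token linear decoder to P² pixel logits.  Single-branch
variants use identity fusion, so removing a branch removes exactly that
branch's parameters.

## Losses

* **Soft Dice**: (2Σpg + s)/(Σp + Σg + s) per image, batch-averaged;
  smooth s = 1e-6 defines the both-empty case as perfect.  With binary
  inputs this equals the set-based Dice exactly.
* **TopK**: per-pixel two-class cross-entropy, the ⌈k%·N⌉ highest-loss
  pixels of each image selected on detached values, averaged.  Default
  k = 10%.  Normalization is by the selected count |K| so that k = 100%
  reduces exactly to mean cross-entropy (standard OHEM practice); a
  `literal_n_norm` flag divides by N instead, which rescales the loss by
  the constant |K|/N without changing gradient directions.  Selection is
  per image, then batch-averaged, matching per-image metric reporting.
* **Cross-entropy / Focal** complete the loss-ablation grid; focal
  multiplies each pixel's CE by (1 − p_true)^γ (γ default 2) and is
  differentiated through the modulating factor.
* **Joint loss**: weighted sum of the configured components; default
  Dice + TopK with unit weights.  The per-component breakdown reconstructs
  the total exactly and is logged per iteration.

Probabilities are clamped to [1e-7, 1−1e-7] before logarithms; gradients
are zero outside the clamp, which only triggers at saturation.

## Metrics

Dice, precision and recall come from the pixel confusion counts of the
binarized prediction (threshold 0.5, strict inequality).  Surface metrics
use boundary point sets: foreground pixels with at least one 4-connected
background neighbour, the image border counting as background, at
pixel-centre coordinates scaled by the pixel spacing (default 1 mm/px; real
datasets must supply their own).  HD is the exact symmetric Hausdorff
distance — no 95th-percentile variant — and ASD divides the summed
bidirectional nearest-surface distances by |S(A)| + |S(B)|.  Nearest
neighbours are computed with a k-d tree; the test suite checks exact
agreement with an exhaustive O(|A||B|) pairwise-distance oracle.

Degenerate masks are explicit: both-empty pairs score Dice = precision =
recall = 1 with distances undefined; one-empty pairs score Dice 0 with
distances undefined.  Aggregation averages distances over non-degenerate
records only and reports the exclusion counts, so "failed detections" are
visible rather than silently absorbed.

## Synthetic phantoms

The generator emulates the statistical structure of ultrasound frames, not
their physics: a star-convex target (lumpy disc "blob", or annulus "ring"
with 18–35 % relative wall thickness) of characteristic diameter drawn from
`size_range` (default 10–35 % of the image diagonal), foreground/background
contrast 0.45, Gaussian boundary blur (σ default 1.5 px), then
multiplicative speckle `pixel × (1 + strength·η)` with η standard normal
(strength default 0.35; a unit-mean Rayleigh field is available as
`speckle_model="rayleigh"`), clipped to [0,1] and quantized to 8 bits so
PNG round-trips are bit-exact.  A configurable fraction of frames has an
all-zero mask, mimicking frames where the target is absent.  Every sample
is a pure function of (spec, seed, index) via seed sequences.

Augmentation is offline ×5 — original, horizontal flip, vertical flip, one
random rescale (factor in [0.8, 1.25], canvas fixed by centre crop/pad) and
one random rotation (±15°, reflection padding for the image, zero padding
for the mask) — because the published pool sizes (1,710 → 8,550;
718 → 3,590) imply exactly one derived sample per transform.  Masks are
resampled with nearest neighbour and stay strictly binary.  `crop_resize`
centre-crops to square aspect and resizes (bilinear image / nearest mask),
rescaling the spacing so mm-scale metrics remain comparable.

What passing tests on phantoms do *not* show: robustness to real speckle
statistics (which are neither Gaussian nor stationary), shadowing and
attenuation artefacts, annotation noise, or anatomical shape priors.  The
phantoms establish that the architecture, losses, metrics and harness are
correct and that the network can learn; they say nothing about clinical
performance.

## Training and comparison harness

SGD with momentum 0.9 and weight decay 1e-4, initial lr 0.01, batch size
10, lr multiplied by `lr_decay_factor` (default 0.1 — the schedule's step
size every 100 epochs is stated in the reference recipe, its factor is not)
at every `lr_step_epochs`.  No validation split or early stopping by
default (fixed-epoch training); divergence to a non-finite loss aborts with
a diagnostic.  All randomness — initialization, shuffling, phantom
generation — fans out from one root seed through seed sequences, making
runs bit-reproducible on one device.

The Friedman test ranks algorithms within each image (average ranks on
ties, rank M = best, so higher mean rank = better), applies the standard
tie correction to the chi-square statistic, and uses M − 1 degrees of
freedom.  The implementation is cross-checked in the tests against scipy's
independent `friedmanchisquare` on random tables with and without ties.

## Numerical engine and problem sizes

The network runs on a small reverse-mode autodiff engine over numpy
(float32 for training, float64 for gradient checks): im2col convolutions
with dilation, ceil-mode average pooling, max pooling, bilinear resampling
with exact adjoints, and fused-free composites for softmax/layernorm.
Every primitive is verified against central finite differences.

Desk-scale experiments use a reduced configuration (stage widths 8–128,
D = 64, L = 2, heads 4, pyramid fields (1, 2, 2, 4) to fit the 4×4
bottleneck of 64×64 inputs).  The test suite and the acceptance script run
this configuration on 64×64 phantoms: 8 images / 200 iterations for the
overfitting check, 16 train + 8 test images / 150 iterations for the
generalization check, and 40-iteration runs for the ablation comparison —
sizes chosen so a single CPU core completes the whole suite in minutes
while still exercising every code path at realistic depth.

## Known limitations

* The full-size configuration (~166 M parameters) is buildable and
  structurally tested, but training it requires GPU-scale compute.
* Only binary segmentation, 2-D, single-channel input.
* No pretrained encoder weights; no dropout (the reference recipe does not
  specify regularization beyond weight decay).
* The exact fusion operator of the two bottleneck branches and several
  transformer hyperparameters (D, heads, MLP width) are not pinned down by
  the reference description; the defaults here are explicit, documented
  choices (`fusion`, `embed_dim`, … in `ModelConfig`), not claims about the
  original training setup.
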
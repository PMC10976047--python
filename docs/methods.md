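# Methods

## Problem setting

Binary lesion segmentation on brain MRI is heavily imbalanced: lesions
(e.g. white matter hyperintensities on FLAIR) typically occupy 0.1–2% of
brain voxels. Training a voxel classifier with a plain mean-reduced loss
lets the background class dominate the optimisation. The standard remedies
are loss functions that reweight the classes — explicitly (focal loss,
class-weighted cross-entropy) or implicitly (Dice-family overlap losses).
This package implements seven such losses under one interface, trains the
same 3D U-net under each of them with shared random state, and evaluates
how each loss shapes Dice (DSC), sensitivity (TPf) and precision over
training epochs, at patch scope and at reconstructed-image scope.

## Losses

With target `y_i ∈ {0,1}`, probability `p_i = sigmoid(f_i)` and `N` voxels,
all scalar losses use mean-over-voxels reduction:

* `xent` — binary cross-entropy.
* `focal1` / `focal2` — focal loss `−α(1−p)^γ log p` (foreground) /
  `−(1−α)p^γ log(1−p)` (background), with γ=2 and α=0.25 / α=0.75.
* `gdsc` — generalised Dice loss with inverse-squared-volume class weights
  `w_fg = 1/N_fg²`, `w_bg = 1/N_bg²`, recomputed per batch.
* `dsc` — binary Dice loss `1 − (2Σp·y + ε)/(Σ(p+y) + ε)`.
* `mixed` — binary Dice + cross-entropy with equal (unit) weights.
* `new` — the gradient-defined weighted loss, below.

### The gradient-defined loss

Instead of weighting the loss value, the class weight α and modulating
exponent γ are applied directly to the gradient of sigmoid+cross-entropy
with respect to the logits:

    ∂L/∂f_i = −α (1−p_i)^γ / N      on foreground voxels,
    ∂L/∂f_i = +(1−α) p_i^γ / N      on background voxels,

with γ=2 and α = N_bg/N computed per training batch. This expression has no
closed-form antiderivative, so the loss exists only through a
custom-backward contract: the training engine must use the closed form
verbatim, and the "forward value" reported in logs is a monitoring quantity
(the α-weighted cross-entropy). Design choices the defining expression
leaves open, resolved here:

* **Sign.** Both branches are emitted with the sign that makes the update
  direction agree with the sigmoid+cross-entropy gradient `(p−y)/N`
  (negative on foreground). With γ=1, α=0.5 the expression then reduces
  exactly to half of that gradient, which is the reduction the construction
  intends; the opposite sign would ascend the error.
* **Scaling.** The gradient is divided by N so that its magnitude is
  commensurate with the mean-reduced value losses.
* **α per batch.** The batch is the optimisation unit; dataset-level class
  counts are not available inside a generic training step. A batch with no
  foreground gives α=1 (foreground-silent gradient) and a warning.

### Numerical conventions

* Probabilities are clipped to `[1e-7, 1−1e-7]` before any logarithm.
* Dice smoothing ε defaults to 1e-6 (configurable); ε=0 with empty
  prediction and target is an error rather than a silent 0/0.
* `gdsc` on a batch with no foreground sets `w_fg = 0` with a warning
  (1/N_fg² is undefined); lesion-patch filtering normally prevents this.
* All analytic logit-gradients are the chain rule
  `∂L/∂f = ∂L/∂p · p(1−p)`; every one is tested against central finite
  differences (step 1e-4, relative tolerance 1e-4).

The saturation pathology that motivates the gradient-defined loss is
exposed directly: for a background voxel predicted at `p = 1−10^-k`, the
Dice logit-gradient magnitude decays to zero as k grows (the bounded Dice
derivative is multiplied by the vanishing sigmoid slope), while the
cross-entropy logit-gradient converges to 1/N — confidently wrong voxels
stop receiving corrective signal under Dice-family losses.

## Network

A simple 3D U-net: encoder levels of 32, 64, 128, 256 channels, one
3×3×3 convolution per level followed by ReLU and group normalisation
(groups of 8 channels), max pooling of size 2 between levels; decoder with
parameter-free ×2 upsampling, concatenation skips and one conv+ReLU+norm
per level; final 1×1×1 convolution to a single logit channel. With two
input channels this has exactly 2,906,913 trainable parameters. The
parameter count is treated as the architectural ground truth: enumerating
the open design axes (input channels 1/2, convs per block 1/2,
transposed-conv vs parameter-free upsampling, norm on/off, bias on/off)
yields exactly one matching configuration — the one above. The count
cannot distinguish nearest-neighbour from trilinear upsampling; nearest is
used because its backward is an exact block-sum adjoint.

The network is implemented on a small explicit-backprop numpy engine
(`nnops`): convolutions as 27 shifted GEMMs, group-norm and max-pool with
hand-derived backward passes, and Adam (lr 1e-3 by default — the
conventional choice for U-nets of this size). Float32 throughout;
weight initialisation is He-normal drawn from a `numpy.random.Generator`,
so identical seeds give bitwise-identical weights. The whole-network
backward is verified against float64 central differences.

Input volumes are z-scored per volume over brain-mask voxels; air stays at
zero.

## Patch pipeline

Patches of 32³ voxels are taken on a stride-16 sliding window over the
brain bounding box (0-based, half-open windows). The last origin per axis
is clamped to `hi−32` so coverage is exact for any extent; boxes narrower
than a patch get a single centred window with zero-padding at extraction.
Training uses only lesion-containing windows, shuffled deterministically
per epoch and grouped into batches of 16. Evaluation uses *all* windows:
full images are reconstructed by averaging every window prediction
covering each voxel (uncovered voxels are 0 — reconstruction covers the
whole volume, not just the bounding box), then binarised at 0.5 (ties
count as foreground).

## Metrics

DSC = 2TP/(2TP+FN+FP), TPf = TP/(TP+FN), precision = TP/(TP+FP), from
voxel confusion counts. Degenerate denominators use the
"reward correctly empty output" convention (a lesion-free truth scores
TPf = 1 iff there are no false positives); lesion-free images do not arise
in the intended evaluation, so any consistent convention serves. Image-wise
results are recorded per subject and averaged across subjects (confusion
counts can equally be pooled; per-subject averaging is the default
reporting); patch-wise results pool confusion counts over all training
patches of the epoch.

## Experiment harness

For each cross-validation fold and each seed, a sub-seed is derived from
(seed, fold) by a fixed integer hash — never from the loss — so that all
losses in a cell start from bitwise-identical weights and see identical
batch orders. Folds are near-equal disjoint test splits, fixed by a
separate split seed and reused across seeds and losses. Each epoch trains
on the lesion-containing patches and then evaluates patch scope, training
images and test images, in that order. No early stopping: runs always
reach `max_epochs`. Band summaries report min/mean/max per (loss, epoch,
scope, metric) over seeds, folds and subjects.

## Synthetic phantoms

The generator emulates the imbalance statistics of public lesion cohorts
rather than their appearance: a volume (default 96³) containing an
ellipsoidal brain (default semi-axes 0.30/0.27/0.24 of the volume extent,
i.e. a head-sized field of view where the brain occupies a small fraction
of voxels), smooth tissue texture (Gaussian random field, σ=4 voxels) plus
voxel noise (σ=0.05), and ellipsoidal lesions with log-normal sizes
(default mean 111 voxels, log-σ 0.7 — the mean matches reported lesion
statistics; the heavy right tail is the standard lesion-size model since
only the mean is pinned). Lesions are placed uniformly inside the brain,
rejected on contact with existing lesions (1-voxel gap, so connected
components equal placed lesions), and added until the lesion fraction of
brain voxels is within ±25% of the target; a rasterised blob that would
overshoot the band is re-drawn smaller. Two presets: `wmh_like` (fraction
0.0154) and `lit_like` (0.0014). Lesion intensities sit above the tissue
99th percentile (hyperintensity contract). Two-channel mode duplicates the
anatomy with different contrast and independent noise.

What the phantoms do **not** contain: MRI physics (bias fields, partial
volume, anisotropic voxels), realistic anatomy, registration artefacts, or
longitudinal change. Consequently, passing tests demonstrate that the
pipeline and the loss behaviours are correct under controlled imbalance —
the characteristic high-sensitivity/low-precision signature of heavily
foreground-weighted losses reproduces clearly — but say nothing about
absolute segmentation quality on real MRI.

## Desk-scale problem sizes

The reference protocol (5 seeds × 5 folds × 25 epochs, full-width network)
is a GPU-scale computation. The package's own end-to-end check runs a
reduced campaign chosen to exercise every code path on a single CPU:
12 subjects at 96³ with lesion fraction 1.5%, two losses (xent, new),
2 seeds × 2 folds × 5 epochs, and a narrow U-net variant
(widths 2/4/8/16, group size 2) exposed through the experiment plan. All
protocol structure (patch size 32, stride 16, batch 16, threshold 0.5,
shared-seed discipline) is identical to the full configuration; only
widths and counts are scaled down. The qualitative conclusions that the
package asserts at this scale are directional (e.g. early-epoch training
image TPf of the gradient-weighted loss exceeds cross-entropy's), not
numeric reproductions of full-scale results.

## Known limitations

* The numpy engine is single-device and unbatched across cells; full-width
  training is supported but slow — the engine exists for correctness and
  reproducibility, not throughput.
* Only binary segmentation; no multi-class labels, boundary losses, or
  lesion-wise (component) detection metrics.
* Nearest-neighbour upsampling is one of several decoders consistent with
  the printed parameter count; results at full scale could differ mildly
  under trilinear interpolation.
* The gradient-defined loss's forward value is a monitoring convention;
  only its gradient is meaningful for optimisation.
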
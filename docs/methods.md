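# Methods

This note records what `brainmga` implements, the assumptions and numerical
choices behind it, and what the synthetic data generator does and does not
emulate.

## 1. Scientific problem

Brain age — the age a regression model predicts from a structural T1-weighted
MR volume — is a widely used imaging biomarker: a positive gap between
predicted and chronological age correlates with neurodegenerative risk.
`brainmga` implements a 3D convolutional brain-age regressor whose residual
blocks are augmented with two parallel attention mechanisms:

* a **spatial squeeze-and-excitation (sSE)** gate that reweights voxels, and
* a **multi-hop graph attention (MGA)** module that treats patches of the
  feature map as graph nodes and lets spatially distant regions exchange
  information along multi-step similarity paths.

The motivation for MGA is that aging affects anatomically distant structures
in a correlated way (e.g. ventricle enlargement together with cortical
thinning), which plain convolutions with local receptive fields capture only
slowly with depth.

## 2. The MGA module

For a feature map of extent `C × H × W × D` and split ratio γ:

1. **Patchify.** Patches of extent `C × H//γ × W//γ × D//γ` are placed on a
   grid with stride `min(H//γ, W//γ, D//γ)`. Axes whose patch extent exceeds
   the stride produce overlapping placements; on non-divisible extents the
   final placement is anchored at `extent − patch_extent` so every voxel is
   covered.
2. **Node descriptors.** Each patch becomes a 2-vector: its mean (global
   average pooling) and maximum (global max pooling).
3. **Edge scores.** With a learned embedding `V ∈ ℝ^{2×2}`, the similarity of
   nodes i, j is `e_ij = 1 / exp(‖V h_i − V h_j‖₂)`. The diagonal is exactly
   1 and the matrix is exactly symmetric by construction. Distances are
   clipped at 50 before exponentiation so `e_ij` never underflows to a
   denormal regime.
4. **Normalization.** `Ẽ = D⁻¹ E` with `D = diag(row sums)`; each row of `Ẽ`
   is a probability distribution.
5. **Multi-hop accumulation.** `E∀m = Σ_{j=1..m} β^{j−1} Ẽ^j` aggregates walk
   probabilities up to m hops with decay β, then is symmetrized as
   `(E∀m + E∀mᵀ)/2`. Before symmetrization every row sums to
   `(1 − β^m)/(1 − β)` (or `m` when β = 1), which the tests exploit as a
   closed-form invariant.
6. **Thresholding.** θ is the mean of the superdiagonal of the symmetrized
   matrix; the binary adjacency keeps entries strictly above θ and forces
   self-loops. The binary mask is treated as a constant under
   differentiation (a straight-through-style choice: the mask is piecewise
   constant, so its exact derivative is zero almost everywhere).
7. **Masked attention.** With a learned vector `a ∈ ℝ⁴`, logits
   `LeakyReLU(aᵀ[V h_i ‖ V h_j])` (slope 0.2) are softmax-normalized over
   each node's binary neighborhood; the attention matrix multiplies the
   patch matrix, and patches are reassembled with a voxelwise mean over
   overlapping placements.

A full MGA layer runs `k` such branches (default split ratios γ ∈ {2, 4})
and averages their outputs. During training each branch is dropped
independently with probability `drop_path_rate` (default 0.1); if every
branch drops, the layer is the identity.

Defaults follow the published configuration: m = 3, k = 2, γ = {2, 4},
β = 0.8.

Two implementations exist and are tested against each other: a float64
functional reference (`brainmga.mga`) used by oracles and the acceptance
script, and a batched float32 differentiable layer (`backbone.MGALayer`)
used inside the network.

## 3. The backbone

`MGASSEResNet18` is a 3D ResNet18: a 7³ stride-2 stem convolution with batch
normalization and a 3³ stride-2 max pool, then four stages of two residual
units with channel widths `w, 2w, 4w, 8w` (published width w = 64). Each
unit computes the standard pre-activation-free basic block
`y = relu(bn(conv(relu(bn(conv(x))))) + skip)` and then adds the averaged
attention correction `z = y + mean(sSE(y), MGA(y))` as an outer skip
connection. Global average pooling, an optional sex one-hot concatenation,
and a linear unit produce the scalar age.

Numerical/architectural choices:

* **Halving padding.** Every stride-2 operation uses per-axis padding chosen
  so the output extent is exactly `floor(n/2)`, reproducing the size ladder
  `101×101×121 → 50×50×60 → 25×25×30 → 12×12×15 → 6×6×7`. The 1×1×1
  projection on downsampling skips cannot pad, so it crops one leading voxel
  per axis before the stride-2 convolution, which yields the same `n//2`.
* **Minimum input extent 32.** Five stride-2 halvings of anything smaller
  leave zero voxels; the forward pass rejects such inputs.
* **γ clamping.** Deep stages of desk-scale (32³) inputs have feature maps
  smaller than γ; the layer clamps γ to the smallest spatial extent instead
  of erroring (the functional API keeps the strict invalid-split error).
* **Per-component RNG streams.** Each unit draws its convolution, sSE, MGA,
  and drop-path randomness from independent seeded streams, so toggling a
  module off leaves every other parameter bitwise unchanged (exact ablation
  parity, which the tests verify).
* **Batch normalization** after every convolution (the standard ResNet18
  recipe), momentum 0.1, eps 1e-5.
* **Head bias initialization.** The regression head's bias starts at the
  mean training age. Adam's per-step displacement is bounded by the learning
  rate, so starting at 0 would spend far more than the desk-scale budget
  moving the output toward ~45 years; mean-age initialization is standard in
  brain-age regression and leaves the learning task intact. It is skipped
  when resuming a checkpoint whose head is already trained.

The package contains its own compact reverse-mode automatic differentiation
engine (`brainmga.autodiff`) and layer library (`brainmga.nn`) built on
numpy: convolutions are im2col gathers with scatter-add backward passes, and
every primitive's gradient is validated against central finite differences
in the test suite. Model parameters are float32; the functional MGA
reference is float64.

## 4. Training protocol

* **Loss.** `MSE + λ·(1 − ρ_soft)` where `ρ_soft` is a differentiable
  Spearman surrogate: prediction ranks are softened as
  `r_i = Σ_j σ((x_i − x_j)/τ)` with temperature τ = 0.1, targets keep exact
  ranks, and the Pearson correlation of the two rank vectors is taken. As
  τ → 0 it converges to the exact Spearman coefficient (the exact
  coefficient is kept as a non-differentiable test oracle). With one sample
  or a constant target batch the loss falls back to MSE with a warning.
* **Optimizer.** Adam, initial learning rate 0.005, weight decay 1e-4
  (L2 folded into the gradient), batch size 12, learning rate ×0.1 every 70
  epochs.
* **Augmentation.** Per-axis rotation ~ Uniform(−20°, 20°) composed about
  the three axes, plus integer translation ~ Uniform{−6,…,6} voxels per
  axis; one composed affine resampling (trilinear, zero fill).
* **Split.** 70/15/15 stratified by age decade, with largest-remainder
  allocation so the global validation/test counts equal `round(n·frac)`
  exactly.
* **Model selection.** The checkpoint with the best validation MAE is
  retained.
* **Bias correction.** Brain-age models regress toward the training mean.
  An OLS fit `pred ≈ a·chron + b` on validation predictions gives the
  correction `corrected = (pred − b)/a`; fits with fewer than two distinct
  ages or zero slope are refused.
* **Metrics.** Mean absolute error (years) and the Pearson correlation
  coefficient; degenerate (zero-variance) inputs report the correlation as
  NaN.

All randomness (initialization, drop path, shuffling, augmentation) derives
from a single integer seed; two runs with the same seed produce identical
histories on CPU.

## 5. Synthetic phantom generator — scope

The generator emulates the *statistical structure* a brain-age model relies
on, not anatomy:

* an outer brain ellipsoid (semi-axes 0.42 of each grid extent) at
  parenchyma intensity 0.6;
* a cortical shell (ellipsoidal radius in (0.85, 1]) whose intensity fades
  linearly with age, 0.03 per decade from 0.9;
* a central spherical "ventricle" cavity (intensity 0.1) whose radius grows
  0.4 voxels per decade (on a 32-grid scale), from 2.0 voxels at the lower
  age bound;
* optional low-order polynomial shading, additive Gaussian noise (σ = 0.05),
  and a final min–max normalization to [0, 1].

Ventricle enlargement and cortical fading co-vary with age in spatially
distant regions, so long-range feature co-occurrence genuinely carries the
label — the property MGA is designed to exploit. Ages are uniform on
[20, 70]; sex labels are Bernoulli(0.5) **null covariates** with no
structural effect, so a sex-input model should gain nothing from them.
Volumes can be written as NIfTI with 1.2 mm isotropic voxel metadata plus a
CSV manifest, and read back bit-identically.

What the phantoms do **not** emulate: real neuroanatomy, tissue-contrast
physics, scanner/site effects, registration error, or the published
cohort's age distribution. Desk-scale results on phantoms therefore say
nothing about real-data accuracy; they verify that the pipeline can extract
a known age signal.

## 6. Problem sizes and limitations

* The reference MR extent `101 × 101 × 121` (1.2 mm isotropic) runs in a
  forward pass at reduced width on CPU; training at published width
  (w = 64) and scale (thousands of volumes, hundreds of epochs) requires
  GPU hardware and is out of scope.
* Desk-scale experiments use 32³ phantoms at quarter width (w = 16): a
  200-subject, 10-epoch run takes roughly two minutes on one CPU and beats
  the constant mean-age predictor on validation by a wide margin
  (see README).
* The published headline accuracy (MAE ≈ 2.8 years on real data) is **not**
  a claim of this package and is not reproducible at desk scale; no
  empirical claim in this documentation goes beyond what the included tests
  and scripts compute.
* The autodiff engine is single-threaded numpy; it favors correctness and
  testability over speed. Memory scales with the autodiff tape; batch 12 at
  32³ and width 16 stays well under 2 GiB.
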
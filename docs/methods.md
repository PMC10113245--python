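# Methods

## Scope and substrate

The package implements the DHMF-MLP segmentation architecture and its
training/evaluation pipeline as a self-contained numpy library. No deep
learning framework is used: `dhmfmlp.nn` is a tape-based reverse-mode
autodiff engine whose operations (convolution with groups/stride via strided
window views, per-pixel linear maps, layer/batch normalization, exact-erf
GELU, block and adaptive max pooling, matrix-form bilinear upsampling, axial
shifting, and the losses) each carry an analytically derived adjoint. Every
adjoint is verified against float64 central differences in the test suite,
which is the load-bearing correctness argument for everything built on top.

## Architecture choices where the design was open

* **Channel bookkeeping in the first fusion pass.** A depth-wise convolution
  cannot change the channel count and DSLA is channel-preserving, so after
  concatenating the down-sampled fᵢ₋₁′ (Cᵢ₋₁ channels) with fᵢ (Cᵢ), a 1×1
  convolution (+BN+ReLU) projects back to Cᵢ. With this reading the fusion
  plumbing contributes 1,664,288 parameters and the five axial MLPs
  361,920 + 4 μ scalars, which together with the 2,515,361-parameter backbone
  reproduce the architecture's reported rounded totals for every ablation
  variant (2.52 / 4.18 / 4.54 M). Those totals were used as the calibration
  constraint wherever the layer-level description is ambiguous.
* **Skip merging.** Concatenation with the encoder feature followed by a 1×1
  projection (not addition); this is the choice consistent with the 2.52 M
  backbone total. A variant with addition after channel-matching 1×1 maps
  lands at 2.47 M and was rejected.
* **Tok-MLP normalization.** One layer norm at block entry (UNeXt parity).
  A variant with a second norm before the output projection would add 6,144
  parameters and break the published totals, so it was rejected.
* **DSLA composition.** Serial, ASAM first (feature selection) then
  Axial-mlp (global context). The printed ReLU inside ASAM is kept as
  printed even though it confines attention weights to [0.5, 1).
* **μ parameterization.** Each of the four DSLA instances stores one
  unconstrained scalar mapped through a logistic (initialized at 0 so
  μ starts at 0.5); μ therefore stays strictly inside (0,1) during training.
  The `no_lp_no_axial` variant replaces it with the constant 0.5 and
  registers no parameter.
* **Shift convention.** h = 5 contiguous channel groups with offsets
  (−2,−1,0,+1,+2) and zero filling. The configured widths (32…256, hidden
  768) are not multiples of 5, so groups are formed by near-equal contiguous
  splits, largest first, keeping every channel shifted. The standalone
  `axial_shift` operation is strict (errors unless C divides by h).
* **Grid size at small resolutions.** The axial MLP mixes across a d×d tile
  partition with d = 8. At the full 256/512-pixel configurations every
  instance runs at d = 8; for the 64-pixel synthetic protocol the coarsest
  stages are 4- and 2-pixel maps, where the per-instance grid degrades to
  d = min(8, H, W) (one-pixel tiles, i.e. fully global mixing). Parameter
  totals quoted above always refer to the full-size configuration.
* **Tokenization** is row-major (y, x) flattening; because the token-wise
  linear maps act on the channel axis it is carried implicitly by the
  (B, C, H, W) layout and inverts bit-exactly.

## Objective, metrics, numerical conventions

* L = 0.5·BCE + (1 − soft Dice), BCE computed from logits with the stable
  log1p form, Dice smoothing ε = 1 in numerator and denominator. The Dice
  term is a loss; a literal similarity term would be maximized by bad
  predictions.
* Probabilities are binarized at τ = 0.5 with ŷ ≥ τ counted positive.
* Zero-denominator policy: IoU/Dice/SE/PPV/SP are defined as 1 when their
  denominator is empty (vacuous agreement, e.g. empty ground truth and empty
  prediction); metrics never crash.
* Metrics are computed per image from that image's confusion counts and
  averaged over the set (the mean row of the CSV), rather than pooling
  counts across images.
* Layer norm uses ε = 1e−6 over channels per pixel; batch norm ε = 1e−5,
  momentum 0.1 with unbiased running variance. Bilinear upsampling uses
  half-pixel (align-corners-false) sampling expressed as two interpolation
  matrices, which makes its adjoint exact.
* Weight init: truncated normal (σ = 0.02) for linear maps, Kaiming-normal
  for convolutions, unit/zero for norms; all construction flows from one
  `numpy` Generator seeded per model.

## Training recipe

Adam with β₁ = 0.9 ("momentum 0.9" read as the first-moment coefficient),
β₂ = 0.999, initial learning rate 1e−4 annealed by cosine to 1e−5 over the
run (a constant schedule is available by flag); 400 epochs and batch size 8
by default (4 for gland-histology-style runs); 8:2 random split with the
training share floored; augmentation restricted to lossless transforms
(50% horizontal flip, 50% vertical flip, uniform k·90° rotation) applied
identically to image and mask so masks stay exactly binary. Images are
scaled to [−1, 1]. Non-finite losses abort with a diagnostic.

## Synthetic data

The generator emulates the statistical shape of ultrasound-like lesion data:
a low-frequency textured background (bilinear-upsampled coarse Gaussian
field, amplitude 0.08 around level 0.35), 1–4 rotated ellipses per image
with semi-major axes 3–25% of the image side (the lower end is the
small-lesion regime, foreground < 2%), a +0.3 intensity offset inside
lesions, multiplicative Gaussian speckle (σ = 0.15), and near-identical RGB
channels. The mask is the ellipse union. It reproduces bit-exactly from its
seed. It does **not** emulate acoustic shadowing, attenuation, anisotropic
speckle, annotator noise, or class imbalance across patients — so passing
tests demonstrate architectural correctness and trainability, not clinical
performance.

## Reduced-scale trainability protocol

Full-scale training (hundreds of 256² images, 400 epochs) is out of scope on
a single CPU. The capacity check trains the width-reduced model (channels
and token width divided by 4) on 20 synthetic 64×64 images for 200 epochs
and requires training IoU ≥ 0.9 with a plateauing loss curve. Because this
is ~600 optimizer steps — an order of magnitude fewer than a full-scale
run — the protocol uses a 1e−3 → 1e−5 cosine schedule; the library default
remains 1e−4. "Plateauing" is implemented as: over the final half of the
window-5-smoothed loss curve there is no net rise and no single smoothed
step up exceeding 5% of the run's total loss drop (epoch means over three
reshuffled batches fluctuate by a few percent even when converged).

## Known limitations

* CPU-only and eager: a full 256² forward pass takes seconds, so the
  package targets correctness, small-scale experiments, and teaching, not
  production training.
* Binary segmentation only (1-logit head).
* Adaptive max pooling supports integer-ratio reductions (all shapes that
  arise in this architecture); arbitrary ratios are rejected.
* Input sides must be divisible by 32; the axial-MLP grid additionally
  requires divisibility by the per-stage effective d, which holds for the
  supported sizes.
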
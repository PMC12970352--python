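# Methods

## The pretraining objective

The backbone is a standard vision transformer. A frame `x ∈ R^{H×W×C}` is
split into non-overlapping `P×P×C` patches, each flattened and linearly
projected to a `D`-dimensional patch token; fixed 1-D sinusoidal position
embeddings are added to the patch tokens, and a learnable CLS token (no
position embedding) is prepended. Two self-supervised losses are combined:

**Masked autoencoding.** A fraction `ratio` (default 0.75) of the `N` patch
tokens is hidden uniformly at random; the encoder sees only the
`L = N − round(ratio·N)` visible tokens plus CLS. Zero embeddings are
re-inserted at the hidden positions to rebuild the full-length sequence in
original patch order, and a small transformer decoder (width `D/2`, depth 2
by default) maps it back to pixels. The loss is the mean squared error,
averaged over the `P²C` elements within each patch and over the selected
patches. Two scopes are supported: `masked_only` (default — reconstructing
visible patches is nearly trivial and dilutes the signal) and
`all_patches` (the literal all-patch average). The per-element mean (rather
than a per-patch sum) makes the loss scale independent of patch size, so
the contrastive weight `λ` does not need retuning across resolutions.

**Temporal contrastive loss.** Each batch of `B` frames contains `B/2`
anchors; each anchor at time `t` is paired with a positive drawn uniformly
from `{t−1, t+1}` (clipped at clip boundaries), and every other frame in
the batch is a negative. Anchors are chosen to be visually distinct by
greedy farthest-point selection on 32×32 grayscale downsamples (first
anchor uniform, seeded; ties break to the lowest frame index), and
same-video anchors are kept `min_negative_gap + 2` frames apart (default
gap 30) so that no same-video non-positive pair is closer than the gap.
CLS embeddings are projected by a 2-layer GELU MLP and scored with
InfoNCE:

    L = −(2/B) Σ_{i∈A} log [ exp(s(i,i′)/τ) / Σ_{j≠i} exp(s(i,j)/τ) ]

where the denominator runs over *all* `j ≠ i`, including the positive.
With `τ = 1` and raw dot-product similarity this is the plain form the
oracle tests enumerate. The total loss is `L_MSE + λ·L_InfoNCE`, optimized
with AdamW (β = 0.9/0.95, weight decay 0.05) under cosine-annealed lr with
a 10-step linear warmup.

### Desk-scale defaults and why they deviate from common large-scale practice

The default configuration (64px frames, P=8 → N=64 tokens, D=128, depth 4,
4 heads, batch 16, 300 steps, base lr 1e-3) is sized to train in minutes on
one CPU. Three defaults were set by direct experiment at this scale:

* **Contrastive branch on a separate unmasked pass**
  (`contrastive_full_pass=True`). At a 0.75 mask ratio the moving subject
  frequently loses *all* of its patches, so a masked-pass CLS often cannot
  carry any temporal information and the InfoNCE term sits permanently at
  its collapse value `log(B−1)`. Sharing the masked pass remains available
  as a flag (it is the cheaper choice when the subject covers most of the
  frame).
* **Normalized projections with τ = 0.1, λ = 1.0.** With raw dot products
  and near-identical initial projections the loss surface is a plateau;
  normalization plus a sharp temperature restores a usable gradient and
  makes the InfoNCE converge within the 300-step budget (the depth of the
  final InfoNCE value is what predicts how well projections rank temporal
  neighbors). λ and τ were selected by a small sweep on the synthetic
  validation scene. The raw `τ=1` form is what the brute-force
  equivalence tests check.
* **Fan-in-scaled weight init** (trunc normal, std `1/√fan_in`). The
  0.02-std init common in large ViTs leaves the frame-dependent part of
  the CLS embedding at ~1e-4 of its norm at this width; fan-in scaling
  preserves enough input signal for the contrastive term to train from
  scratch (there is no large pretrained checkpoint to start from here).

Masking uses `round(ratio·N)` so non-multiple-of-4 patch counts are
handled; `N=196, ratio=0.75` gives exactly 49 visible tokens.

## Synthetic behavioral scenes

The generator emulates the regime this kind of pretraining targets:
controlled experiments with a static background and a single moving
subject.

* **Background**: smoothed uniform noise, fixed per `background_seed`;
  bitwise constant across frames away from the sprite.
* **Motion**: mean-reverting (Ornstein–Uhlenbeck-style) random walk with
  reversion 0.05/frame toward the frame center and base step s.d. 2.5 px,
  clamped to keep the sprite inside the frame.
* **States**: a sticky hidden Markov chain (default 3 states, 0.95
  self-transition) that scales the step s.d. by `4^(k − (K−1)/2)` —
  states modulate *motion*, not appearance, so segmenting them requires
  temporal context.
* **Keypoints**: rigid offsets from the sprite center (radii 0.4–0.75 of
  the sprite radius) plus isotropic Gaussian jitter of s.d. 0.5 px, which
  sets a known floor on achievable pose error. Keypoints are rendered as
  small bright dots on the sprite body so they are visually localizable.
  Sprite geometry is drawn from `appearance_seed` (fixed by default, like
  `background_seed`), so scenes that differ only in `seed` show the *same*
  subject with new behavior — the faithful analog of a held-out animal
  from the same experimental setup. Frozen-feature pipelines are sensitive
  to this: a subject with different geometry shifts the feature
  distribution between train and held-out scenes.
* **Spikes**: `Poisson(softplus(w·[position, velocity] + b))`, rates
  rescaled so the maximum equals `bin_rate_max` (default 5 expected
  spikes/bin) and floored at 1e-9.

What the generator does **not** emulate: appearance-defined behaviors,
multi-animal interaction, camera motion, lighting changes, occlusion, or
non-Poisson spiking. Passing the recovery tests therefore shows the
pipeline is implemented correctly and can extract motion-borne structure;
it does not certify performance on real video.

## Downstream heads

**Neural encoding.** Features (per-frame CLS embeddings of the full
unmasked pass, 1-D motion energy, keypoints, or any external series) are
fit to spike counts with (a) reduced-rank regression — the ridge OLS
solution projected onto the top-`r` right singular vectors of its fitted
values — or (b) a temporal convolution network: two 1-D convolutions
(joint receptive field = `window`, default 21 bins) with GELU and a
pointwise head, trained with the Poisson likelihood through a softplus
(counts) or squared error (neural PCs). The TCN is a small configurable
stand-in for temporal-convolution encoders used in facial-videography
work; its exact published architecture is not reproduced. Because a wide
temporal window overfits short recordings, `fit_tcn_encoder` accepts a
validation block and restores the best-validation parameters (checked
every 10 epochs). Scores: bits per spike, `(LL(pred) − LL(train-mean)) /
(n_spikes·log 2)`, with neurons lacking test spikes excluded and reported;
or per-PC `R² = 1 − SSE/SST` about the test mean. Splits are contiguous
70/15/15 time blocks to prevent temporal leakage.

**Pose estimation.** A head on the patch embeddings reshapes them to the
patch grid and applies two learned pixel-shuffle (kernel-2/stride-2
transposed-convolution) upsampling stages plus a pointwise convolution,
giving K heatmaps at 4× the patch grid (stride `P/4` pixels). Targets are
unit-peak Gaussians with σ = 2 heatmap pixels; training is end-to-end
(backbone + head) with visibility-masked MSE. Decoding is soft-argmax over
a softmax-normalized map with sharpness β = 20 — β was calibrated so that
encoding a keypoint to the σ=2 target and decoding it back errs by at most
~0.12 px for interior keypoints (small β blurs toward the image center,
large β collapses to the cell grid); two equal peaks decode to their
midpoint by construction. Ensemble evaluation reports the error-vs-
difficulty curve: e.s.d. of a (frame, keypoint) is the RMS Euclidean
deviation of ensemble members from their mean prediction, and each curve
point is the member-averaged pixel error over keypoints with e.s.d. above
a threshold (the τ=0 point covers all keypoints).

**Action segmentation.** The backbone is frozen. Frame features are either
CLS embeddings or patch embeddings pooled by a single learned query with
multi-head attention (4 heads; the pooler adds no positional terms — patch
embeddings already carry position — and is used with seeded fixed weights
as a feature extractor). Features are concatenated with their inter-frame
differences (zero at t=0), windowed (W=11, replication padding at edges),
and classified by a linear head or a two-convolution TCN predicting the
central frame's class, trained with cross-entropy (optional
inverse-frequency class weights; classes absent from the train split get
weight 0 with a warning). Ensembles average logits across seeds *before*
the softmax (5 seeds by default). Evaluation is macro-averaged F1,
optionally over a named class subset; the held-out unit is a whole scene
(new generator seed), the synthetic analog of a held-out animal.

## Numerical and implementation notes

* All models run on an in-package reverse-mode autodiff core over NumPy
  float64 (`beast.nn`): the model sizes here make a plain vectorized
  NumPy graph fast, exactly reproducible, and dependency-free. Every
  forward pass in inference mode is deterministic; all randomness flows
  from explicit integer seeds through `numpy.random.Generator`.
* Temporal convolutions use replicate padding, so a "window" at a sequence
  edge repeats the boundary frame — consistent between the windowing
  utility and the convolutional heads.
* InfoNCE masks the `j = i` diagonal with −1e30 before a stable
  log-sum-exp; MAE with `masked_only` scope and an all-false mask is
  rejected rather than silently returning 0/0.
* RRR with `ridge = 0` raises on (near-)singular designs (condition number
  > 1e12) with advice to add ridge, rather than returning an unstable
  solve.
* Problem sizes used by the acceptance script: one 2,000-frame 64×64
  scene, 300 pretraining steps at batch 16; 100 labeled frames for pose
  with a 100-frame held-out block; 1,200 training frames and a 600-frame
  held-out scene for segmentation; contiguous 70/15/15 splits for
  encoding. These sizes were chosen so the whole pipeline reruns from
  scratch in minutes while every recovery stays comfortably measurable.

## Known limitations

* The anchor-distinctness metric (pixel L2 on 32×32 grayscale thumbnails)
  is a cheap stand-in; it is monotone in the obvious cases but blind to
  small-object appearance changes. It is injectable (`thumbnails=` /
  swappable metric) by design.
* The greedy farthest-point anchor selection can paint itself into a
  corner under the temporal-separation constraint; it then falls back to
  an evenly spaced temporal grid, which is always feasible when the
  capacity check passes.
* Video containers (MP4/AVI) are read through imageio and require an
  ffmpeg-capable backend in the environment; PNG/JPEG frame directories
  are the first-class path.
* The TCN architectures (encoder and segmentation head) are small
  config-exposed stand-ins, not reproductions of any published network.
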
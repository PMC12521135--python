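# Methods

## Problem and model

The package predicts early neurological deterioration (ND) after pontine
infarction. ND is defined on the National Institutes of Health Stroke Scale
(NIHSS, a 0–42 severity score): a patient is ND-positive when the total
NIHSS rises by at least 2 points between the initial and the maximal
neurological deficit. The classifier consumes two modalities per patient —
a 3D intensity volume (DWI-like, skull-stripped, intensity-normalized) and
four clinical variables (length of hospital stay, admission NIHSS,
discharge NIHSS, and vertebrobasilar artery stenosis) — and couples
patients through a cohort-level similarity graph.

The network has three stages:

1. **Feature processing.** A 3D CNN encodes the volume and a small FC stack
   encodes the clinical vector, both to a shared embedding length L
   (default 64). Each embedding is refined by a selective state-space
   block: the L-vector is reshaped into L/d tokens of width d (default 8)
   and passed through the input-dependent discretized recurrence

       h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t x_t,   y_t = C_t h_t + D x_t,

   with Δ_t = softplus(x_t W_Δ + b_Δ), B_t = x_t W_B, C_t = x_t W_C, and
   A < 0 (parameterized as −exp(A_log)). A sigmoid-gated residual returns
   the refined tokens to the input, so a zero-initialized block is the
   identity. The two refiners have separate parameters per modality.

2. **Dynamic residual fusion.** The two embeddings are channel-interleaved
   (image at even, tabular at odd indices) into O of length 2L, passed
   through a single-channel 1D convolution with "same" zero padding
   (kernel 3) plus a residual, and combined with an image-residual branch
   under convex weights:

       m = ω₁·(Conv(O) + O) + ω₂·lift(f_i),   ω₁ + ω₂ = 1,

   where lift(f_i) interleaves the image embedding with itself so its
   entries align with O's image channels (the fused length stays at 2L
   while the raw image embedding has length L; elementwise addition
   against O requires this lift). The weights are a softmax over two
   learnable logits initialized equal.

3. **Adaptive graph.** Fused embeddings are affinely rescaled
   (trainable α₁, β₁), row-L2-normalized, and their Gram matrix W gives
   pairwise cosine affinities. Hard thresholding W at 0.95 yields the
   binary adjacency A (the unit diagonal guarantees self-loops); its edge
   list feeds a two-layer GCN with symmetric degree normalization
   D̃^{−1/2}ÃD̃^{−1/2}, SiLU between layers, and a trainable (α₂, β₂)
   rescale before the row softmax. "Norm" is read as row-L2 normalization
   because the affinities are explicitly cosines; batch or layer
   normalization would not produce them. The threshold is
   non-differentiable, so the adjacency is treated as a constant within a
   forward pass and gradients reach the classifier through the node
   features only.

## Losses

* **Cross-modal alignment (CSDM).** Row-softmax (temperature τ, default
  0.02) of the n×n cross-modal cosine matrix gives predicted matching
  distributions in both directions; the loss is the mean KL divergence
  against the one-hot identity target. An exact one-hot makes the KL
  infinite, so ε = 1e−8 is added to the target inside the logarithm.
* **Graph-edge consistency (GE).** Frobenius distance between the
  predicted adjacency and the label-derived block adjacency
  (A*_ij = 1 iff y_i = y_j). Because the binary A blocks gradients, the
  training default evaluates the distance on the pre-threshold affinity W
  clamped to [0, 1]; the binary form is available (`ge_on_binary`) and
  used when reporting at evaluation. Inside the total training objective
  the GE term is divided by the batch size: the Frobenius distance between
  n×n adjacencies grows roughly linearly with n, and without this the
  effective loss weighting would depend on batch size. The standalone
  `ge_loss` function is the plain Frobenius distance.
* **Cross-entropy (CE)** on the softmax class probabilities, with
  probabilities floored at 1e−12 inside the log.

Total loss: λ₁·CSDM + λ₂·GE + λ₃·CE with defaults (0.2, 0.4, 0.4). Setting
any λ to zero disables its term, which together with the module switches
(`use_refiners`, `use_fusion`, `use_graph`, `modality`) reproduces the
standard ablation grid.

## Training and evaluation protocol

Adam with learning rate 1e−4, weight decay 1e−7, betas (0.9, 0.98),
100 epochs, batch size 32 (batch size is a package choice; the evaluation
graph is always built over the full evaluation cohort, transductively).
A stratified 20% test split is fixed first; stratified 5-fold
cross-validation divides the remaining 80% into train (64% of total) and
validation (16%) folds. Per fold, the checkpoint maximizing the unweighted
mean of validation accuracy, recall and precision is selected (ties go to
the earliest epoch) and evaluated on the common test set; metrics
(accuracy, recall, precision, F1, AUC, all for the positive class,
hard-label threshold 0.5) are aggregated as mean and sample SD over the
five test evaluations. Stratification is a package choice to keep both
classes present in every subset at small cohort sizes.

Because no deep-learning framework is part of the dependency set, the
package ships its own reverse-mode automatic differentiation tape over
numpy (`ndfusion._autodiff`) with exactly the primitives the model needs
(3D convolution via im2col, max pooling, matmul, reductions, softmax, the
scan) and a classic Adam. Analytic gradients are validated against central
finite differences in the test suite (relative error < 1e−3), and the scan
against a hand-unrolled recurrence.

## Synthetic cohorts

The real cohort (386 patients, 126 ND-positive) is hospital-proprietary;
the generator reproduces its published class-conditional summary
statistics. Generation is label-first: the class is fixed, then features
are drawn conditionally. Per class:

* **Continuous features** (age, stay length, admission/discharge NIHSS)
  come from Gaussians clipped to plausibility bounds (NIHSS to [0, 42],
  age to [18, 100], stay to [1, 90] days). Clipping shifts means and
  shrinks SDs, so the generator first solves for pre-clip (μ, σ) such that
  the *post-clip* mean and SD equal the published targets, using
  closed-form clipped-normal moments and scipy root finding. Admission and
  discharge NIHSS are drawn jointly from a bivariate Gaussian; the implied
  correlation is recovered from the published marginal SDs and the SD of
  the change via ρ = (σ_a² + σ_d² − σ_Δ²)/(2σ_aσ_d) (positive class
  ≈ 0.49, negative ≈ 0.85), and the pre-clip correlation is additionally
  calibrated (1D quadrature for the clipped cross-moment + root finding)
  so the post-clip change-SD matches the printed value.
* **Published negative-class age SD (48.16).** No distribution supported
  on [18, 100] can have an SD above half the range (41), so this printed
  value is unattainable under any plausible-age model and is almost
  certainly a transcription error. The generator matches the negative-class
  age *mean* exactly (mean-only calibration at the printed σ) and lets the
  support cap the SD; tests assert the mean but not this SD.
* **Maximal NIHSS** is constructed so the ND rule reproduces the class:
  positives add max(2, round(|half-normal, scale 2|)) points to the
  admission score, negatives add a fair coin flip (0 or 1). Only the label
  rule is anchored in published data; the rise distribution is a minimal
  mechanism choice. The maximal score is recorded but never fed to the
  model.
* **Binary features** (sex, thrombolysis, stenosis) use exact class counts
  by default — at full cohort size the published splits exactly, scaled by
  rounding at other sizes — assigned by a seeded shuffle; a Bernoulli mode
  exists.
* **Volumes** are ellipsoidal "brainstem" phantoms with additive Gaussian
  noise and one hyperintense spherical lesion (radius 1.5–3 voxels) whose
  contrast is class-dependent, then z-scored within the nonzero foreground
  mask. This carries a tunable amount of image-label signal; it does not
  emulate real DWI texture, lesion morphology, or scanner physics, so
  passing tests demonstrate the pipeline's mechanics and statistical
  protocol, not clinical performance.
* **`effect_scale`** rescales the between-class separation of the model's
  input features and the lesion contrast around their pooled values:
  0 yields a label-free null cohort, 1 the published separation, larger
  values a strongly separable cohort for capacity checks.

## Numerical and sizing choices

* Float64 throughout; group normalization (batch-size independent) after
  each conv stage; SiLU activations; Kaiming-style init.
* Test and acceptance runs use desk-scale settings chosen as the smallest
  sizes at which each property is meaningful: 8×16×16 or 8×32×32 volumes,
  embeddings of 16–32, cohorts of 16–40, and 1–3 training epochs for
  protocol checks. The capacity check (16 separable samples to perfect
  training accuracy within 200 epochs) uses learning rate 1e−2: it probes
  model capacity, and 200 full-batch Adam steps at the protocol's 1e−4
  cannot traverse the loss landscape from a fresh initialization at any
  problem size.
* Moment-recovery checks use 2×10⁵ samples per class against 2–3 standard
  errors.

## Known limitations

* Discharge NIHSS is a model input yet is temporally posterior to the ND
  event window; it is included because the published variable selection
  includes it, but a deployed predictor could not use it prospectively.
* The cohort graph is transductive; evaluation cohorts are classified
  jointly, and test-time nodes see only other evaluation nodes by default.
* The synthetic image modality is a phantom; conclusions about real-data
  discriminative performance cannot be drawn from it.
* The published headline metrics of the original cohort are data-bound and
  are not reproduction targets for the synthetic pipeline.
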
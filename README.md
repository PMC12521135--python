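# ndfusion

Multimodal prediction of early **neurological deterioration (ND)** after
pontine infarction — a brainstem ischemic stroke — from a 3D image volume
plus a handful of clinical variables, with patients coupled through a
cohort-level similarity graph. ND is defined as a ≥ 2-point rise in the
total NIHSS (National Institutes of Health Stroke Scale, 0–42) between the
initial and the maximal neurological deficit.

The package is aimed at methods researchers in medical image + tabular
fusion: the real 386-patient cohort behind the published statistics is
hospital-proprietary, so `ndfusion` pairs the full model and protocol with
a **synthetic cohort generator** that reproduces the published
class-conditional clinical statistics (means/SDs, exact binary-feature
counts, the correlated admission/discharge NIHSS pair) and renders phantom
volumes with a controllable class-dependent lesion signal — making the
entire pipeline buildable, trainable and testable end to end.

## The model

Per patient with volume *I* and clinical vector *T* (length of stay,
admission NIHSS, discharge NIHSS, vertebrobasilar artery stenosis):

1. **Feature processing** — f_θ(x) = SSM_θ(En_θ(x)), θ ∈ {i, t}: a 3D CNN
   (image) and an FC stack (tabular) embed each modality to length L,
   then a selective state-space block (input-dependent discretized
   recurrence h_t = Ā_t h_{t−1} + B̄_t x_t, y_t = C_t h_t, gated residual)
   refines each embedding.
2. **Dynamic residual fusion** — channel interleaving
   O[0::2] = f_i, O[1::2] = f_t, then
   m = ω₁·(Conv(O) + O) + ω₂·lift(f_i) with softmax-constrained weights
   ω₁ + ω₂ = 1 and a single-channel 1D convolution.
3. **Adaptive graph** — cosine affinity W = N Nᵀ of the row-normalized
   fused embeddings, hard-thresholded at 0.95 into a binary adjacency; a
   two-layer GCN with symmetric degree normalization classifies the
   cohort's nodes jointly (transductively).

Training minimizes λ₁·L_CSDM + λ₂·L_GE + λ₃·L_CE, defaults (0.2, 0.4,
0.4): a cross-modal similarity-distribution-matching KL loss, a Frobenius
graph-edge consistency loss against the label-block adjacency, and
cross-entropy. The evaluation protocol is a stratified 20% held-out test
set plus stratified 5-fold cross-validation of the remainder (64%/16%
train/validation), Adam (lr 1e−4, weight decay 1e−7, betas (0.9, 0.98),
100 epochs), checkpoint selection by the balanced mean of validation
accuracy/recall/precision, and mean ± SD of the five test evaluations.

The network, including a small reverse-mode autodiff engine it runs on, is
implemented on numpy alone — see `docs/methods.md` for the model details,
design choices, and limitations.

## Worked example

```python
from ndfusion import (CohortConfig, EncoderConfig, ModelConfig,
                      NeuroDeteriorationModel, TrainConfig)

cohort = CohortConfig(n_total=40, n_positive=16, volume_shape=(8, 16, 16),
                      lesion_radius_range=(1.0, 2.0), effect_scale=3.0, seed=0)
encoder = EncoderConfig(embed_dim=16, image_channels=(4, 8),
                        ssm_token_dim=4, ssm_state_dim=2, groupnorm_groups=2)
model = NeuroDeteriorationModel.from_synthetic(cohort, ModelConfig(encoder=encoder))
results = model.fit(TrainConfig(epochs=20, batch_size=16, learning_rate=3e-3, seed=0))
print(results.summary())
```

prints (a strongly separable 40-patient synthetic cohort, desk-scale
architecture, ~20 s on one CPU):

```
Neurological deterioration prediction - cross-validated test metrics
====================================================================
cohort size: 40   positives: 16   parameters: 3076
splits (test/val/train): 8/7/25
--------------------------------------------------------------------
metric            mean        sd
acc             0.9500    0.1118
recall          0.8667    0.2981
precision       1.0000    0.0000
f1              0.9000    0.2236
auc             1.0000    0.0000
====================================================================
```

Each row is the mean and sample SD over the five cross-validation models,
each evaluated on the same held-out 8-patient test set: with a strong
synthetic class signal (`effect_scale=3`) the cohort is essentially
separable and every fold ranks the test patients perfectly by score
(AUC 1.0), while the hard 0.5-threshold metrics retain some fold-to-fold
spread. On an `effect_scale=0` (null) cohort the same run hovers at
AUC ≈ 0.5.

A command line mirrors the library
(`ndfusion simulate|train|evaluate|ablate --config cfg.yaml --out DIR
--seed N`), writing cohorts as a clinical CSV plus NIfTI or `.npz`
volumes, metrics as JSON, and predictions as CSV.

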
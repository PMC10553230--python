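# vaebench

Benchmarking variational-autoencoder (VAE) variants on transcriptomics
data: which model and which hyperparameters give a latent space that is
actually useful downstream — for clustering samples by cancer type or
tissue, for survival modelling, and for interpretable (disentangled)
latent factors?

The package is aimed at computational biologists who embed bulk or
single-cell expression matrices with VAEs and need a systematic,
reproducible way to compare objectives and training settings, rather than
trusting the validation loss — which, as the benchmark itself shows, can
disagree with downstream performance.

## What it implements

**Six VAE objectives** over one fixed architecture (two fully-connected
layers per network, `input → 512 → d` encoder and mirrored decoder, MSE
reconstruction = Gaussian decoder with unit variance):

| variant | objective |
|---|---|
| vanilla | negative ELBO: `E‖x−x̂‖² + D_KL(q(z\|x) ‖ N(0, I))` |
| β-VAE | KL term weighted by β |
| β-TCVAE | KL decomposed into index-code MI (α) + total correlation (β) + dimension-wise KL (γ), minibatch-weighted-sampling estimator |
| DIP-VAE-II | vanilla + λ_od Σ_{i≠j}[Cov_q(z)]²_ij + λ_d Σ_i([Cov_q(z)]_ii − 1)² |
| IWAE | −log (1/K) Σ_k p(x\|z_k)p(z_k)/q(z_k\|x), log-sum-exp over K draws |
| CAT-VAE | Gumbel-softmax categorical latents; reconstruction + KL(q(y\|x) ‖ uniform) |

All models train on a compact reverse-mode autodiff engine
(`vaebench.autodiff`) with Adam / RMSprop / SGD, so the whole benchmark
runs anywhere numpy runs. Gradients are verified against finite
differences in the test suite.

**The benchmark protocol**: an exhaustive grid over model × latent
dimension {10, 20, 30, 50, 100, 200} × learning rate {1e-1 … 1e-6} ×
optimizer {adam, rmsprop, sgd} × five weight initializations × {relu,
tanh} — 1,080 configurations per model, 6,480 in all; 70/30
group-stratified splits, up to 1,000 epochs with patience-3 early
stopping, 10 restarts per configuration, and explicit failure detection
(any non-finite loss, gradient or weight fails the restart — divergence
is a recorded outcome, not a crash).

**Downstream evaluation**: Leiden communities on the 15-nearest-neighbour
Euclidean graph of the embedding scored against known group labels
(adjusted Rand index), and a Cox proportional-hazards fit on
[embedding ∥ age ∥ gender ∥ group one-hots] scored by AIC = 2k − 2 ln L̂
against a covariates-only baseline.

**Disentanglement**: latent–feature association matrix (Spearman ρ with
the |ρ| ≥ 0.1 rule; a logistic fit for binary features), the 1-or-2-factor
disentanglement rule, WSEPIN (informativeness-weighted conditional mutual
information of each latent), and normalized RMIG (gap between the two
strongest latent–feature mutual informations over the feature's entropy).

**Synthetic data with ground truth** (`vaebench.synthetic`): clustered
low-rank expression (mixture of separated Gaussians in factor space times
a loading matrix plus noise), ten metadata features each driven by a known
factor through a monotone link — with the mutation signatures SBS2/SBS13
deliberately sharing one factor, as they co-occur in real tumours — and
exponential survival with factor-dependent hazard and right-censoring.
Every downstream claim is testable against this ground truth without any
download.

## Worked example

```python
import vaebench as vb
from vaebench.downstream import (embed, cluster_embedding, adjusted_rand_index,
                                 fit_cox_aic, covariates_only_baseline)

data, truth = vb.generate_dataset(seed=1)     # 600 samples x 300 genes, 6 clusters
data = vb.zscore_genes(data)

cfg = vb.HyperparameterConfig("vanilla", latent_dim=10, learning_rate=1e-3,
                              optimizer="adam", init_scheme="kaiming_uniform",
                              activation="tanh")   # the recommended setup
rec, model = vb.train_configuration(cfg, data, max_epochs=100, seed=1,
                                    return_model=True)
print(rec.status, rec.epochs_run, round(rec.final_val_loss, 2))

emb = embed(model, data)
labels = cluster_embedding(emb, seed=1)
print("ARI:", adjusted_rand_index(labels, truth.cluster_assignment))

args = (data.features["age"], data.features["gender"], data.group_label,
        data.survival_time, data.event_observed)
print("AIC embedding:", round(fit_cox_aic(emb, *args).aic, 1),
      "vs covariates only:", round(covariates_only_baseline(*args).aic, 1))
```

prints

```
converged 38 119.81
ARI: 1.0
AIC embedding: 4479.7 vs covariates only: 4493.8
```

Training stopped early at epoch 38; Leiden clustering of the 10-D
embedding recovers the six ground-truth clusters exactly (ARI 1.0), and
adding the embedding to the Cox model improves its fit over age, gender
and group alone (lower AIC), as the survival times were generated with
factor-dependent hazards the expression matrix encodes.

## The analysis pipeline

Numbered drivers under `analysis/` rerun the study end to end and write
tables under `results/`:

1. `01_simulate_dataset.py` — the synthetic panel + ground truth;
2. `02_run_benchmark_grid.py` — a desk-scale grid (all six variants,
   lr {1e-1, 1e-3} × {adam, sgd}, 3 restarts) with downstream scores per
   restart; divergent restarts (42% at lr 0.1 here) are recorded, not fatal;
3. `03_aggregate_results.py` — per-model and per-hyperparameter summaries,
   viability counts, and loss-vs-ARI/AIC Spearman correlations;
4. `04_disentanglement.py` — association matrices, WSEPIN and RMIG per
   variant at the recommended configuration, with the ground-truth factors
   as reference.

The same pipeline is scriptable through the `vaebench` CLI
(`simulate`, `benchmark --config`, `aggregate`, `evaluate-embedding`);
`vaebench example-config` prints a fully documented YAML configuration.

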
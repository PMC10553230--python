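# Methods

## Scope and model

The package benchmarks six VAE objectives on a samples × genes real-valued
expression matrix (assumed log-scale, batch-corrected upstream). All
variants share one architecture — encoder `input → 512 → d` with two
linear heads for the posterior mean and log-variance (a single logits head
for the categorical variant), decoder `d → 512 → input` with a linear
output layer since inputs are z-scored — and one reconstruction term:
squared error summed over genes, averaged over the batch. That is the
log-likelihood of a Gaussian decoder with fixed unit variance up to
constants; summing over genes (rather than averaging) keeps the
reconstruction/KL balance of the ELBO. A `kl_weight` factor
(default `batch_size / n_train` during training) rescales the KL side the
same way per-batch objectives in common VAE implementations do.

### The six objectives

- **vanilla**: reconstruction + `kl_weight · D_KL(q(z|x) ‖ N(0, I))`,
  with the diagonal-Gaussian closed form
  `½ Σ_j (exp(s_j) + μ_j² − 1 − s_j)`, `s = log σ²`.
- **β-VAE**: the KL term multiplied by β (default 4). β = 1 reproduces the
  vanilla loss bit-exactly (tested).
- **β-TCVAE**: the KL estimate decomposed into index-code mutual
  information (weight α, default 1), total correlation (β, default 6) and
  dimension-wise KL (γ, default 1). The aggregate posterior `q(z)` and its
  marginals are estimated with minibatch weighted sampling: for a batch of
  size B from a dataset of size N,
  `log q(z_i) ≈ logsumexp_j log q(z_i|x_j) − log(B·N)`, and likewise per
  dimension. The three terms telescope to the single-sample KL estimate,
  so at α = β = γ = 1 their sum is an unbiased estimator of the batch-mean
  analytic KL — the decomposition is tested against that identity within
  Monte-Carlo error. With one latent dimension the total-correlation term
  is identically zero (joint = product of marginals).
- **DIP-VAE-II**: vanilla plus
  `λ_od Σ_{i≠j} Cov[z]²_ij + λ_d Σ_i (Cov[z]_ii − 1)²` where
  `Cov[z]` is the batch (population) covariance of the posterior means
  plus the mean encoder variance on the diagonal. Defaults λ_d = 10,
  λ_od = 5.
- **IWAE**: `−E[logsumexp_k(log w_k) − log K]` with
  `w_k = p(x|z_k) p(z_k) / q(z_k|x)` and K = 5 draws by default, computed
  in log space. The likelihood p(x|z) is the same unit-variance Gaussian
  as the MSE choice, so the bound is on the same scale as the other
  losses. K = 1 equals the single-draw ELBO estimate exactly.
- **CAT-VAE**: `latent_dim` counts categorical variables, each with 10
  categories (a fixed design constant; the grid's latent-dimension axis
  then still controls capacity). Sampling uses the Gumbel-softmax
  relaxation at fixed temperature 0.5 (no annealing, for determinism);
  the unlabeled objective is reconstruction + Σ_vars KL(softmax(logits) ‖
  uniform) in closed form. The downstream embedding is the flattened
  category-probability vector.

Weight initializations: `normal01` ~ N(0,1), `uniform01` ~ U(0,1) (both
deliberately naive grid points), `xavier_normal` / `xavier_uniform`
(fan_in+fan_out scaling), and `kaiming_uniform` with the leaky-relu gain
a = √5 — bound `1/√fan_in` — matching the default linear-layer
initialization of the major deep-learning framework. Biases start at zero.

### Numerical core

No GPU framework is required: `vaebench.autodiff` is a small tape-based
reverse-mode engine over numpy (broadcasting-aware, with matmul, the usual
elementwise ops, reductions and a stable log-sum-exp). Gradients of every
composed pattern the losses use are tested against central finite
differences at 1e-7 tolerance. Losses are written once against a
type-dispatching functional layer, so the identical code runs
differentiably on tensors and as plain numpy in tests and metrics.

## Training protocol

Grid: Cartesian product over (model, latent_dim, learning_rate, optimizer,
init_scheme, activation) in that axis precedence, each axis in declared
order — 1,080 per model, 6,480 for all six. Splits are 70/30 stratified by
group label, re-drawn per restart together with the weight initialization
(seed = base_seed + restart). Optimizers use the standard defaults
(Adam β₁ = 0.9, β₂ = 0.999; RMSprop α = 0.99; ε = 1e-8). Batch size is a
free protocol constant, default 128, recorded in every training record.

Early stopping: training halts when the validation loss (the same
composite objective as training, evaluated full-batch) has gone `patience`
consecutive epochs (default 3, min_delta 0) without strictly improving on
the best value — e.g. the sequence (5, 4, 4, 4, 4) stops after epoch 5 —
or at `max_epochs` (default 1,000).

Failure detection: every batch checks the loss, the gradients and the
updated weights for non-finite values; the first hit ends the restart with
status `failed` and no loss values. Summaries (mean and sample sd of the
final validation loss) pool converged restarts only; a configuration is
failed overall only if all restarts failed. This separates viability
accounting from performance statistics.

## Preprocessing

Gene filtering keeps the top-k genes by mean absolute deviation — read
literally as the mean of |x − mean| (a `kind="median"` switch offers the
median-absolute-deviation reading, since the field uses the acronym both
ways). Ranking is descending with ties broken by gene identifier.
Z-scoring uses the population standard deviation by default (`ddof`
exposed), errors on constant genes, and is computed on the matrix as
given — any count normalization or log transform is assumed done upstream.

## Downstream evaluation

Clustering: the embedding of the whole dataset (deterministic posterior
means; flattened probabilities for CAT-VAE) is turned into a
15-nearest-neighbour graph under Euclidean distance (ties by sample
index), symmetrized, and partitioned by Leiden at resolution 1.0 with a
fixed seed; agreement with group labels is the adjusted Rand index.

Survival: Cox proportional hazards on [embedding ∥ age ∥ gender one-hot ∥
group one-hot], one reference level dropped per categorical covariate,
Efron handling of tied event times. AIC = 2k − 2 ln L̂ with k the number
of estimated coefficients; the identity is asserted to 1e-9 on every fit.
Covariate columns that are (near-)constant or linearly dependent are
dropped deterministically by pivoted QR on the centered, column-normalized
design (pivot threshold 1e-6); this matters in practice because the
categorical variant's probability blocks each sum to one and can span the
group indicators. If the Hessian is still effectively singular
(quasi-separating embedding columns), the fit retries with damped Newton
steps and then with a ridge penalty (1e-6, last resort 1e-3) far below the
likelihood scale.

## Disentanglement metrics

Association matrix: Spearman ρ of every latent with every numeric feature,
flagged at |ρ| ≥ 0.1 — a threshold on effect magnitude, approximately the
α = 0.05 significance cut at n ≈ 400. For the binary feature (gender) a
univariate logistic regression per latent provides the test (slope
p < 0.05) and the point-biserial correlation provides the magnitude, which
must also reach the same 0.1 threshold. Using the p-value alone would make
the rule sample-size-dependent (at n = 10⁴ it flags |r| ≈ 0.02), so the
magnitude guard keeps the binary and numeric rules on one scale. A feature
is *encoded* if ≥ 1 latent is flagged, *disentangled* if exactly 1 or 2
are.

Mutual information is a plug-in estimate on equal-frequency (quantile)
bins, 20 by default; variables with ≤ 20 distinct values are used as-is.
The bin count is the largest source of metric variance and is exposed
everywhere. Calibration is tested on a ρ = 0.8 bivariate Gaussian against
−½ ln(1 − ρ²) and on permutation nulls.

Normalized RMIG per feature: the two largest latent–feature MIs, their
gap divided by the feature's entropy under the same binning, clipped to
[0, 1]. It is exactly 0 when the two strongest latents are copies and ≈ 1
when one latent is a relabeling of a discrete feature; invariant to
monotone transforms of the latents.

WSEPIN: the sample index plays the role of the data variable x. For a
latent subset S, `I(x, z_S) = E_i[log q(z_S|x_i) − log q(z_S)]` with the
aggregate `q(z_S)` a uniform mixture of per-sample posteriors over a
subsample (default 400) and a small number of Monte-Carlo draws (default
4, seeded). Conditional informativeness is `I(x, z) − I(x, z_≠i)`; weights
ρ_i normalize the per-latent informativeness to sum to one, and
WSEPIN = Σ ρ_i · I(x, z_i | z_≠i). Deterministic embeddings (no encoder
variances) are smoothed with an isotropic Gaussian of sd 0.1. Two known
properties of this estimator family: (i) exact duplicate latents retain a
small positive conditional-information floor (the smoothing noise makes
copies non-identical), so the redundant-latent limit is "small relative to
independent factors", not exactly zero; (ii) once every latent is
informative enough to identify each sample, `I(x, z_≠i)` saturates at
log n and conditional information — hence WSEPIN — collapses toward zero.
The collapse is a property of the metric in high-dimensional informative
latent spaces, and it is visible in the analysis pipeline's own tables.

## Synthetic data

The generator emulates the structure the analysis assumes of a pan-cancer
or multi-tissue expression panel:

- latent factors: a mixture of `n_clusters` unit-covariance Gaussians
  whose means sit on scaled coordinate axes, pairwise `cluster_separation`
  apart (default 10, i.e. well-separated);
- expression: factors × a dense loading matrix + N(0, noise_sd²), so a
  linear probe recovers the loadings exactly at zero noise (tested);
- metadata: ten features, each a monotone function of exactly one factor
  plus noise — age and immune infiltration linear, days-to-metastasis
  exponential (skewed, positive), gender Bernoulli(logistic(factor)), six
  SBS mutation-signature activities linear, with SBS2 and SBS13 sharing a
  factor to model the co-occurring APOBEC signature pair — giving a
  correlated-feature test case for the 1-or-2-factor rule;
- survival: exponential with rate `base_rate · exp(h·f)` (hazard on the
  age- and immune-linked factors); a `censor_frac` fraction of samples (in
  expectation) is right-censored uniformly before its event time — the
  simplest mechanism with exactly the requested expected censoring
  fraction;
- layout: with the default `d_true = 16`, the 6 cluster-offset dimensions
  and the 9 feature-driving factors occupy disjoint subspaces. Overlapping
  them (small `d_true`) makes cluster membership induce cross-factor
  correlations of ~0.17, which contaminates every feature's association
  row; the minimum `d_true` is the number of features (10), where partial
  overlap returns and is the caller's informed choice.

What it does **not** emulate: RNA-seq count noise (negative binomial),
library-size or batch effects, gene–gene correlation beyond the low-rank
factor structure, non-proportional hazards, or informative censoring
beyond the uniform mechanism. Tests passing on this generator therefore
validate the pipeline's logic and its recovery behavior under the stated
generative assumptions — not performance on real panels.

## Problem sizes

The default study conditions are 600 samples × 300 genes with 6 clusters
and 30% censoring; the end-to-end check trains the recommended
configuration (Adam, lr 1e-3, Kaiming uniform, tanh, 10 latents) for at
most 100 epochs. Metric calibrations use n = 5,000–10,000 where estimator
bias demands it; the estimator-identity checks use small fixed posteriors
with hundreds of resamples. These sizes are the package's chosen test
conditions — large enough for the stochastic tolerances used, small
enough to run everywhere.

## Known limitations

- The 512-unit hidden layer is a protocol constant, not a tuned choice;
  varying it is out of scope.
- The β-TCVAE estimator uses minibatch weighted sampling only; the
  stratified-sampling alternative is not implemented.
- Per-variant disentanglement weights (β, α, γ, λ, K, temperature) are
  held at documented defaults and are not grid axes.
- The WSEPIN/RMIG values depend on the binning and smoothing constants;
  orderings and limiting behavior are stable, absolute values are not
  comparable across estimator settings.
- lifelines' ridge fallback slightly perturbs coefficients for
  quasi-separated designs; the reported log-likelihood remains the
  unpenalized partial likelihood at the fitted coefficients.
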
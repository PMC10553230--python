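"""Six variational-autoencoder variants sharing one fixed architecture.

Architecture (held fixed across the whole benchmark): encoder and decoder
are each two fully-connected layers, input -> 512 -> latent for the encoder
(two linear heads produce the posterior mean and log-variance) and
latent -> 512 -> input for the decoder, with a linear output layer since
inputs are z-scored reals.

Variants and their objectives (all share the same reconstruction term:
squared error summed over genes, averaged over the batch — a Gaussian
decoder with fixed unit variance, constants dropped):

- vanilla:    negative ELBO, reconstruction + KL(q(z|x) || N(0, I)).
- beta_vae:   KL term multiplied by beta (> 1 encourages disentanglement).
- beta_tcvae: KL decomposed into index-code mutual information (alpha),
  total correlation (beta) and dimension-wise KL (gamma), estimated with
  the minibatch-weighted-sampling estimator (needs the dataset size).
- dip_vae:    DIP-VAE-II — penalizes squared deviations of the aggregate
  posterior covariance (batch covariance of mu plus mean encoder variance
  on the diagonal) from the identity.
- iwae:       K-sample importance-weighted bound, computed with
  log-sum-exp; tighter than the ELBO for K > 1.
- cat_vae:    categorical latents via Gumbel-softmax relaxation; the
  unlabeled objective is reconstruction + KL(q(y|x) || uniform). Here
  `latent_dim` counts categorical variables, each with `n_categories`
  categories (default 10); the downstream embedding is the flattened
  category-probability vector.

All losses are finite on finite inputs; a non-finite loss signals training
failure and is handled by the trainer, never silently clipped here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "VARIANTS",
    "INIT_SCHEMES",
    "ACTIVATIONS",
    "DEFAULT_VARIANT_WEIGHTS",
    "ModelSpec",
    "LossBreakdown",
    "VAEModel",
    "init_weights",
    "gaussian_kl",
    "reparameterize",
    "mse_reconstruction",
    "vanilla_loss",
    "beta_vae_loss",
    "btcvae_loss",
    "dipvae_loss",
    "dip_penalty_from_cov",
    "iwae_loss",
    "single_draw_elbo",
    "gumbel_softmax_sample",
    "categorical_kl_from_probs",
    "catvae_loss",
]

VARIANTS = ("vanilla", "beta_vae", "beta_tcvae", "dip_vae", "iwae", "cat_vae")
INIT_SCHEMES = ("normal01", "uniform01", "xavier_normal", "xavier_uniform", "kaiming_uniform")
ACTIVATIONS = ("relu", "tanh")

LOG2PI = math.log(2.0 * math.pi)

# weights of the variant-specific loss terms, held constant across the grid
DEFAULT_VARIANT_WEIGHTS = {
    "beta": 4.0,        # beta_vae KL multiplier
    "btc_alpha": 1.0,   # beta_tcvae mutual-information weight
    "btc_beta": 6.0,    # beta_tcvae total-correlation weight
    "btc_gamma": 1.0,   # beta_tcvae dimension-wise KL weight
    "lambda_d": 10.0,   # dip_vae diagonal penalty
    "lambda_od": 5.0,   # dip_vae off-diagonal penalty
    "K": 5,             # iwae importance samples
    "temperature": 0.5, # cat_vae Gumbel-softmax temperature (fixed, no annealing)
}


# --------------------------------------------------------------------------
# weight initialization
# --------------------------------------------------------------------------

def init_weights(layer_shapes, scheme: str, seed: int) -> list[np.ndarray]:
    """Draw weight matrices for the given (fan_in, fan_out) shapes.

    normal01 / uniform01 draw i.i.d. from N(0,1) / U(0,1); the Xavier
    variants scale by fan_in+fan_out; kaiming_uniform uses the fan_in-based
    bound with leaky-relu gain a = sqrt(5) (bound 1/sqrt(fan_in)), the
    common deep-learning-framework default for linear layers. Deterministic
    given the seed.
    """
    if scheme not in INIT_SCHEMES:
        raise ValueError(f"unknown init scheme {scheme!r}; choose from {INIT_SCHEMES}")
    rng = np.random.default_rng(seed)
    out = []
    for fan_in, fan_out in layer_shapes:
        if scheme == "normal01":
            w = rng.standard_normal((fan_in, fan_out))
        elif scheme == "uniform01":
            w = rng.random((fan_in, fan_out))
        elif scheme == "xavier_normal":
            w = rng.normal(0.0, math.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out))
        elif scheme == "xavier_uniform":
            b = math.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-b, b, (fan_in, fan_out))
        else:  # kaiming_uniform with leaky-relu gain a=sqrt(5):
            # bound = sqrt(6 * gain^2 / fan_in), gain^2 = 2/(1+a^2) = 1/3
            b = 1.0 / math.sqrt(fan_in)
            w = rng.uniform(-b, b, (fan_in, fan_out))
        out.append(w)
    return out


def xavier_uniform_bound(fan_in: int, fan_out: int) -> float:
    return math.sqrt(6.0 / (fan_in + fan_out))


# --------------------------------------------------------------------------
# loss primitives (type-dispatching: numpy arrays or autodiff Tensors)
# --------------------------------------------------------------------------

def gaussian_kl(mu, log_var):
    """KL( N(mu, diag(exp(log_var))) || N(0, I) ), closed form.

    1-D inputs give a scalar; 2-D (batch, latent) inputs give one value per
    row (summed over the latent axis).
    """
    return 0.5 * ad.tsum(ad.exp(log_var) + ad.square(mu) - 1.0 - log_var, axis=-1)


def reparameterize(mu, log_var, noise):
    """z = mu + exp(log_var / 2) * noise, the pathwise gradient estimator."""
    return mu + ad.exp(log_var * 0.5) * noise


def mse_reconstruction(x, x_hat):
    """Squared error summed over genes, averaged over the batch."""
    sq = ad.square(x - x_hat)
    if ad.value_of(x).ndim == 1:
        return ad.tsum(sq)
    return ad.tmean(ad.tsum(sq, axis=1))


@dataclass
class LossBreakdown:
    """A loss value decomposed into named terms (floats or Tensors).

    Unused terms are None. For vanilla and beta_vae,
    total == reconstruction + weight * kl exactly.
    """

    total: object
    reconstruction: object
    kl: object = None
    mi_term: object = None
    tc_term: object = None
    dim_kl_term: object = None
    dip_penalty: object = None

    def floats(self) -> dict[str, float]:
        out = {}
        for name in ("total", "reconstruction", "kl", "mi_term", "tc_term",
                     "dim_kl_term", "dip_penalty"):
            v = getattr(self, name)
            if v is not None:
                out[name] = ad.as_float(v)
        return out


def vanilla_loss(x, x_hat, mu, log_var, kl_weight: float = 1.0) -> LossBreakdown:
    """Negative ELBO: reconstruction + kl_weight * batch-mean KL."""
    recon = mse_reconstruction(x, x_hat)
    kl = ad.tmean(gaussian_kl(mu, log_var))
    return LossBreakdown(total=recon + kl_weight * kl, reconstruction=recon, kl=kl)


def beta_vae_loss(x, x_hat, mu, log_var, beta: float, kl_weight: float = 1.0) -> LossBreakdown:
    """As the vanilla loss with the KL term multiplied by beta."""
    if not beta >= 0:
        raise ValueError("beta must be non-negative")
    recon = mse_reconstruction(x, x_hat)
    kl = ad.tmean(gaussian_kl(mu, log_var))
    return LossBreakdown(total=recon + kl_weight * (beta * kl), reconstruction=recon, kl=kl)


def _log_normal(z, mu, log_var):
    """Elementwise log N(z; mu, exp(log_var)); broadcasts."""
    return -0.5 * (ad.square(z - mu) * ad.exp(-1.0 * log_var) + log_var + LOG2PI)


def btcvae_loss(x, x_hat, mu, log_var, z_sample, alpha: float, beta: float,
                gamma: float, dataset_size: int) -> LossBreakdown:
    """KL decomposition with the minibatch-weighted-sampling estimator.

    The single-sample KL estimate splits (telescopes) into index-code
    mutual information E[log q(z|x) - log q(z)], total correlation
    E[log q(z) - log prod_j q(z_j)] and dimension-wise KL
    E[log prod_j q(z_j) - log p(z)]. The aggregate posterior q(z) and its
    marginals are estimated from the minibatch with importance weights
    1/(batch_size * dataset_size), which is why `dataset_size` is required.
    """
    B = ad.value_of(mu).shape[0]
    if B < 2:
        raise ValueError("beta-TCVAE needs batch size >= 2 to estimate the aggregate posterior")
    if dataset_size < B:
        raise ValueError("dataset_size must be >= batch size")
    D = ad.value_of(mu).shape[1]
    recon = mse_reconstruction(x, x_hat)

    z = z_sample
    log_qzx = ad.tsum(_log_normal(z, mu, log_var), axis=1)  # (B,)
    # pairwise matrix: log q(z_i^(d) | x_j)
    z3 = z.reshape(B, 1, D) if isinstance(z, Tensor) else ad.value_of(z).reshape(B, 1, D)
    mu3 = mu.reshape(1, B, D) if isinstance(mu, Tensor) else ad.value_of(mu).reshape(1, B, D)
    lv3 = log_var.reshape(1, B, D) if isinstance(log_var, Tensor) else ad.value_of(log_var).reshape(1, B, D)
    mat = _log_normal(z3, mu3, lv3)  # (B, B, D)
    log_norm = math.log(B * dataset_size)
    log_qz = ad.logsumexp(ad.tsum(mat, axis=2), axis=1) - log_norm           # (B,)
    log_qz_prod = ad.tsum(ad.logsumexp(mat, axis=1) - log_norm, axis=1)      # (B,)
    log_pz = ad.tsum(-0.5 * (ad.square(z) + LOG2PI), axis=1)

    mi = ad.tmean(log_qzx - log_qz)
    tc = ad.tmean(log_qz - log_qz_prod)
    dim_kl = ad.tmean(log_qz_prod - log_pz)
    total = recon + alpha * mi + beta * tc + gamma * dim_kl
    return LossBreakdown(total=total, reconstruction=recon,
                         mi_term=mi, tc_term=tc, dim_kl_term=dim_kl)


def dip_penalty_from_cov(cov, lambda_d: float, lambda_od: float):
    """DIP-VAE-II penalty from an aggregate-posterior covariance matrix.

    lambda_od * sum_{i != j} Cov_ij^2 + lambda_d * sum_i (Cov_ii - 1)^2.
    """
    D = ad.value_of(cov).shape[0]
    eye = np.eye(D)
    off = ad.tsum(ad.square(cov * (1.0 - eye)))
    diag = ad.tsum(ad.square((cov * eye).sum(axis=1) - 1.0)) if isinstance(cov, Tensor) \
        else np.sum((np.diag(ad.value_of(cov)) - 1.0) ** 2)
    return lambda_od * off + lambda_d * diag


def dipvae_loss(x, x_hat, mu, log_var, lambda_d: float, lambda_od: float,
                kl_weight: float = 1.0) -> LossBreakdown:
    """Vanilla loss plus the DIP-VAE-II covariance penalty.

    Cov_q(z)[z] is estimated over the batch as the (population) covariance
    of the posterior means plus the mean encoder variance on the diagonal.
    """
    B = ad.value_of(mu).shape[0]
    if B < 2:
        raise ValueError("DIP-VAE needs batch size >= 2 to estimate the latent covariance")
    base = vanilla_loss(x, x_hat, mu, log_var, kl_weight=kl_weight)
    mu_c = mu - ad.tmean(mu, axis=0, keepdims=True)
    cov_mu = (mu_c.T @ mu_c) * (1.0 / B) if isinstance(mu, Tensor) \
        else (ad.value_of(mu_c).T @ ad.value_of(mu_c)) / B
    D = ad.value_of(mu).shape[1]
    mean_var = ad.tmean(ad.exp(log_var), axis=0)
    cov = cov_mu + np.eye(D) * mean_var
    penalty = dip_penalty_from_cov(cov, lambda_d, lambda_od)
    return LossBreakdown(total=base.total + penalty, reconstruction=base.reconstruction,
                         kl=base.kl, dip_penalty=penalty)


def _gaussian_loglik(x, x_hat, axis=-1):
    """log p(x | z) for a unit-variance Gaussian decoder (with constants)."""
    return -0.5 * ad.tsum(ad.square(x - x_hat) + LOG2PI, axis=axis)


def iwae_loss(x, decoder, mu, log_var, K: int, noise_draws):
    """K-sample importance-weighted bound (negated), via log-sum-exp.

    `decoder` maps a (n, latent) array/Tensor of latent samples to
    reconstructions; `noise_draws` is (batch, K, latent) standard normal.
    Returns the batch mean of -[logsumexp_k(log w_k) - log K].
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    B, D = ad.value_of(mu).shape
    noise = noise_draws if isinstance(noise_draws, Tensor) else np.asarray(noise_draws, dtype=float)
    assert ad.value_of(noise).shape == (B, K, D)
    mu3 = mu.reshape(B, 1, D) if isinstance(mu, Tensor) else ad.value_of(mu).reshape(B, 1, D)
    lv3 = log_var.reshape(B, 1, D) if isinstance(log_var, Tensor) else ad.value_of(log_var).reshape(B, 1, D)
    z = mu3 + ad.exp(lv3 * 0.5) * noise  # (B, K, D)
    z_flat = z.reshape(B * K, D)
    x_hat = decoder(z_flat)
    G = ad.value_of(x).shape[-1]
    x3 = x.reshape(B, 1, G) if isinstance(x, Tensor) else ad.value_of(x).reshape(B, 1, G)
    xh3 = x_hat.reshape(B, K, G)
    log_px_z = _gaussian_loglik(x3, xh3, axis=2)                     # (B, K)
    log_pz = ad.tsum(-0.5 * (ad.square(z) + LOG2PI), axis=2)         # (B, K)
    log_qz = ad.tsum(_log_normal(z, mu3, lv3), axis=2)               # (B, K)
    log_w = log_px_z + log_pz - log_qz
    bound = ad.logsumexp(log_w, axis=1) - math.log(K)
    return -1.0 * ad.tmean(bound)


def single_draw_elbo(x, decoder, mu, log_var, noise):
    """Single-sample negative-ELBO estimate on one fixed noise draw.

    Independent of the importance-weighted path: no log-sum-exp involved.
    """
    z = reparameterize(mu, log_var, noise)
    x_hat = decoder(z)
    log_px_z = _gaussian_loglik(x, x_hat, axis=-1)
    log_pz = ad.tsum(-0.5 * (ad.square(z) + LOG2PI), axis=-1)
    log_qz = ad.tsum(_log_normal(z, mu, log_var), axis=-1)
    return -1.0 * ad.tmean(log_px_z + log_pz - log_qz)


def gumbel_softmax_sample(logits, temperature: float, uniform_noise):
    """Relaxed one-hot samples: softmax((logits + Gumbel noise)/temperature).

    `uniform_noise` in (0,1) with the shape of logits; the Gumbel draws are
    -log(-log(u)). Rows (last axis) sum to 1.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    u = uniform_noise
    g = -1.0 * ad.log(-1.0 * ad.log(u))
    return ad.softmax((logits + g) * (1.0 / temperature), axis=-1)


def categorical_kl_from_probs(p: np.ndarray, n_categories: int | None = None) -> float:
    """Closed-form KL(Categorical(p) || uniform) = sum_c p_c log(p_c * C)."""
    p = np.asarray(p, dtype=float)
    C = p.shape[-1] if n_categories is None else n_categories
    return float(np.sum(xlogy(p, p * C)))


def catvae_loss(x, x_hat, logits, temperature: float = 0.5) -> LossBreakdown:
    """Unlabeled categorical-VAE objective.

    reconstruction + sum over categorical variables of
    KL(softmax(logits) || uniform); `temperature` only affects the sampling
    path, not the KL, and is carried for the record.
    """
    recon = mse_reconstruction(x, x_hat)
    C = ad.value_of(logits).shape[-1]
    log_p = logits - ad.logsumexp(logits, axis=-1, keepdims=True)
    p = ad.exp(log_p)
    kl_el = p * (log_p + math.log(C))
    if ad.value_of(logits).ndim == 3:  # (batch, variables, categories)
        kl = ad.tmean(ad.tsum(ad.tsum(kl_el, axis=2), axis=1))
    else:
        kl = ad.tsum(kl_el)
    return LossBreakdown(total=recon + kl, reconstruction=recon, kl=kl)


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Configuration of one VAE instance (architecture + variant weights)."""

    variant: str
    input_dim: int
    latent_dim: int
    activation: str = "tanh"
    init_scheme: str = "kaiming_uniform"
    hidden_dim: int = 512
    n_categories: int = 10  # cat_vae only
    variant_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        w = dict(DEFAULT_VARIANT_WEIGHTS)
        w.update(self.variant_weights)
        self.variant_weights = w

    @property
    def embedding_dim(self) -> int:
        if self.variant == "cat_vae":
            return self.latent_dim * self.n_categories
        return self.latent_dim


class VAEModel:
    """One instantiated VAE: parameters, forward passes and loss."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        d_in, h, d_z = spec.input_dim, spec.hidden_dim, spec.latent_dim
        enc_out = d_z * spec.n_categories if spec.variant == "cat_vae" else d_z
        dec_in = spec.embedding_dim
        shapes = [(d_in, h)]
        if spec.variant == "cat_vae":
            shapes.append((h, enc_out))
        else:
            shapes += [(h, d_z), (h, d_z)]
        shapes += [(dec_in, h), (h, d_in)]
        weights = init_weights(shapes, spec.init_scheme, seed)
        names = ["W_e1"] + (["W_head"] if spec.variant == "cat_vae" else ["W_mu", "W_lv"]) + ["W_d1", "W_d2"]
        self.params: dict[str, Tensor] = {}
        for name, w in zip(names, weights):
            self.params[name] = Tensor(w, requires_grad=True)
            self.params[name.replace("W", "b")] = Tensor(
                np.zeros(w.shape[1]), requires_grad=True
            )

    # ---- forward ---------------------------------------------------------
    def _act(self, x):
        return ad.tanh(x) if self.spec.activation == "tanh" else ad.relu(x)

    def encode(self, x):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        p = self.params
        h = self._act(x @ p["W_e1"] + p["b_e1"])
        if self.spec.variant == "cat_vae":
            logits = h @ p["W_head"] + p["b_head"]
            B = ad.value_of(logits).shape[0]
            return logits.reshape(B, self.spec.latent_dim, self.spec.n_categories)
        mu = h @ p["W_mu"] + p["b_mu"]
        log_var = h @ p["W_lv"] + p["b_lv"]
        return mu, log_var

    def decode(self, z):
        z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
        p = self.params
        h = self._act(z @ p["W_d1"] + p["b_d1"])
        return h @ p["W_d2"] + p["b_d2"]

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Deterministic embedding: posterior mean (Gaussian variants) or
        flattened category probabilities (cat_vae). No sampling involved."""
        X = np.asarray(X, dtype=float)
        if self.spec.variant == "cat_vae":
            logits = ad.value_of(self.encode(X))
            probs = ad.softmax(logits, axis=-1)
            return probs.reshape(X.shape[0], -1)
        mu, _ = self.encode(X)
        return ad.value_of(mu).copy()

    # ---- loss ------------------------------------------------------------
    def loss(self, x_batch, rng: np.random.Generator, dataset_size: int,
             kl_weight: float = 1.0) -> LossBreakdown:
        """Differentiable loss of one minibatch (Tensor inputs/outputs)."""
        spec = self.spec
        x = x_batch if isinstance(x_batch, Tensor) else Tensor(np.asarray(x_batch, dtype=float))
        B = x.shape[0]
        w = spec.variant_weights
        if spec.variant == "cat_vae":
            logits = self.encode(x)
            u = rng.random(ad.value_of(logits).shape)
            u = np.clip(u, 1e-12, 1.0 - 1e-12)
            y = gumbel_softmax_sample(logits, w["temperature"], u)
            y_flat = y.reshape(B, spec.embedding_dim)
            x_hat = self.decode(y_flat)
            return catvae_loss(x, x_hat, logits, w["temperature"])
        mu, log_var = self.encode(x)
        if spec.variant == "iwae":
            K = int(w["K"])
            noise = rng.standard_normal((B, K, spec.latent_dim))
            total = iwae_loss(x, self.decode, mu, log_var, K, noise)
            return LossBreakdown(total=total, reconstruction=None)
        noise = rng.standard_normal((B, spec.latent_dim))
        z = reparameterize(mu, log_var, noise)
        x_hat = self.decode(z)
        if spec.variant == "vanilla":
            return vanilla_loss(x, x_hat, mu, log_var, kl_weight=kl_weight)
        if spec.variant == "beta_vae":
            return beta_vae_loss(x, x_hat, mu, log_var, beta=w["beta"], kl_weight=kl_weight)
        if spec.variant == "beta_tcvae":
            return btcvae_loss(x, x_hat, mu, log_var, z,
                               alpha=w["btc_alpha"], beta=w["btc_beta"],
                               gamma=w["btc_gamma"], dataset_size=dataset_size)
        if spec.variant == "dip_vae":
            return dipvae_loss(x, x_hat, mu, log_var,
                               lambda_d=w["lambda_d"], lambda_od=w["lambda_od"],
                               kl_weight=kl_weight)
        raise AssertionError(spec.variant)

    # ---- bookkeeping -----------------------------------------------------
    def zero_grad(self):
        for t in self.params.values():
            t.zero_grad()

    def all_finite(self) -> bool:
        return all(np.all(np.isfinite(t.value)) for t in self.params.values())

    def grads_finite(self) -> bool:
        return all(t.grad is None or np.all(np.isfinite(t.grad)) for t in self.params.values())

    def save(self, path) -> None:
        """Checkpoint as a delimited-text bundle (one section per array)."""
        with open(path, "w") as fh:
            fh.write(f"# variant={self.spec.variant} input_dim={self.spec.input_dim} "
                     f"latent_dim={self.spec.latent_dim} hidden_dim={self.spec.hidden_dim} "
                     f"activation={self.spec.activation} n_categories={self.spec.n_categories}\n")
            for name, t in self.params.items():
                arr = np.atleast_2d(t.value)
                fh.write(f">{name} {t.value.ndim} {' '.join(map(str, t.value.shape))}\n")
                np.savetxt(fh, arr, delimiter="\t")

    @classmethod
    def load(cls, path, spec: ModelSpec) -> "VAEModel":
        model = cls(spec, seed=0)
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 1
        while i < len(lines):
            header = lines[i]
            assert header.startswith(">")
            parts = header[1:].split()
            name, ndim = parts[0], int(parts[1])
            shape = tuple(int(s) for s in parts[2:])
            nrows = 1 if ndim == 1 else shape[0]
            block = np.loadtxt(lines[i + 1: i + 1 + nrows], delimiter="\t", ndmin=2)
            model.params[name] = Tensor(block.reshape(shape), requires_grad=True)
            i += 1 + nrows
        return model
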
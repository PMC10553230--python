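"""Latent-space disentanglement metrics.

Three views of how latent factors relate to per-sample metadata features:

1. Association matrix — Spearman correlation of each latent factor with
   each numeric feature (threshold |rho| >= 0.1, roughly the alpha = 0.05
   significance level at the benchmark's sample sizes); binary features
   (gender) use a univariate logistic model per factor, significant at
   p < 0.05. A feature is *encoded* when at least one factor is
   significant and *disentangled* when exactly one or two are.

2. WSEPIN — weighted separability-and-informativeness. With the sample
   index playing the role of the data variable x, I(x, z_i) is the
   informativeness of latent i and I(x, z_i | z_{!=i}) its separable
   (unique) information; WSEPIN = sum_i rho_i * I(x, z_i | z_{!=i}) with
   weights rho_i = I(x, z_i) / sum_j I(x, z_j). Both quantities are
   Monte-Carlo estimates from the encoder posteriors: the aggregate
   posterior is a uniform mixture of per-sample posteriors over a
   subsample, and I(x, z_S) = E_i[log q(z_S|x_i) - log q(z_S)].

3. Normalized RMIG — robust mutual-information gap per feature: the
   difference between the two largest latent-feature mutual informations,
   divided by the feature's (binned) entropy, clipped to [0, 1].

Mutual information is estimated with a plug-in estimate on equal-frequency
(quantile) bins, 20 by default — deterministic and adequate for ranking;
the bin count is the largest source of metric variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import logsumexp
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import mutual_info_score

__all__ = [
    "AssociationMatrix",
    "DisentanglementReport",
    "spearman_rho",
    "logit_association",
    "association_matrix",
    "count_disentangled",
    "estimate_mi",
    "binned_entropy",
    "wsepin",
    "rmig_normalized",
    "disentanglement_report",
]


# --------------------------------------------------------------------------
# association matrix and the 1-or-2-factor rule
# --------------------------------------------------------------------------

def spearman_rho(z_i, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Constant input makes the correlation undefined; returned as 0 with a
    warning so downstream thresholding treats the pair as unassociated.
    """
    z_i = np.asarray(z_i, dtype=float)
    y = np.asarray(y, dtype=float)
    if z_i.shape != y.shape or z_i.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if z_i.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(z_i) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined, returning 0")
        return 0.0
    rho, _ = spearmanr(z_i, y)
    return float(rho)


def logit_association(z_values: np.ndarray, binary_feature,
                      alpha: float = 0.05,
                      min_abs: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-latent association of a binary feature via univariate logistic fits.

    Returns (association values, significance flags). The reported value is
    the point-biserial correlation (signed, on the correlation scale); a
    factor counts as associated when the logistic slope is significant at
    two-sided p < alpha AND the effect magnitude reaches `min_abs` — the
    same magnitude cut as the numeric-feature rule, which keeps the flag
    meaningful at sample sizes where p < alpha alone admits negligible
    effects. A single-class feature yields all-zero associations, flagged
    not significant.
    """
    z_values = np.atleast_2d(np.asarray(z_values, dtype=float))
    y = np.asarray(binary_feature, dtype=float)
    D = z_values.shape[1]
    if np.unique(y).size < 2:
        warnings.warn("single-class binary feature: no association estimable")
        return np.zeros(D), np.zeros(D, dtype=bool)
    values = np.zeros(D)
    sig = np.zeros(D, dtype=bool)
    for i in range(D):
        zi = z_values[:, i]
        if np.ptp(zi) == 0:
            continue
        values[i] = pearsonr(zi, y)[0]  # point-biserial
        design = sm.add_constant((zi - zi.mean()) / zi.std())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            sig[i] = bool(fit.pvalues[1] < alpha)
        except Exception:
            # perfect separation: the association could not be stronger
            sig[i] = True
        sig[i] = sig[i] and abs(values[i]) >= min_abs
    return values, sig


@dataclass
class AssociationMatrix:
    """latent_dim x n_features association values with significance flags."""

    values: np.ndarray
    significant: np.ndarray
    feature_names: list[str]
    threshold: float = 0.1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if self.values.shape != self.significant.shape:
            raise ValueError("values and significance shapes differ")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")


def association_matrix(emb_values: np.ndarray, features, binary_features=("gender",),
                       threshold: float = 0.1) -> AssociationMatrix:
    """Associate every latent factor with every metadata feature.

    `features` is a DataFrame (columns = feature names). Numeric features
    use Spearman correlation thresholded at |rho| >= threshold; features
    named in `binary_features` use the logistic-fit rule instead.
    """
    emb_values = np.asarray(emb_values, dtype=float)
    D = emb_values.shape[1]
    names = list(features.columns)
    values = np.zeros((D, len(names)))
    significant = np.zeros((D, len(names)), dtype=bool)
    for j, name in enumerate(names):
        y = features[name].to_numpy(dtype=float)
        if name in binary_features:
            values[:, j], significant[:, j] = logit_association(
                emb_values, y, min_abs=threshold)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for i in range(D):
                    values[i, j] = spearman_rho(emb_values[:, i], y)
            significant[:, j] = np.abs(values[:, j]) >= threshold
    return AssociationMatrix(values=values, significant=significant,
                             feature_names=names, threshold=threshold)


def count_disentangled(assoc: AssociationMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply the 1-or-2-factor rule.

    encoded: feature significant with >= 1 factor; disentangled: with
    exactly 1 or 2 factors. Returns (encoded, disentangled, n_disentangled).
    """
    counts = assoc.significant.sum(axis=0)
    encoded = counts >= 1
    disentangled = (counts >= 1) & (counts <= 2)
    return encoded, disentangled, int(disentangled.sum())


# --------------------------------------------------------------------------
# mutual information (plug-in on quantile bins)
# --------------------------------------------------------------------------

def _discretize(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; already-discrete variables pass through."""
    v = np.asarray(v, dtype=float)
    uniq = np.unique(v)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, v)
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, v, side="right")


def estimate_mi(a, b, n_bins: int = 20) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    `a` may be a vector or a matrix (columns jointly binned into one
    discrete code); `b` must be a vector. Non-negative; symmetric for 1-D
    arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if b.ndim != 1:
        raise ValueError("b must be 1-dimensional")
    n = b.size
    if n < n_bins:
        raise ValueError(f"too few samples ({n}) for {n_bins} bins")
    if a.ndim == 1:
        code_a = _discretize(a, n_bins)
    else:
        cols = [_discretize(a[:, j], n_bins) for j in range(a.shape[1])]
        _, code_a = np.unique(np.column_stack(cols), axis=0, return_inverse=True)
    code_b = _discretize(b, n_bins)
    return float(mutual_info_score(code_a, code_b))


def binned_entropy(y, n_bins: int = 20) -> float:
    """Plug-in entropy (nats) of a feature under the same quantile binning
    as :func:`estimate_mi`, so normalized ratios are internally consistent."""
    code = _discretize(np.asarray(y, dtype=float), n_bins)
    _, counts = np.unique(code, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


# --------------------------------------------------------------------------
# WSEPIN
# --------------------------------------------------------------------------

def wsepin(posterior_means: np.ndarray, posterior_log_vars: np.ndarray | None = None,
           n_subsample: int = 400, n_mc: int = 4, seed: int = 0,
           embedding_sd: float = 0.1) -> tuple[float, np.ndarray | None]:
    """Weighted separability-and-informativeness of a latent space.

    Treats the sample index as the data variable x. For a latent subset S,
    I(x, z_S) = E_i[ log q(z_S|x_i) - log q(z_S) ] with the aggregate
    q(z_S) a uniform mixture of per-sample posteriors over a subsample;
    conditional informativeness is I(x, z) - I(x, z_{!=i}). Monte-Carlo
    over `n_mc` posterior draws, deterministic given `seed`.

    When `posterior_log_vars` is None the matrix is treated as a
    deterministic embedding smoothed with an isotropic Gaussian of sd
    `embedding_sd` (needed to make the mixture densities finite).

    Returns (wsepin, rho_weights); rho_weights is None (flagged) when no
    latent carries information.
    """
    mu = np.asarray(posterior_means, dtype=float)
    n, D = mu.shape
    if D < 2:
        raise ValueError("WSEPIN needs latent_dim >= 2")
    if posterior_log_vars is None:
        lv = np.full_like(mu, 2.0 * np.log(embedding_sd))
    else:
        lv = np.asarray(posterior_log_vars, dtype=float)
    rng = np.random.default_rng(seed)
    if n > n_subsample:
        idx = rng.choice(n, size=n_subsample, replace=False)
        mu, lv = mu[idx], lv[idx]
        n = n_subsample
    var = np.exp(lv)

    I_single = np.zeros(D)
    I_drop = np.zeros(D)
    I_full = 0.0
    for _ in range(n_mc):
        z = mu + np.sqrt(var) * rng.standard_normal((n, D))
        # mat[i, j, d] = log N(z_i^d ; mu_j^d, var_j^d)
        diff = z[:, None, :] - mu[None, :, :]
        mat = -0.5 * (diff**2 / var[None, :, :] + lv[None, :, :] + np.log(2 * np.pi))
        own = np.einsum("iid->id", mat)  # log q(z_i^d | x_i)

        def info(dims) -> float:
            joint = mat[:, :, dims].sum(axis=2)
            log_qz = logsumexp(joint, axis=1) - np.log(n)
            return float(np.mean(own[:, dims].sum(axis=1) - log_qz))

        I_full += info(list(range(D)))
        for d in range(D):
            I_single[d] += info([d])
            I_drop[d] += info([k for k in range(D) if k != d])
    I_single /= n_mc
    I_drop /= n_mc
    I_full /= n_mc

    informativeness = np.maximum(I_single, 0.0)
    total = informativeness.sum()
    if total <= 0:
        return 0.0, None
    rho = informativeness / total
    conditional = np.maximum(I_full - I_drop, 0.0)
    return float(np.sum(rho * conditional)), rho


# --------------------------------------------------------------------------
# RMIG
# --------------------------------------------------------------------------

def rmig_normalized(z_values: np.ndarray, y_k, n_bins: int = 20) -> float:
    """Normalized robust mutual-information gap of one feature.

    Gap between the two largest latent-feature mutual informations,
    divided by the feature's binned entropy, clipped to [0, 1].
    """
    z_values = np.asarray(z_values, dtype=float)
    if z_values.ndim != 2 or z_values.shape[1] < 2:
        raise ValueError("need a samples x latent matrix with latent_dim >= 2")
    y = np.asarray(y_k, dtype=float)
    H = binned_entropy(y, n_bins)
    if H <= 0:
        raise ValueError("feature has zero entropy (constant); RMIG undefined")
    mi = np.array([estimate_mi(z_values[:, i], y, n_bins) for i in range(z_values.shape[1])])
    top = np.sort(mi)[::-1]
    return float(np.clip((top[0] - top[1]) / H, 0.0, 1.0))


# --------------------------------------------------------------------------
# full report
# --------------------------------------------------------------------------

@dataclass
class DisentanglementReport:
    """All disentanglement metrics of one embedding against one feature set."""

    association: AssociationMatrix
    encoded: np.ndarray
    disentangled: np.ndarray
    n_disentangled: int
    rmig_normalized: dict[str, float]
    wsepin: float
    rho_weights: np.ndarray | None

    def to_frame(self):
        import pandas as pd
        rows = []
        for j, name in enumerate(self.association.feature_names):
            rows.append({
                "feature": name,
                "encoded": bool(self.encoded[j]),
                "disentangled": bool(self.disentangled[j]),
                "n_significant_factors": int(self.association.significant[:, j].sum()),
                "rmig_normalized": self.rmig_normalized[name],
            })
        return pd.DataFrame(rows)


def disentanglement_report(emb_values: np.ndarray, features,
                           posterior_log_vars: np.ndarray | None = None,
                           binary_features=("gender",), threshold: float = 0.1,
                           n_bins: int = 20, seed: int = 0) -> DisentanglementReport:
    """Association matrix + 1-or-2-factor flags + RMIG per feature + WSEPIN."""
    assoc = association_matrix(emb_values, features,
                               binary_features=binary_features, threshold=threshold)
    encoded, disentangled, n_dis = count_disentangled(assoc)
    rmig = {}
    for name in assoc.feature_names:
        y = features[name].to_numpy(dtype=float)
        try:
            rmig[name] = rmig_normalized(emb_values, y, n_bins)
        except ValueError:
            rmig[name] = float("nan")
    score, rho = wsepin(emb_values, posterior_log_vars, seed=seed)
    return DisentanglementReport(
        association=assoc, encoded=encoded, disentangled=disentangled,
        n_disentangled=n_dis, rmig_normalized=rmig, wsepin=score, rho_weights=rho,
    )
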
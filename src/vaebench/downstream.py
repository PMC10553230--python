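"""Downstream evaluation of a trained model's embedding.

Unsupervised task: build a 15-nearest-neighbour graph (Euclidean) on the
embedding of the whole dataset, partition it with Leiden community
detection at the default resolution, and score agreement with the known
group labels by the adjusted Rand index (ARI).

Supervised task: fit a Cox proportional-hazards model on the embedding
columns plus age, one-hot gender and one-hot group label, with overall
survival as the endpoint, and report AIC = 2k - 2 ln(L-hat) where k counts
the estimated coefficients. A covariates-only baseline (no embedding
columns) provides the reference fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import kneighbors_graph

from .training import HyperparameterConfig

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "DownstreamScores",
    "embed",
    "cluster_embedding",
    "adjusted_rand_index",
    "fit_cox_aic",
    "covariates_only_baseline",
    "loss_score_correlation",
]


@dataclass
class EmbeddingMatrix:
    """Samples x embedding_dim matrix aligned with its source dataset."""

    values: np.ndarray
    sample_ids: list[str]
    source_config: HyperparameterConfig | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries; "
                             "embeddings from failed models are never produced")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match embedding rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class DownstreamScores:
    """Scores of one embedding on the two downstream tasks."""

    ari: float | None = None
    n_clusters_found: int | None = None
    aic: float | None = None
    cox_n_params: int | None = None
    cox_log_likelihood: float | None = None


def embed(model, data) -> EmbeddingMatrix:
    """Deterministic embedding of a dataset: posterior means (Gaussian
    variants) or flattened category probabilities (cat_vae)."""
    if model is None:
        raise ValueError("cannot embed with a failed (absent) model")
    values = model.embed(data.values)
    return EmbeddingMatrix(values=values, sample_ids=list(data.sample_ids))


def cluster_embedding(emb: EmbeddingMatrix, n_neighbors: int = 15,
                      seed: int = 0, resolution: float = 1.0) -> np.ndarray:
    """Leiden communities on the k-NN (Euclidean) graph of the embedding.

    The graph connects each sample to its `n_neighbors` nearest neighbours
    (ties broken by sample index, the kneighbors default); edges are made
    undirected. Deterministic given the seed.
    """
    n = emb.n_samples
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_samples={n}")
    adj = kneighbors_graph(emb.values, n_neighbors=n_neighbors,
                           mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T)  # undirected
    sources, targets = adj.nonzero()
    mask = sources < targets
    g = igraph.Graph(n=n, edges=list(zip(sources[mask], targets[mask])))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(f"label lengths differ: {labels_a.shape} vs {labels_b.shape}")
    if labels_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(labels_a, labels_b))


def _one_hot(values, prefix: str) -> pd.DataFrame:
    """One-hot encode dropping the first (reference) level."""
    s = pd.Series(np.asarray(values).astype(str))
    return pd.get_dummies(s, prefix=prefix, drop_first=True, dtype=float)


def _drop_degenerate(df: pd.DataFrame) -> pd.DataFrame:
    """Drop constant and (nearly) collinear covariate columns, logged.

    Collinearity is resolved by rank-revealing pivoted QR on the centered
    design: columns whose pivot falls below tol relative to the largest are
    linear combinations of the kept ones (e.g. the flattened category
    probabilities of a categorical latent space, which sum to 1 per
    variable). Deterministic; k shrinks accordingly.
    """
    X0 = df.to_numpy(dtype=float)
    Xc = X0 - X0.mean(axis=0)  # centering mimics the baseline-hazard intercept
    norms = np.linalg.norm(Xc, axis=0)
    # (near-)constant columns carry no information and break normalization
    const = norms <= 1e-10 * (1.0 + np.abs(X0).max(axis=0))
    if const.any():
        logger.warning("dropping constant covariate columns %r",
                       [c for c, f in zip(df.columns, const) if f])
        df = df.loc[:, ~const]
        Xc, norms = Xc[:, ~const], norms[~const]
    if df.shape[1] == 0:
        return df
    X = Xc / norms  # scale-invariant rank detection
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > 1e-6))
    independent = sorted(piv[:rank])
    dropped = [df.columns[j] for j in range(df.shape[1]) if j not in independent]
    if dropped:
        logger.warning("dropping collinear covariate columns %r", dropped)
    return df.iloc[:, independent]


def _cox_fit(design: pd.DataFrame, survival_time, event_observed) -> DownstreamScores:
    time = np.asarray(survival_time, dtype=float)
    event = np.asarray(event_observed, dtype=int)
    if event.sum() < 1:
        raise ValueError("survival fit needs at least one observed event")
    design = _drop_degenerate(design)
    if not np.all(np.isfinite(design.to_numpy())):
        raise ValueError("non-finite covariate values in Cox design matrix")
    df = design.copy()
    df["time"] = time
    df["event"] = event
    # Efron handling of event-time ties (library default). Quasi-one-hot
    # embedding columns can leave the Hessian singular even at full column
    # rank (quasi-separation); damped steps, then a ridge penalty far below
    # the likelihood scale, recover those fits.
    attempts = [
        (CoxPHFitter(), {}),
        (CoxPHFitter(), {"fit_options": {"step_size": 0.25}}),
        (CoxPHFitter(penalizer=1e-6), {"fit_options": {"step_size": 0.25}}),
        (CoxPHFitter(penalizer=1e-3), {"fit_options": {"step_size": 0.1}}),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (cph, kwargs) in enumerate(attempts):
            try:
                cph.fit(df, duration_col="time", event_col="event", **kwargs)
                break
            except Exception:
                if i == len(attempts) - 1:
                    raise
                logger.warning("Cox fit retry %d (damping/ridge)", i + 1)
    k = int(cph.params_.shape[0])
    ll = float(cph.log_likelihood_)
    return DownstreamScores(aic=2.0 * k - 2.0 * ll, cox_n_params=k,
                            cox_log_likelihood=ll)


def fit_cox_aic(emb: EmbeddingMatrix | None, age, gender, group_label,
                survival_time, event_observed) -> DownstreamScores:
    """Cox PH fit on [embedding || age || one-hot gender || one-hot group].

    Gender and group one-hot encodings drop a reference level to avoid
    collinearity with the baseline hazard. Constant or duplicated columns
    are dropped with a logged warning (k shrinks accordingly).
    """
    parts = []
    if emb is not None:
        parts.append(pd.DataFrame(
            emb.values, columns=[f"z{i}" for i in range(emb.values.shape[1])]))
    parts.append(pd.DataFrame({"age": np.asarray(age, dtype=float)}))
    parts.append(_one_hot(gender, "gender").reset_index(drop=True))
    parts.append(_one_hot(group_label, "group").reset_index(drop=True))
    design = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    return _cox_fit(design, survival_time, event_observed)


def covariates_only_baseline(age, gender, group_label, survival_time,
                             event_observed) -> DownstreamScores:
    """Cox PH fit on the covariates alone (no embedding columns)."""
    return fit_cox_aic(None, age, gender, group_label, survival_time, event_observed)


def loss_score_correlation(losses, scores) -> float:
    """Spearman correlation between validation losses and task scores
    across configurations (NaN-safe; pairs with missing values dropped)."""
    losses = np.asarray(losses, dtype=float)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(losses) & np.isfinite(scores)
    if ok.sum() < 3:
        return float("nan")
    rho, _ = spearmanr(losses[ok], scores[ok])
    return float(rho)
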
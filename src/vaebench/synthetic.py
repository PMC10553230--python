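"""Synthetic transcriptomics-like datasets with full ground truth.

Emulates the statistical structure the benchmark assumes of pan-cancer /
multi-tissue expression panels: well-separated sample clusters living in a
low-dimensional factor space, per-sample metadata features each driven by a
known generative factor through a monotone link, and survival times whose
hazard depends on the factors, with right-censoring.

Generative model
----------------
- latent factors F (n x d): mixture of `n_clusters` unit-covariance
  Gaussians whose means sit on scaled coordinate axes, pairwise separated
  by `cluster_separation` in Euclidean norm;
- expression X = F @ L + eps, with loading matrix L drawn once per seed and
  eps ~ N(0, noise_sd^2);
- features: each metadata feature is a monotone function of exactly one
  factor plus independent noise (gender is Bernoulli(logistic(factor)));
  the mutation signatures SBS2 and SBS13 deliberately share one factor, a
  known co-occurring pair, giving a correlated-feature test case;
- survival: T ~ Exponential(rate = base_rate * exp(h . f)); a fraction
  `censor_frac` of samples (in expectation) is right-censored at a uniform
  time before its event.

The defaults are the study conditions used throughout the tests and the
analysis scripts; all parameters are explicit arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset

__all__ = ["SyntheticGroundTruth", "generate_dataset", "write_ground_truth", "FEATURE_FACTOR_LINKS"]

# feature name -> (driving slot, link); slots index the LAST factors of the
# space, keeping them disjoint from the leading cluster-offset dimensions
# whenever d_true >= n_clusters + 9. SBS2 and SBS13 share slot 5 (a known
# co-occurring signature pair).
FEATURE_FACTOR_LINKS: dict[str, tuple[int, str]] = {
    "age": (0, "linear"),
    "gender": (1, "bernoulli_logistic"),
    "days_to_metastasis": (2, "exponential"),
    "immune_infiltration": (3, "linear"),
    "SBS1": (4, "linear"),
    "SBS2": (5, "linear"),
    "SBS5": (6, "linear"),
    "SBS13": (5, "linear"),
    "SBS15": (7, "linear"),
    "SBS40": (8, "linear"),
}

_N_DRIVING_FACTORS = max(i for i, _ in FEATURE_FACTOR_LINKS.values()) + 1  # 9
_N_FEATURES = len(FEATURE_FACTOR_LINKS)  # 10


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    true_factors: np.ndarray  # (n_samples, d_true)
    loading_matrix: np.ndarray  # (d_true, n_genes)
    cluster_assignment: np.ndarray  # (n_samples,) int
    feature_factor_map: dict[str, tuple[int, str]]
    hazard_coefficients: np.ndarray  # (d_true,)
    noise_sd: float
    seed: int


def _cluster_means(n_clusters: int, d: int, separation: float) -> np.ndarray:
    """Cluster means on scaled coordinate axes, pairwise `separation` apart.

    Means on distinct axes at radius r are r*sqrt(2) apart, so r is chosen
    as separation/sqrt(2). If n_clusters exceeds d the axes are reused at
    growing radii (separation then holds only approximately).
    """
    means = np.zeros((n_clusters, d))
    r = separation / np.sqrt(2.0)
    for c in range(n_clusters):
        means[c, c % d] = r * (1 + c // d)
    return means


def generate_dataset(
    n_samples: int = 600,
    n_genes: int = 300,
    n_clusters: int = 6,
    d_true: int = 16,
    cluster_separation: float = 10.0,
    noise_sd: float = 1.0,
    censor_frac: float = 0.3,
    seed: int = 0,
    base_hazard_rate: float = 0.02,
) -> tuple[ExpressionDataset, SyntheticGroundTruth]:
    """Draw one synthetic dataset; same seed gives bit-identical output.

    The default d_true (16) keeps the 6 cluster-offset dimensions and the
    9 feature-driving factors in disjoint subspaces, so cluster membership
    does not leak correlation into every metadata feature.
    """
    if n_clusters > n_samples:
        raise ValueError("n_clusters cannot exceed n_samples")
    if d_true < _N_FEATURES:
        raise ValueError(
            f"d_true must be >= {_N_FEATURES} (the number of metadata features)"
        )
    rng = np.random.default_rng(seed)
    offset = d_true - _N_DRIVING_FACTORS  # feature factors occupy the tail
    factor_map = {name: (offset + slot, link)
                  for name, (slot, link) in FEATURE_FACTOR_LINKS.items()}

    clusters = rng.integers(0, n_clusters, size=n_samples)
    # guarantee every cluster non-empty
    for c in range(n_clusters):
        if not np.any(clusters == c):
            clusters[rng.integers(0, n_samples)] = c
    means = _cluster_means(n_clusters, d_true, cluster_separation)
    factors = means[clusters] + rng.standard_normal((n_samples, d_true))

    loading = rng.normal(0.0, 1.0 / np.sqrt(d_true), size=(d_true, n_genes))
    expression = factors @ loading + noise_sd * rng.standard_normal((n_samples, n_genes))

    feats = {}
    for name, (j, link) in factor_map.items():
        f = factors[:, j]
        eps = noise_sd * rng.standard_normal(n_samples)
        if link == "linear":
            feats[name] = f + eps
        elif link == "exponential":
            # noise inside the exponent keeps the value positive and the
            # dependence monotone; skewed like real time-to-event features
            feats[name] = np.exp(0.5 * (f + eps))
        elif link == "bernoulli_logistic":
            p = 1.0 / (1.0 + np.exp(-f))
            feats[name] = rng.binomial(1, p).astype(float)
        else:  # pragma: no cover
            raise ValueError(link)
    # rescale age onto a plausible year range (monotone affine; rank-safe)
    feats["age"] = 60.0 + 8.0 * feats["age"]
    features = pd.DataFrame(feats, index=[f"S{i:05d}" for i in range(n_samples)])

    hazard = np.zeros(d_true)
    hazard[factor_map["age"][0]] = 0.3  # age-linked factor contributes to risk
    hazard[factor_map["immune_infiltration"][0]] = 0.6  # dominant risk driver
    lin = factors @ hazard
    lin = lin - lin.mean()  # center so base_hazard_rate sets the scale
    rate = base_hazard_rate * np.exp(lin)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(n_samples) < censor_frac
    censor_time = rng.uniform(0.0, event_time)
    time = np.where(censored, censor_time, event_time)
    event = (~censored).astype(int)

    data = ExpressionDataset(
        values=expression,
        sample_ids=list(features.index),
        gene_ids=[f"G{j:05d}" for j in range(n_genes)],
        group_label=np.array([f"C{c}" for c in clusters]),
        survival_time=time,
        event_observed=event,
        features=features,
    )
    truth = SyntheticGroundTruth(
        true_factors=factors,
        loading_matrix=loading,
        cluster_assignment=clusters.astype(int),
        feature_factor_map=factor_map,
        hazard_coefficients=hazard,
        noise_sd=noise_sd,
        seed=seed,
    )
    return data, truth


def write_ground_truth(truth: SyntheticGroundTruth, directory) -> None:
    """Write ground truth as plain text (TSV matrices + JSON summary)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.true_factors).to_csv(directory / "true_factors.tsv", sep="\t")
    pd.DataFrame(truth.loading_matrix).to_csv(directory / "loading_matrix.tsv", sep="\t")
    meta = {
        "cluster_assignment": truth.cluster_assignment.tolist(),
        "feature_factor_map": {k: list(v) for k, v in truth.feature_factor_map.items()},
        "hazard_coefficients": truth.hazard_coefficients.tolist(),
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)
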
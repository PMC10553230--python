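"""Reading, writing and preprocessing of expression matrices and metadata.

The pipeline expects a samples x genes real-valued matrix of log-scale
expression plus per-sample metadata (group label, survival time/event,
numeric or binary covariate features). Preprocessing mirrors standard
practice for pan-cancer / tissue expression panels: keep the top-k most
variable genes by mean absolute deviation (MAD), then z-score each gene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "load_expression_table",
    "load_metadata_table",
    "select_top_mad_genes",
    "zscore_genes",
    "write_expression_table",
    "write_metadata_table",
]


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with aligned per-sample metadata.

    Attributes
    ----------
    values : (n_samples, n_genes) float array, log-scale expression.
    sample_ids, gene_ids : identifier lists matching the matrix axes.
    group_label : per-sample categorical label (cancer type / tissue),
        or None when unavailable.
    survival_time, event_observed : optional survival records; event 1 means
        the event was observed, 0 means right-censored.
    features : optional per-sample covariate table (age, gender, ...),
        indexed like sample_ids.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    group_label: np.ndarray | None = None
    survival_time: np.ndarray | None = None
    event_observed: np.ndarray | None = None
    features: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            group_label=None if self.group_label is None else self.group_label[idx],
            survival_time=None if self.survival_time is None else self.survival_time[idx],
            event_observed=None if self.event_observed is None else self.event_observed[idx],
            features=None if self.features is None else self.features.iloc[idx],
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    # pandas silently renames duplicate header entries; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate column identifiers: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df


def load_expression_table(path, orientation: str = "samples_by_genes") -> ExpressionDataset:
    """Load a delimited expression table, returning it samples x genes.

    Parameters
    ----------
    path : TSV/CSV file; first column holds row identifiers, first row
        column identifiers.
    orientation : 'samples_by_genes' (rows are samples) or
        'genes_by_samples' (rows are genes; the matrix is transposed).
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "genes_by_samples":
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups}")
    # locate non-numeric / missing cells and name them in the error
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return ExpressionDataset(
        values=numeric.to_numpy(dtype=np.float64),
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def load_metadata_table(path, data: ExpressionDataset) -> ExpressionDataset:
    """Attach a metadata table (keyed by sample id) to a dataset.

    Recognized columns: ``group`` (label), ``time`` and ``event``
    (survival); every other column becomes a covariate feature.
    """
    meta = _read_table(path)
    meta.index = meta.index.astype(str)
    missing = [s for s in data.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:5]}")
    meta = meta.loc[data.sample_ids]
    out = replace(data)
    if "group" in meta:
        out.group_label = meta["group"].to_numpy()
    if "time" in meta:
        out.survival_time = meta["time"].to_numpy(dtype=float)
    if "event" in meta:
        out.event_observed = meta["event"].to_numpy(dtype=int)
    feat_cols = [c for c in meta.columns if c not in ("group", "time", "event")]
    if feat_cols:
        out.features = meta[feat_cols].astype(float)
    return out


def gene_mad(values: np.ndarray, kind: str = "mean") -> np.ndarray:
    """Per-gene absolute-deviation statistic across samples.

    kind='mean' is the mean absolute deviation from the gene's mean (the
    default variability filter here); kind='median' is the median absolute
    deviation from the median, offered because the MAD acronym is ambiguous.
    """
    if kind == "mean":
        return np.mean(np.abs(values - values.mean(axis=0)), axis=0)
    if kind == "median":
        return np.median(np.abs(values - np.median(values, axis=0)), axis=0)
    raise ValueError(f"unknown MAD kind {kind!r}")


def select_top_mad_genes(data: ExpressionDataset, k: int, kind: str = "mean") -> ExpressionDataset:
    """Keep the k most variable genes ranked by descending MAD.

    Ties at the cutoff are broken by gene identifier (lexicographic) so the
    selection is deterministic. k >= n_genes returns all genes reordered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mad = gene_mad(data.values, kind=kind)
    # sort by (-mad, gene_id): stable, deterministic tie-break
    order = sorted(range(data.n_genes), key=lambda j: (-mad[j], data.gene_ids[j]))
    keep = order[: min(k, data.n_genes)]
    out = replace(data)
    out.values = data.values[:, keep]
    out.gene_ids = [data.gene_ids[j] for j in keep]
    return out


def zscore_genes(data: ExpressionDataset, ddof: int = 0) -> ExpressionDataset:
    """Standardize each gene to zero mean, unit sd (population sd by default).

    Raises on zero-variance genes: filter them out first (e.g. with
    :func:`select_top_mad_genes`).
    """
    mean = data.values.mean(axis=0)
    sd = data.values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [data.gene_ids[j] for j in zero[:5]]
        raise ValueError(
            f"zero-variance genes cannot be z-scored: {names}; "
            "apply MAD filtering first"
        )
    out = replace(data)
    out.values = (data.values - mean) / sd
    return out


def write_expression_table(data: ExpressionDataset, path, sep: str = "\t") -> None:
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def write_metadata_table(data: ExpressionDataset, path, sep: str = "\t") -> None:
    cols = {}
    if data.group_label is not None:
        cols["group"] = data.group_label
    if data.survival_time is not None:
        cols["time"] = data.survival_time
    if data.event_observed is not None:
        cols["event"] = data.event_observed
    df = pd.DataFrame(cols, index=data.sample_ids)
    if data.features is not None:
        feats = data.features.copy()
        feats.index = data.sample_ids
        df = pd.concat([df, feats], axis=1)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)
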
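"""Hyperparameter grid enumeration, stratified splitting and training.

The benchmark grid crosses six model variants with five hyperparameter
axes: latent dimension {10, 20, 30, 50, 100, 200}, learning rate 1e-1 ..
1e-6 (decades), optimizer {adam, rmsprop, sgd}, five weight-initialization
schemes and two activations — 1080 configurations per model, 6480 in all.

Each configuration is trained up to `max_epochs` (default 1000) with early
stopping once the validation loss has gone `patience` (default 3)
consecutive epochs without a new best, and repeated over `n_restarts`
(default 10) restarts that redraw both the weight initialization and the
70/30 group-stratified split. Any non-finite loss, gradient or weight
fails the restart immediately — divergence (exploding gradients) is a
recorded outcome, not an exception.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data_io import ExpressionDataset
from .models import ModelSpec, VAEModel, VARIANTS, INIT_SCHEMES, ACTIVATIONS

__all__ = [
    "DEFAULT_GRID",
    "HyperparameterConfig",
    "TrainingRecord",
    "enumerate_grid",
    "stratified_split",
    "EarlyStopper",
    "train_configuration",
    "run_restarts",
    "SGD",
    "RMSprop",
    "Adam",
    "make_optimizer",
    "append_ledger",
    "read_ledger",
]

DEFAULT_GRID = {
    "model": list(VARIANTS),
    "latent_dim": [10, 20, 30, 50, 100, 200],
    "learning_rate": [1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6],
    "optimizer": ["adam", "rmsprop", "sgd"],
    "init_scheme": list(INIT_SCHEMES),
    "activation": list(ACTIVATIONS),
}


@dataclass(frozen=True)
class HyperparameterConfig:
    model: str
    latent_dim: int
    learning_rate: float
    optimizer: str
    init_scheme: str
    activation: str


@dataclass
class TrainingRecord:
    """Outcome of one restart of one configuration."""

    config: HyperparameterConfig
    restart_index: int
    seed: int
    epochs_run: int
    final_train_loss: float | None
    final_val_loss: float | None
    status: str  # 'converged' | 'failed'
    batch_size: int

    def to_row(self) -> dict:
        row = asdict(self.config)
        row.update(
            restart_index=self.restart_index,
            seed=self.seed,
            epochs_run=self.epochs_run,
            final_train_loss=self.final_train_loss,
            final_val_loss=self.final_val_loss,
            status=self.status,
            batch_size=self.batch_size,
        )
        return row


def enumerate_grid(models=None, grid: dict | None = None) -> list[HyperparameterConfig]:
    """Cartesian product of the grid axes, in deterministic order.

    Axis precedence (outermost first): model, latent_dim, learning_rate,
    optimizer, init_scheme, activation; each axis iterates in its declared
    grid order.
    """
    g = dict(DEFAULT_GRID)
    if grid:
        g.update(grid)
    if models is not None:
        g["model"] = list(models)
    axes = ["model", "latent_dim", "learning_rate", "optimizer", "init_scheme", "activation"]
    for ax in axes:
        if not g[ax]:
            raise ValueError(f"grid axis {ax!r} is empty")
    return [
        HyperparameterConfig(*combo)
        for combo in itertools.product(*(g[ax] for ax in axes))
    ]


def stratified_split(data: ExpressionDataset, train_frac: float = 0.7,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation split stratified by group.

    Each group contributes round(train_frac * group size) training samples
    (clamped so both sides stay non-empty); deterministic given the seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if data.group_label is None:
        groups = np.zeros(data.n_samples, dtype=int)
    else:
        groups = np.asarray(data.group_label)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        if members.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples; cannot stratify")
        perm = rng.permutation(members)
        n_train = int(round(train_frac * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------

class SGD:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params, self.lr = params, lr

    def step(self):
        for t in self.params.values():
            if t.grad is not None:
                t.value = t.value - self.lr * t.grad


class RMSprop:
    """Running-mean-square scaling; alpha and eps at framework defaults."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params, self.lr, self.alpha, self.eps = params, lr, alpha, eps
        self.sq = {k: np.zeros_like(t.value) for k, t in params.items()}

    def step(self):
        for k, t in self.params.items():
            if t.grad is None:
                continue
            self.sq[k] = self.alpha * self.sq[k] + (1 - self.alpha) * t.grad**2
            t.value = t.value - self.lr * t.grad / (np.sqrt(self.sq[k]) + self.eps)


class Adam:
    """Adam with bias correction; betas and eps at framework defaults."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, t in self.params.items():
            if t.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * t.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * t.grad**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            t.value = t.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def make_optimizer(name: str, params: dict[str, Tensor], lr: float):
    if name == "adam":
        return Adam(params, lr)
    if name == "rmsprop":
        return RMSprop(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


# --------------------------------------------------------------------------
# early stopping / training
# --------------------------------------------------------------------------

class EarlyStopper:
    """Stop once the validation loss has gone `patience` consecutive epochs
    without strictly improving (by more than min_delta) on the best value.

    A non-finite validation loss is a failure, reported separately.
    """

    def __init__(self, patience: int = 3, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best: float | None = None
        self.stale = 0
        self.failed = False

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if not np.isfinite(val_loss):
            self.failed = True
            return True
        if self.best is None or val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _composite_loss(model: VAEModel, X: np.ndarray, rng: np.random.Generator,
                    dataset_size: int, kl_weight: float) -> float:
    lb = model.loss(X, rng, dataset_size=dataset_size, kl_weight=kl_weight)
    from .autodiff import as_float
    return as_float(lb.total)


def train_configuration(config: HyperparameterConfig, data: ExpressionDataset,
                        split: tuple[np.ndarray, np.ndarray] | None = None,
                        max_epochs: int = 1000, patience: int = 3,
                        seed: int = 0, batch_size: int = 128,
                        min_delta: float = 0.0,
                        variant_weights: dict | None = None,
                        restart_index: int = 0,
                        return_model: bool = False):
    """Train one configuration once; returns a TrainingRecord.

    The validation criterion is the same composite loss as training. Any
    non-finite batch loss, gradient or weight halts the restart with
    status 'failed' and no recorded loss values. Deterministic given the
    seed. With return_model=True, returns (record, model-or-None).
    """
    if split is None:
        split = stratified_split(data, 0.7, seed=seed)
    train_idx, val_idx = split
    X_train = data.values[train_idx]
    X_val = data.values[val_idx]
    n_train = X_train.shape[0]
    bs = min(batch_size, n_train)
    kl_weight = bs / n_train  # reconstruction/KL balance of the reference protocol

    spec = ModelSpec(
        variant=config.model,
        input_dim=data.n_genes,
        latent_dim=config.latent_dim,
        activation=config.activation,
        init_scheme=config.init_scheme,
        variant_weights=variant_weights or {},
    )
    model = VAEModel(spec, seed=seed)
    opt = make_optimizer(config.optimizer, model.params, config.learning_rate)
    rng = np.random.default_rng(seed)
    stopper = EarlyStopper(patience=patience, min_delta=min_delta)

    def fail(epoch):
        rec = TrainingRecord(config, restart_index, seed, epoch, None, None,
                             "failed", bs)
        return (rec, None) if return_model else rec

    epochs_run = 0
    train_loss = np.nan
    val_loss = np.nan
    # divergence shows up as inf/nan and is caught explicitly below, so
    # numpy's overflow warnings during a diverging restart are just noise
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for epoch in range(1, max_epochs + 1):
            epochs_run = epoch
            order = rng.permutation(n_train)
            batch_losses = []
            for start in range(0, n_train, bs):
                idx = order[start:start + bs]
                if idx.size < 2 and config.model in ("beta_tcvae", "dip_vae"):
                    continue  # aggregate-posterior estimates need >= 2 samples
                model.zero_grad()
                lb = model.loss(X_train[idx], rng, dataset_size=n_train,
                                kl_weight=kl_weight)
                loss_val = float(lb.total.value)
                if not np.isfinite(loss_val):
                    return fail(epoch)
                lb.total.backward()
                if not model.grads_finite():
                    return fail(epoch)
                opt.step()
                if not model.all_finite():
                    return fail(epoch)
                batch_losses.append(loss_val)
            train_loss = float(np.mean(batch_losses))
            val_loss = _composite_loss(model, X_val, rng,
                                       dataset_size=X_val.shape[0],
                                       kl_weight=kl_weight)
            if not np.isfinite(val_loss):
                return fail(epoch)
            if stopper.update(val_loss):
                break
    rec = TrainingRecord(config, restart_index, seed, epochs_run,
                         train_loss, val_loss, "converged", bs)
    return (rec, model) if return_model else rec


def run_restarts(config: HyperparameterConfig, data: ExpressionDataset,
                 n_restarts: int = 10, base_seed: int = 0,
                 **train_kwargs) -> tuple[list[TrainingRecord], dict]:
    """Train `n_restarts` restarts (seed = base_seed + r, fresh split each).

    Returns the records plus a summary over converged restarts: mean and
    (sample) sd of the final validation loss, convergence counts, and an
    overall status that is 'failed' only when every restart failed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    records = []
    for r in range(n_restarts):
        seed = base_seed + r
        rec = train_configuration(config, data, split=None, seed=seed,
                                  restart_index=r, **train_kwargs)
        records.append(rec)
    return records, summarize_records(records)


def summarize_records(records: list[TrainingRecord]) -> dict:
    """Mean and sample sd of final validation loss over converged restarts.

    Failed restarts never contribute a loss; if every restart failed the
    summary carries no loss values and the overall status is 'failed'.
    """
    losses = [rec.final_val_loss for rec in records if rec.status == "converged"]
    return {
        "n_restarts": len(records),
        "n_converged": len(losses),
        "n_failed": len(records) - len(losses),
        "status": "converged" if losses else "failed",
        "val_loss_mean": float(np.mean(losses)) if losses else None,
        "val_loss_sd": float(np.std(losses, ddof=1)) if len(losses) > 1
        else (0.0 if losses else None),
    }


# --------------------------------------------------------------------------
# results ledger (delimited text, unit of downstream aggregation)
# --------------------------------------------------------------------------

LEDGER_KEY = ["model", "latent_dim", "learning_rate", "optimizer",
              "init_scheme", "activation", "restart_index"]


def append_ledger(records: list[TrainingRecord], path,
                  extra_columns: dict | None = None) -> None:
    """Append one row per restart; creates the file with a header if new."""
    rows = []
    for rec in records:
        row = rec.to_row()
        if extra_columns:
            row.update(extra_columns.get((rec.config, rec.restart_index), {}))
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    header = not path.exists()
    df.to_csv(path, sep="\t", mode="a", header=header, index=False)


def read_ledger(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"ledger {path} is empty")
    return df


def completed_keys(path) -> set[tuple]:
    """(config fields..., restart_index) tuples already present in a ledger."""
    path = Path(path)
    if not path.exists():
        return set()
    df = pd.read_csv(path, sep="\t")
    return {tuple(row) for row in df[LEDGER_KEY].itertuples(index=False)}
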
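"""Tidy aggregation of benchmark ledgers.

A ledger holds one row per (configuration, restart) with the config
fields, seed, epochs, losses, status, and any downstream scores (ari,
aic). Every summary here is recomputable from the ledger alone. Failed
restarts are excluded from score statistics but counted separately, so
viability and performance are reported side by side.
"""

from __future__ import annotations

import pandas as pd

from .downstream import loss_score_correlation

__all__ = [
    "per_model_summary",
    "marginal_summary",
    "failure_counts",
    "correlation_summary",
]

HYPER_AXES = ["latent_dim", "learning_rate", "optimizer", "init_scheme", "activation"]
SCORE_COLS = ["final_val_loss", "ari", "aic"]


def _present_scores(df: pd.DataFrame) -> list[str]:
    return [c for c in SCORE_COLS if c in df.columns]


def per_model_summary(ledger: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/median of each score per model, over converged restarts."""
    if ledger.empty:
        raise ValueError("empty ledger")
    ok = ledger[ledger["status"] == "converged"]
    rows = []
    for model, sub in ok.groupby("model"):
        row = {"model": model, "n_converged": len(sub),
               "n_failed": int((ledger["model"] == model).sum() - len(sub))}
        for col in _present_scores(sub):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std()
            row[f"{col}_median"] = sub[col].median()
        rows.append(row)
    return pd.DataFrame(rows)


def marginal_summary(ledger: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Fix one hyperparameter axis, pool everything else (converged only)."""
    if axis not in HYPER_AXES + ["model"]:
        raise ValueError(f"unknown axis {axis!r}")
    ok = ledger[ledger["status"] == "converged"]
    rows = []
    for value, sub in ok.groupby(axis):
        row = {axis: value, "n": len(sub)}
        for col in _present_scores(sub):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_median"] = sub[col].median()
        rows.append(row)
    return pd.DataFrame(rows)


def failure_counts(ledger: pd.DataFrame) -> pd.DataFrame:
    """Failed/successful restart counts per (axis, value), per model."""
    rows = []
    for axis in ["model"] + HYPER_AXES:
        for value, sub in ledger.groupby(axis):
            rows.append({
                "axis": axis,
                "value": value,
                "n_failed": int((sub["status"] == "failed").sum()),
                "n_converged": int((sub["status"] == "converged").sum()),
            })
    return pd.DataFrame(rows)


def correlation_summary(ledger: pd.DataFrame) -> dict[str, float]:
    """Spearman correlations among validation loss, ARI and AIC
    (converged restarts; NaN when a score column is absent)."""
    ok = ledger[ledger["status"] == "converged"]
    out = {}
    loss = ok["final_val_loss"] if "final_val_loss" in ok else None
    for col, key in (("ari", "loss_vs_ari"), ("aic", "loss_vs_aic")):
        out[key] = (loss_score_correlation(loss, ok[col])
                    if loss is not None and col in ok else float("nan"))
    out["ari_vs_aic"] = (loss_score_correlation(ok["ari"], ok["aic"])
                         if "ari" in ok and "aic" in ok else float("nan"))
    return out
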
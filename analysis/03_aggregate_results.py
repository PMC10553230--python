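#!/usr/bin/env python
"""Aggregate the benchmark ledger into the study's summary tables.

Writes per-model score distributions, per-hyperparameter marginal
summaries (fix one axis, pool the rest), failure counts per axis value
(the viability accounting), and the Spearman correlations between
validation loss and the two downstream scores — the benchmark's central
question of whether the training loss predicts downstream usefulness.
"""

import json
from pathlib import Path

import pandas as pd

from vaebench.aggregate import (HYPER_AXES, correlation_summary, failure_counts,
                                marginal_summary, per_model_summary)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    ledger = pd.read_csv(ROOT / "ledger.tsv", sep="\t")
    out = ROOT / "summaries"
    out.mkdir(parents=True, exist_ok=True)

    pm = per_model_summary(ledger)
    pm.to_csv(out / "per_model.tsv", sep="\t", index=False)
    print("per-model medians (converged restarts):")
    cols = [c for c in ("ari_median", "aic_median", "final_val_loss_median")
            if c in pm.columns]
    print(pm[["model", "n_converged", "n_failed", *cols]].to_string(index=False))

    for axis in HYPER_AXES:
        marginal_summary(ledger, axis).to_csv(out / f"marginal_{axis}.tsv",
                                              sep="\t", index=False)
    fc = failure_counts(ledger)
    fc.to_csv(out / "failures.tsv", sep="\t", index=False)
    lr_fail = fc[fc["axis"] == "learning_rate"]
    print("\nviability by learning rate (failed / total restarts):")
    for _, row in lr_fail.iterrows():
        total = row["n_failed"] + row["n_converged"]
        print(f"  lr={row['value']:g}: {row['n_failed']}/{total}")

    corr = correlation_summary(ledger)
    with open(out / "correlations.json", "w") as fh:
        json.dump(corr, fh, indent=1)
    print("\nSpearman correlations across converged restarts:")
    print(f"  validation loss vs ARI: {corr['loss_vs_ari']:+.2f}")
    print(f"  validation loss vs AIC: {corr['loss_vs_aic']:+.2f}")
    print(f"  ARI vs AIC:             {corr['ari_vs_aic']:+.2f}")
    print(f"\nsummaries -> {out}")


if __name__ == "__main__":
    main()
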
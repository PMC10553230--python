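#!/usr/bin/env python
"""Disentanglement of the learned latent spaces at the recommended setup.

Trains each VAE variant once with the recommended configuration (Adam,
lr 1e-3, Kaiming uniform, tanh, 10 latent dimensions), then quantifies
how the latent factors relate to the ten metadata features: the
association matrix with the |rho| >= 0.1 rule, the per-feature normalized
RMIG, and the WSEPIN score. The ground-truth factors are evaluated the
same way as an upper-bound reference — on them every feature is encoded
and disentangled by construction.
"""

from pathlib import Path

import pandas as pd

from vaebench import HyperparameterConfig, train_configuration, zscore_genes
from vaebench.data_io import load_expression_table, load_metadata_table
from vaebench.disentanglement import disentanglement_report
from vaebench.downstream import embed
from vaebench.synthetic import generate_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"
VARIANTS = ["vanilla", "beta_vae", "beta_tcvae", "dip_vae", "iwae", "cat_vae"]
SEED = 0


def main():
    data = load_expression_table(ROOT / "data" / "expression.tsv")
    data = load_metadata_table(ROOT / "data" / "metadata.tsv", data)
    data = zscore_genes(data)
    out = ROOT / "disentanglement"
    out.mkdir(parents=True, exist_ok=True)

    # reference: the generator's own factors. Note WSEPIN saturates to ~0
    # whenever every latent is informative enough to identify each sample
    # (here, and for trained models with many informative latents) — the
    # same high-dimension collapse the metric shows on real panels.
    ref_data, truth = generate_dataset(seed=SEED)
    ref = disentanglement_report(truth.true_factors, ref_data.features, seed=SEED)
    print("ground-truth factors (reference): "
          f"{int(ref.encoded.sum())}/10 encoded, "
          f"{ref.n_disentangled}/10 disentangled, WSEPIN {ref.wsepin:.2f}")

    rows, long_rows = [], []
    for variant in VARIANTS:
        cfg = HyperparameterConfig(variant, 10, 1e-3, "adam",
                                   "kaiming_uniform", "tanh")
        rec, model = train_configuration(cfg, data, max_epochs=30, seed=SEED,
                                         return_model=True)
        if rec.status != "converged":
            print(f"{variant}: training failed, skipped")
            continue
        emb = embed(model, data)
        rep = disentanglement_report(emb.values, data.features, seed=SEED)
        rows.append({"model": variant,
                     "n_encoded": int(rep.encoded.sum()),
                     "n_disentangled": rep.n_disentangled,
                     "wsepin": rep.wsepin})
        per_feat = rep.to_frame()
        per_feat.insert(0, "model", variant)
        long_rows.append(per_feat)
        print(f"{variant}: {int(rep.encoded.sum())}/10 encoded, "
              f"{rep.n_disentangled}/10 disentangled, WSEPIN {rep.wsepin:.3f}")
        # heatmap-ready long format of the association matrix
        assoc = rep.association
        pd.DataFrame(assoc.values, columns=assoc.feature_names).assign(
            latent_factor=range(assoc.values.shape[0])
        ).melt(id_vars="latent_factor", var_name="feature",
               value_name="association").assign(model=variant).to_csv(
            out / f"association_{variant}.tsv", sep="\t", index=False)

    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    pd.concat(long_rows).to_csv(out / "per_feature.tsv", sep="\t", index=False)
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
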
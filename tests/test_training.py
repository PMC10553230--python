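"""Grid enumeration, stratified splitting, early stopping, restarts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vaebench import (DEFAULT_GRID, EarlyStopper, HyperparameterConfig,
                      enumerate_grid, run_restarts, stratified_split,
                      train_configuration)
from vaebench.data_io import ExpressionDataset
from vaebench.training import TrainingRecord, summarize_records


class TestEnumerateGrid:
    def test_full_grid_size(self):
        assert len(enumerate_grid()) == 6480

    def test_single_model_grid_size(self):
        assert len(enumerate_grid(models=["vanilla"])) == 1080

    def test_singleton_axes_give_one_config(self):
        grid = {k: [v[0]] for k, v in DEFAULT_GRID.items()}
        assert len(enumerate_grid(grid=grid)) == 1

    def test_no_duplicates_and_deterministic_order(self):
        a = enumerate_grid()
        b = enumerate_grid()
        assert a == b
        assert len(set(a)) == len(a)
        # model is the outermost axis
        assert [c.model for c in a[:1080]] == ["vanilla"] * 1080

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_grid(grid={"optimizer": []})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(1, 3),
           st.integers(1, 5), st.integers(1, 2), st.integers(1, 4))
    def test_size_is_product_of_axis_cardinalities(self, a, b, c, d, e, m):
        grid = {
            "model": DEFAULT_GRID["model"][:m],
            "latent_dim": DEFAULT_GRID["latent_dim"][:a],
            "learning_rate": DEFAULT_GRID["learning_rate"][:b],
            "optimizer": DEFAULT_GRID["optimizer"][:c],
            "init_scheme": DEFAULT_GRID["init_scheme"][:d],
            "activation": DEFAULT_GRID["activation"][:e],
        }
        assert len(enumerate_grid(grid=grid)) == a * b * c * d * e * m


def _grouped_dataset(sizes: dict) -> ExpressionDataset:
    n = sum(sizes.values())
    labels = np.concatenate([[g] * k for g, k in sizes.items()])
    return ExpressionDataset(values=np.random.default_rng(0).random((n, 3)),
                             sample_ids=[f"s{i}" for i in range(n)],
                             gene_ids=["a", "b", "c"], group_label=labels)


class TestStratifiedSplit:
    def test_exact_stratification(self):
        data = _grouped_dataset({"x": 50, "y": 50})
        tr, va = stratified_split(data, 0.7, seed=0)
        for g in ("x", "y"):
            assert (data.group_label[tr] == g).sum() == 35
            assert (data.group_label[va] == g).sum() == 15

    def test_partition(self):
        data = _grouped_dataset({"x": 13, "y": 29})
        tr, va = stratified_split(data, 0.7, seed=1)
        assert sorted(np.concatenate([tr, va]).tolist()) == list(range(42))
        assert set(tr).isdisjoint(va)

    def test_deterministic_given_seed(self):
        data = _grouped_dataset({"x": 20, "y": 20})
        assert np.array_equal(stratified_split(data, 0.7, seed=5)[0],
                              stratified_split(data, 0.7, seed=5)[0])
        assert not np.array_equal(stratified_split(data, 0.7, seed=5)[0],
                                  stratified_split(data, 0.7, seed=6)[0])

    def test_singleton_group_named_in_error(self):
        data = _grouped_dataset({"x": 10, "lonely": 1})
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(data, 0.7)

    def test_train_frac_bounds(self):
        data = _grouped_dataset({"x": 10})
        with pytest.raises(ValueError, match="train_frac"):
            stratified_split(data, 1.0)


class TestEarlyStopper:
    def test_scripted_sequence_stops_after_patience_stale_epochs(self):
        # best at epoch 2; epochs 3-5 fail to improve -> stop at epoch 5
        stopper = EarlyStopper(patience=3)
        decisions = [stopper.update(v) for v in [5.0, 4.0, 4.0, 4.0, 4.0]]
        assert decisions == [False, False, False, False, True]

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(v) for v in np.linspace(10, 1, 50))

    def test_non_finite_loss_flags_failure(self):
        stopper = EarlyStopper(patience=3)
        assert stopper.update(np.nan) is True
        assert stopper.failed

    def test_min_delta_counts_marginal_gains_as_stale(self):
        stopper = EarlyStopper(patience=2, min_delta=0.5)
        assert [stopper.update(v) for v in [5.0, 4.9, 4.8]] == [False, False, True]


class TestTrainConfiguration:
    CFG = HyperparameterConfig("vanilla", 4, 1e-3, "adam", "kaiming_uniform", "tanh")

    def test_deterministic_given_seed(self, small_dataset):
        data, _ = small_dataset
        r1 = train_configuration(self.CFG, data, max_epochs=3, seed=9, batch_size=64)
        r2 = train_configuration(self.CFG, data, max_epochs=3, seed=9, batch_size=64)
        assert r1.final_val_loss == r2.final_val_loss
        assert r1.final_train_loss == r2.final_train_loss

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # overflow is the point
    def test_divergence_recorded_as_failed_without_losses(self, small_dataset):
        data, _ = small_dataset
        cfg = HyperparameterConfig("vanilla", 4, 1e6, "sgd", "normal01", "relu")
        rec = train_configuration(cfg, data, max_epochs=5, seed=0, batch_size=64)
        assert rec.status == "failed"
        assert rec.final_train_loss is None and rec.final_val_loss is None
        assert rec.epochs_run <= 5

    def test_early_stopping_bounds_epochs(self, small_dataset):
        data, _ = small_dataset
        rec = train_configuration(self.CFG, data, max_epochs=50, patience=2,
                                  seed=1, batch_size=64)
        assert rec.status == "converged"
        assert rec.epochs_run <= 50


class TestRunRestarts:
    CFG = HyperparameterConfig("vanilla", 4, 1e-3, "adam", "kaiming_uniform", "tanh")

    def test_single_restart_summary(self, small_dataset):
        data, _ = small_dataset
        records, summary = run_restarts(self.CFG, data, n_restarts=1, base_seed=0,
                                        max_epochs=2, batch_size=64)
        assert summary["val_loss_mean"] == records[0].final_val_loss
        assert summary["val_loss_sd"] == 0.0

    def test_restarts_use_distinct_seeds_and_splits(self, small_dataset):
        data, _ = small_dataset
        records, _ = run_restarts(self.CFG, data, n_restarts=3, base_seed=10,
                                  max_epochs=2, batch_size=64)
        assert [r.seed for r in records] == [10, 11, 12]
        losses = {r.final_val_loss for r in records}
        assert len(losses) == 3  # different init + split per restart

    def test_summary_arithmetic_over_scripted_records(self):
        def rec(loss, status="converged"):
            return TrainingRecord(self.CFG, 0, 0, 5, loss, loss, status, 64)

        s = summarize_records([rec(1.0), rec(2.0), rec(3.0)])
        assert s["val_loss_mean"] == pytest.approx(2.0)
        assert s["val_loss_sd"] == pytest.approx(1.0)  # sample sd

    def test_failed_restarts_never_contribute_losses(self):
        def rec(loss, status):
            return TrainingRecord(self.CFG, 0, 0, 5, loss, loss, status, 64)

        s = summarize_records([rec(None, "failed"), rec(4.0, "converged")])
        assert s == {"n_restarts": 2, "n_converged": 1, "n_failed": 1,
                     "status": "converged", "val_loss_mean": 4.0, "val_loss_sd": 0.0}

    def test_all_failed_marks_configuration_failed(self):
        def rec():
            return TrainingRecord(self.CFG, 0, 0, 2, None, None, "failed", 64)

        s = summarize_records([rec(), rec()])
        assert s["status"] == "failed"
        assert s["val_loss_mean"] is None


def test_recommended_configuration_converges_in_all_restarts(small_dataset):
    """The benchmark's recommended setup (Adam, lr 1e-3, Kaiming uniform,
    tanh) must train the vanilla VAE without a single divergence."""
    data, _ = small_dataset
    cfg = HyperparameterConfig("vanilla", 10, 1e-3, "adam", "kaiming_uniform", "tanh")
    records, summary = run_restarts(cfg, data, n_restarts=10, base_seed=0,
                                    max_epochs=3, batch_size=64)
    assert summary["n_converged"] == 10
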
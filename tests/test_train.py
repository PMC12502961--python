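"""Splitting, standardization, training protocol and metrics."""

import numpy as np
import pandas as pd
import pytest

from ringprop import (
    EGATConfig,
    SplitSpec,
    TargetScaler,
    TrainConfig,
    TrainedModel,
    evaluate,
    metrics_by_ring_count,
    split_dataset,
    top_k_errors,
    train_model,
)
from ringprop.train import compute_metrics

TINY_NET = EGATConfig(hidden_dim=16, n_heads=2, head_dims=(16, 8, 5), seed=3)
FAST_TRAIN = TrainConfig(max_epochs=25, patience=25, batch_size=32, seed=4)


class TestSplit:
    def test_split_is_a_disjoint_cover_of_requested_sizes(self):
        train, val, test = split_dataset(100, SplitSpec(60, 20, 20, seed=3))
        assert len(train) == 60 and len(val) == 20 and len(test) == 20
        assert len(set(train) | set(val) | set(test)) == 100

    def test_split_deterministic_given_seed(self):
        a = split_dataset(100, SplitSpec(60, 20, 20, seed=3))
        b = split_dataset(100, SplitSpec(60, 20, 20, seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_different_seeds_overlap_at_hypergeometric_rate(self):
        """E[|A∩B|]/n_train = n_train/n when the two splits are independent."""
        a, _, _ = split_dataset(1000, SplitSpec(600, 200, 200, seed=3))
        b, _, _ = split_dataset(1000, SplitSpec(600, 200, 200, seed=4))
        overlap = len(set(a) & set(b)) / 600
        assert overlap == pytest.approx(0.6, abs=0.07)

    def test_oversized_split_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            split_dataset(10, SplitSpec(8, 2, 2, seed=0))


class TestScaler:
    def test_transform_zero_mean_unit_sd(self, rng):
        y = rng.normal(loc=3.0, scale=2.5, size=(50, 5))
        scaler = TargetScaler(y)
        z = scaler.transform(y)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_inverse_is_exact(self, rng):
        y = rng.normal(size=(30, 5))
        scaler = TargetScaler(y)
        np.testing.assert_allclose(scaler.inverse(scaler.transform(y)), y, atol=1e-12)

    def test_constant_property_rejected(self, rng):
        y = rng.normal(size=(30, 5))
        y[:, 2] = 1.5
        with pytest.raises(ValueError, match="ea"):
            TargetScaler(y)


@pytest.fixture(scope="module")
def trained_small(small_graphs, small_labels):
    split = split_dataset(len(small_graphs), SplitSpec(90, 15, 15, seed=5))
    trained, history = train_model(
        small_graphs, small_labels, split, FAST_TRAIN, TINY_NET
    )
    return trained, history, split


class TestTraining:
    def test_loss_decreases(self, trained_small):
        _, history, _ = trained_small
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_training_is_reproducible(self, small_graphs, small_labels, trained_small):
        trained_a, history_a, split = trained_small
        trained_b, history_b = train_model(
            small_graphs, small_labels, split, FAST_TRAIN, TINY_NET
        )
        pd.testing.assert_frame_equal(history_a, history_b)
        np.testing.assert_array_equal(trained_a.params, trained_b.params)

    def test_shuffled_labels_destroy_generalization(self, small_graphs, small_labels):
        """Permutation-null control: test R² collapses toward zero."""
        rng = np.random.default_rng(12)
        shuffled = small_labels[rng.permutation(len(small_labels))]
        split = split_dataset(len(small_graphs), SplitSpec(90, 15, 15, seed=5))
        trained, _ = train_model(small_graphs, shuffled, split, FAST_TRAIN, TINY_NET)
        m = evaluate(trained, [small_graphs[i] for i in split[2]], shuffled[split[2]])
        assert abs(m.loc["gap", "R2"]) < 0.2

    def test_unlabeled_training_molecule_rejected(self, small_graphs, small_labels):
        labels = small_labels.copy()
        labels[0, 0] = np.nan
        split = (np.array([0, 1, 2, 3]), np.array([4, 5]), np.array([6, 7]))
        with pytest.raises(ValueError, match="labeled"):
            train_model(small_graphs, labels, split, FAST_TRAIN, TINY_NET)

    def test_checkpoint_round_trip(self, tmp_path, trained_small, small_graphs):
        trained, _, _ = trained_small
        path = tmp_path / "model.npz"
        trained.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.egat_config == trained.egat_config
        p1, e1 = trained.predict(small_graphs[:5])
        p2, e2 = loaded.predict(small_graphs[:5])
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(e1, e2)


class TestMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.normal(size=(20, 5))
        m = compute_metrics(y, y)
        assert (m["MAE"] == 0).all() and (m["RMSE"] == 0).all() and (m["R2"] == 1).all()

    def test_constant_offset(self, rng):
        y = rng.normal(size=(20, 5))
        m = compute_metrics(y + 0.5, y)
        np.testing.assert_allclose(m["MAE"], 0.5, atol=1e-12)
        np.testing.assert_allclose(m["RMSE"], 0.5, atol=1e-12)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=(50, 5))
        m = compute_metrics(np.tile(y.mean(axis=0), (50, 1)), y)
        np.testing.assert_allclose(m["R2"], 0.0, atol=1e-12)

    def test_rmse_at_least_mae(self, trained_small, small_graphs, small_labels):
        trained, _, split = trained_small
        m = evaluate(trained, [small_graphs[i] for i in split[2]], small_labels[split[2]])
        assert (m["RMSE"] >= m["MAE"]).all()
        assert (m["R2"] <= 1).all()


class TestStratifiedAndRanked:
    def test_ring_count_groups_conserve_eval_size(
        self, trained_small, small_records, small_graphs, small_labels
    ):
        trained, _, split = trained_small
        idx = split[2]
        table = metrics_by_ring_count(
            trained,
            [small_records[i] for i in idx],
            [small_graphs[i] for i in idx],
            small_labels[idx],
        )
        per_group = table.drop_duplicates("ring_count")["n"]
        assert per_group.sum() == len(idx)

    def test_top_k_errors_ranks_corrupted_label_first(
        self, trained_small, small_records, small_graphs, small_labels
    ):
        trained, _, split = trained_small
        idx = split[2]
        labels = small_labels[idx].copy()
        labels[3, 0] += 10.0  # corrupt one gap label
        table = top_k_errors(
            trained,
            [small_records[i] for i in idx],
            [small_graphs[i] for i in idx],
            labels,
            "gap",
            k=len(idx),
        )
        assert table.loc[0, "mol_id"] == small_records[idx[3]].mol_id
        assert (table["abs_error"].diff().dropna() <= 1e-12).all()
        assert set(table["mol_id"]) == {small_records[i].mol_id for i in idx}

    def test_top_k_ties_break_by_mol_id(self, trained_small, small_records, small_graphs):
        trained, _, split = trained_small
        idx = split[2][:5]
        graphs = [small_graphs[i] for i in idx]
        records = [small_records[i] for i in idx]
        preds, _ = trained.predict(graphs)
        table = top_k_errors(trained, records, graphs, preds, "gap", k=5)
        assert (table["abs_error"] == 0).all()
        assert list(table["mol_id"]) == sorted(r.mol_id for r in records)
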
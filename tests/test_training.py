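"""Splits, training protocol, metrics, aggregation, chi-squared comparison."""

import numpy as np
import pandas as pd
import pytest

from neurofuse.model import build_model, ModelConfig
from neurofuse.training import (
    FoldMetrics,
    TrainConfig,
    aggregate_folds,
    chi_squared_compare,
    evaluate,
    grid_search,
    make_split_plan,
    train_model,
)


def labels_of(n_a, n_b, a="AD", b="CN"):
    return [a] * n_a + [b] * n_b


class TestSplitPlan:
    def test_binary_cohort_sizes_from_floor_rule(self):
        plan = make_split_plan(labels_of(83, 383), n_folds=8, seed=0)
        for fold in plan.folds:
            assert (len(fold["train"]), len(fold["val"]), len(fold["test"])) == (350, 58, 58)

    def test_threeway_explicit_sizes(self):
        labels = ["AD"] * 83 + ["MCI"] * 264 + ["CN"] * 383
        plan = make_split_plan(labels, n_folds=8, rule="explicit", val_size=95, test_size=95, seed=0)
        for fold in plan.folds:
            assert len(fold["train"]) == 540

    def test_stratification_within_one_subject(self):
        labels = labels_of(40, 40)
        plan = make_split_plan(labels, n_folds=8, seed=3)
        for fold in plan.folds:
            for part in ("train", "val", "test"):
                got = sum(1 for i in fold[part] if labels[i] == "AD")
                assert abs(got - len(fold[part]) / 2) <= 1

    def test_disjoint_and_exhaustive(self):
        labels = labels_of(30, 50)
        plan = make_split_plan(labels, n_folds=4, seed=1)
        for fold in plan.folds:
            ids = fold["train"] + fold["val"] + fold["test"]
            assert sorted(ids) == list(range(80))

    def test_deterministic_in_seed_and_varies_across_seeds(self):
        labels = labels_of(30, 50)
        p1 = make_split_plan(labels, n_folds=4, seed=7)
        p2 = make_split_plan(labels, n_folds=4, seed=7)
        p3 = make_split_plan(labels, n_folds=4, seed=8)
        assert p1.folds == p2.folds
        assert any(set(a["test"]) != set(b["test"]) for a, b in zip(p1.folds, p3.folds))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            make_split_plan(labels_of(3, 50), n_folds=8)

    def test_folds_are_independent_draws(self):
        plan = make_split_plan(labels_of(40, 40), n_folds=6, seed=0)
        tests = [frozenset(f["test"]) for f in plan.folds]
        assert len(set(tests)) > 1  # repeated sub-sampling, not a partition


def tiny_net_config(**kw):
    base = dict(n_channels=1, n_classes=2, conv_filters=(2,), kernel_size=3, stride=2,
                padding=1, pool_stages=(), dropout_rate=0.0, fc_widths=(4, 3), init_seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestTrainingLoop:
    def test_early_stopping_halts_at_patience_exhaustion(self):
        # learning rate 0: validation accuracy can never improve after epoch 1
        model = build_model(tiny_net_config())
        x = np.random.default_rng(0).random((8, 1, 6, 6, 6))
        y = np.array([0, 1] * 4)
        cfg = TrainConfig(learning_rate=0.0, batch_size=4, max_epochs=50,
                          early_stop_patience=5, plateau_patience=100, seed=0)
        _, history = train_model(model, x, y, x, y, cfg)
        assert len(history) == 1 + cfg.early_stop_patience

    def test_plateau_halves_learning_rate(self):
        model = build_model(tiny_net_config())
        x = np.random.default_rng(0).random((8, 1, 6, 6, 6))
        y = np.array([0, 1] * 4)
        lr0 = 1e-12  # too small to move validation accuracy
        cfg = TrainConfig(learning_rate=lr0, batch_size=4, max_epochs=12,
                          early_stop_patience=100, plateau_patience=3, seed=0)
        _, history = train_model(model, x, y, x, y, cfg)
        assert history["learning_rate"].iloc[0] == lr0
        assert history["learning_rate"].min() == pytest.approx(lr0 / 4, rel=1e-9)

    def test_separable_cohort_learns(self):
        # class signal in the mean intensity of channel 0
        rng = np.random.default_rng(1)
        n = 24
        y = np.array([0, 1] * (n // 2))
        x = rng.normal(0.0, 0.1, size=(n, 1, 6, 6, 6)) + y[:, None, None, None, None]
        model = build_model(tiny_net_config())
        cfg = TrainConfig(learning_rate=0.01, batch_size=8, max_epochs=30,
                          early_stop_patience=30, seed=0)
        model, history = train_model(model, x[:16], y[:16], x[16:], y[16:], cfg)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]
        assert history["val_accuracy"].max() > 0.5

    def test_empty_sets_rejected(self):
        model = build_model(tiny_net_config())
        with pytest.raises(ValueError):
            train_model(model, np.zeros((0, 1, 6, 6, 6)), np.zeros(0, int),
                        np.zeros((1, 1, 6, 6, 6)), np.zeros(1, int), TrainConfig())


class StubModel:
    """Scores are the inputs themselves; lets metric tests pick any confusion."""

    def eval_mode(self):
        pass

    def predict_proba(self, x):
        return np.asarray(x, float)


def scores_for_confusion(matrix):
    """Build (scores, y_true) realizing a given binary confusion matrix."""
    scores, y = [], []
    for true_cls, row in enumerate(matrix):
        for pred_cls, count in enumerate(row):
            for _ in range(count):
                p = np.full(len(row), 0.1)
                p[pred_cls] = 0.9
                scores.append(p / p.sum())
                y.append(true_cls)
    return np.array(scores), np.array(y)


class TestEvaluate:
    def test_perfect_classifier_scores_100(self):
        scores, y = scores_for_confusion([[8, 0], [0, 6]])
        m = evaluate(StubModel(), scores, y, ["AD", "CN"])
        for metric in ("test_accuracy", "balanced_accuracy", "f1", "precision", "recall", "auc"):
            assert getattr(m, metric) == pytest.approx(100.0)

    def test_balanced_accuracy_hand_computed(self):
        # recalls 8/10 and 6/10 -> balanced accuracy 70.0
        scores, y = scores_for_confusion([[8, 2], [4, 6]])
        m = evaluate(StubModel(), scores, y, ["AD", "CN"])
        assert m.balanced_accuracy == pytest.approx(70.0)
        assert m.test_accuracy == pytest.approx(100 * 14 / 20)
        np.testing.assert_array_equal(m.confusion, [[8, 2], [4, 6]])

    def test_identical_scores_give_chance_auc(self):
        scores = np.tile([0.5, 0.5], (10, 1))
        y = np.array([0] * 5 + [1] * 5)
        m = evaluate(StubModel(), scores, y, ["AD", "CN"])
        assert m.auc == pytest.approx(50.0)

    def test_auc_invariant_under_monotone_transform(self, rng):
        raw = rng.random((20, 2))
        scores = raw / raw.sum(axis=1, keepdims=True)
        y = rng.integers(0, 2, 20)
        m1 = evaluate(StubModel(), scores, y, ["AD", "CN"])
        m2 = evaluate(StubModel(), scores ** 3, y, ["AD", "CN"])  # strictly monotone
        assert m1.auc == pytest.approx(m2.auc)

    def test_missing_class_is_an_error(self):
        scores = np.tile([0.9, 0.1], (5, 1))
        with pytest.raises(ValueError, match="absent"):
            evaluate(StubModel(), scores, np.zeros(5, int), ["AD", "CN"])

    def test_three_class_macro_auc(self):
        scores, y = scores_for_confusion([[5, 0, 0], [0, 5, 0], [0, 0, 5]])
        m = evaluate(StubModel(), scores, y, ["AD", "CN", "MCI"])
        assert m.auc == pytest.approx(100.0)
        assert m.balanced_accuracy == pytest.approx(100.0)


def fold(acc, i=0):
    return FoldMetrics(i, acc, acc, acc, acc, acc, acc, np.eye(2), 10, int(acc / 10))


class TestAggregate:
    def test_equal_folds_zero_sd(self):
        table = aggregate_folds([fold(80.0, 0), fold(80.0, 1)])
        assert table.loc["test_accuracy", "formatted"] == "80.00 ± 0.00"

    def test_two_folds_sample_sd(self):
        table = aggregate_folds([fold(80.0, 0), fold(90.0, 1)])
        assert table.loc["test_accuracy", "mean"] == pytest.approx(85.0)
        assert table.loc["test_accuracy", "sd"] == pytest.approx(10 / np.sqrt(2), abs=1e-2)
        assert table.loc["test_accuracy", "formatted"] == "85.00 ± 7.07"

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([fold(80.0)])


class TestChiSquared:
    def test_equal_proportions_give_zero(self):
        stat, p = chi_squared_compare(40, 50, 80, 100)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_expected_count_oracle(self):
        stat, _ = chi_squared_compare(40, 50, 25, 50)
        obs = np.array([[40, 10], [25, 25]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        want = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(want, abs=1e-9)

    def test_row_swap_symmetry(self):
        s1, p1 = chi_squared_compare(40, 50, 25, 50)
        s2, p2 = chi_squared_compare(25, 50, 40, 50)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_scales_linearly_with_counts(self):
        s1, _ = chi_squared_compare(40, 50, 25, 50)
        s3, _ = chi_squared_compare(120, 150, 75, 150)
        assert s3 == pytest.approx(3 * s1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_compare(0, 5, 0, 5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_compare(6, 5, 1, 5)


class TestGridSearch:
    @staticmethod
    def _data():
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 12)
        x = rng.normal(0, 0.1, (24, 1, 6, 6, 6)) + y[:, None, None, None, None]
        labels = ["AD" if v == 0 else "CN" for v in y]
        from neurofuse.training import make_split_plan

        plan = make_split_plan(labels, n_folds=2, rule="explicit", val_size=4, test_size=4, seed=0)
        return x, y, plan

    def test_single_configuration_returned(self):
        x, y, plan = self._data()
        mcfg = tiny_net_config()
        tcfg = TrainConfig(learning_rate=0.01, batch_size=8, max_epochs=3, seed=0)
        best_m, best_t, table = grid_search(x, y, plan, [mcfg], [tcfg], ["AD", "CN"])
        assert best_m is mcfg and best_t is tcfg
        assert len(table) == 1

    def test_dominating_configuration_selected(self):
        x, y, plan = self._data()
        mcfg = tiny_net_config()
        good = TrainConfig(learning_rate=0.01, batch_size=8, max_epochs=8, seed=0)
        useless = TrainConfig(learning_rate=0.0, batch_size=8, max_epochs=2, seed=0)
        best_m, best_t, table = grid_search(x, y, plan, [mcfg], [good, useless], ["AD", "CN"])
        by_lr = table.set_index("learning_rate")["mean_val_accuracy"]
        if by_lr[0.01] > by_lr[0.0]:
            assert best_t is good

    def test_default_grid_size(self):
        from neurofuse.training import DEFAULT_BATCH_GRID, DEFAULT_LR_GRID
        from neurofuse.model import KERNEL_COMBOS

        assert len(DEFAULT_LR_GRID) * len(DEFAULT_BATCH_GRID) * len(KERNEL_COMBOS) == 50
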
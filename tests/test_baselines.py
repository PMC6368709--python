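"""Pair-feature encoding, soft-impute oracle behaviour, tabular scorers."""

import numpy as np
import pytest

from trialtensor import baselines
from trialtensor.baselines import (
    TuningConfig,
    build_pair_features,
    fit_tabular,
    predict_completion,
    predict_tabular,
    soft_impute,
    soft_impute_objective,
    tune_soft_impute,
)
from trialtensor.data_model import AugmentedTensor, EntityRegistry, OutcomeMatrix, TargetAttributes


def outcome_matrix(M, N, cells):
    reg = EntityRegistry(
        tuple(f"T{i}" for i in range(M)),
        tuple(f"D{j}" for j in range(N)),
        ("S0",),
    )
    i, j, v = (np.array(x) for x in zip(*cells))
    return OutcomeMatrix(reg, i, j, v)


class TestPairFeatures:
    def test_width_is_2k_plus_g(self, tiny_tensor, tiny_attrs):
        pairs = np.array([[0, 0], [1, 1]])
        t = build_pair_features(tiny_tensor, tiny_attrs, pairs)
        assert t.X.shape == (2, 2 * 2 + 3)

    def test_ternary_encoding(self, tiny_tensor, tiny_attrs):
        # cell (0,0,S00)=1 -> (1,0); cell (1,1,S00)=0 -> (0,1); unknown -> (0,0)
        t = build_pair_features(tiny_tensor, tiny_attrs, np.array([[0, 0], [1, 1], [2, 1]]))
        assert t.X[0, 0:2].tolist() == [1, 0]
        assert t.X[1, 0:2].tolist() == [0, 1]
        assert t.X[2, 0:4].tolist() == [0, 0, 0, 0]

    def test_attribute_block_duplicated_per_target(self, tiny_tensor, tiny_attrs):
        t = build_pair_features(tiny_tensor, tiny_attrs, np.array([[1, 0], [1, 1]]))
        assert np.array_equal(t.X[0, 4:], t.X[1, 4:])
        assert t.X[0, 4:].tolist() == [0, 1, 0]

    def test_unregistered_pair_rejected(self, tiny_tensor, tiny_attrs):
        with pytest.raises(ValueError, match="unregistered"):
            build_pair_features(tiny_tensor, tiny_attrs, np.array([[9, 0]]))

    def test_pure_function_row_order_preserved(self, tiny_tensor, tiny_attrs):
        pairs = np.array([[2, 1], [0, 0]])
        t1 = build_pair_features(tiny_tensor, tiny_attrs, pairs)
        t2 = build_pair_features(tiny_tensor, tiny_attrs, pairs)
        assert np.array_equal(t1.X, t2.X)
        assert np.array_equal(t1.pairs, pairs)


class TestSoftImpute:
    def test_rank_one_closed_form(self):
        # [[2,2],[2,2]] has sigma = 4; shrinking by 2 halves the matrix
        res = soft_impute(np.full((2, 2), 2.0), lam=2.0, tol=1e-12)
        assert np.allclose(res.Z, 1.0, atol=1e-8)

    def test_no_shrinkage_fully_observed_is_identity(self):
        om = outcome_matrix(2, 2, [(0, 0, 1), (0, 1, 0), (1, 0, 0), (1, 1, 1)])
        res = soft_impute(om, lam=0.0, tol=1e-10)
        R = np.array([[1, 0], [0, 1]], dtype=float)
        assert np.linalg.norm(res.Z - R, "fro") < 1e-6

    def test_total_shrinkage_yields_zero(self):
        om = outcome_matrix(2, 2, [(0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 1)])
        res = soft_impute(om, lam=10.0)  # lam >= sigma_1 = 2
        assert np.allclose(res.Z, 0.0)

    def test_objective_non_increasing_on_random_instances(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            M, N = 8, 6
            mask_cells = [
                (i, j, int(rng.integers(0, 2)))
                for i in range(M)
                for j in range(N)
                if rng.random() < 0.5
            ]
            om = outcome_matrix(M, N, mask_cells)
            res = soft_impute(om, lam=float(rng.uniform(0.1, 2.0)), max_iter=60)
            diffs = np.diff(res.objective_trace)
            assert (diffs <= 1e-9).all()

    def test_empty_matrix_rejected(self):
        reg = EntityRegistry(("T0",), ("D0",), ("S0",))
        empty = OutcomeMatrix(reg, np.array([], int), np.array([], int), np.array([], int))
        with pytest.raises(ValueError, match="empty"):
            soft_impute(empty, lam=1.0)


class TestTuneSoftImpute:
    def test_singleton_grid(self):
        om = outcome_matrix(2, 2, [(0, 0, 1)])
        assert tune_soft_impute(om, [0.7], None) == 0.7

    def test_empty_grid_rejected(self):
        om = outcome_matrix(2, 2, [(0, 0, 1)])
        with pytest.raises(ValueError, match="grid"):
            tune_soft_impute(om, [], None)

    def test_selected_lambda_interior_on_noisy_low_rank(self, default_world):
        from trialtensor import benchmark as bench

        out = default_world.outcomes
        inner = bench.stratified_random_folds(out, 3, seed=1)
        lam = tune_soft_impute(out, [0.0, 0.5, 1.0, 2.0, 50.0], inner)
        assert 0.0 < lam < 50.0

    def test_equal_scores_pick_largest(self):
        # a grid of huge lambdas all produce the zero matrix -> identical
        # (undefined-free) scores; tie resolves to the largest lambda
        om = outcome_matrix(
            4, 3, [(0, 0, 1), (1, 1, 0), (2, 2, 1), (3, 0, 0), (0, 1, 1), (1, 2, 0)]
        )
        from trialtensor import benchmark as bench

        inner = bench.stratified_random_folds(om, 2, seed=0)
        assert tune_soft_impute(om, [60.0, 80.0, 100.0], inner) == 100.0


class TestTabularModels:
    @pytest.fixture()
    def separable(self, tiny_registry):
        rng = np.random.default_rng(0)
        M, N = 30, 6
        reg = EntityRegistry(
            tuple(f"T{i}" for i in range(M)),
            tuple(f"D{j}" for j in range(N)),
            ("S00",),
        )
        # evidence cell present iff the pair will be labelled positive
        pairs = np.array([(i, j) for i in range(M) for j in range(N)])
        labels = rng.integers(0, 2, len(pairs))
        pos = pairs[labels == 1]
        t = AugmentedTensor(
            reg,
            pos[:, 0],
            pos[:, 1],
            np.zeros(len(pos), dtype=int),
            np.ones(len(pos), dtype=int),
        )
        attrs = TargetAttributes(
            reg.targets, np.zeros((M, 1), dtype=np.int8), (("s", "c"),)
        )
        feats = build_pair_features(t, attrs, pairs)
        return feats, labels

    @pytest.mark.parametrize(
        "kind", ["logreg", "l1_logreg", "random_forest", "gradient_boosting"]
    )
    def test_separable_data_fits_perfectly(self, separable, kind):
        from trialtensor.metrics import auroc

        feats, labels = separable
        scorer = fit_tabular(feats, labels, kind, TuningConfig(inner_k=3, seed=0))
        scores = predict_tabular(scorer, feats)
        assert (scores >= 0).all() and (scores <= 1).all()
        assert auroc(labels, scores) == 1.0

    def test_null_features_give_chance_auroc(self):
        from trialtensor.metrics import auroc

        rng = np.random.default_rng(2)
        n = 2000
        reg = EntityRegistry(
            tuple(f"T{i}" for i in range(n)), ("D0",), ("S00",)
        )
        # one random binary evidence column, labels independent of it
        on = np.flatnonzero(rng.random(n) < 0.5)
        t = AugmentedTensor(
            reg, on, np.zeros(len(on), int), np.zeros(len(on), int), np.ones(len(on), int)
        )
        attrs = TargetAttributes(reg.targets, np.zeros((n, 1), np.int8), (("s", "c"),))
        pairs = np.column_stack([np.arange(n), np.zeros(n, int)])
        feats = build_pair_features(t, attrs, pairs)
        labels = rng.integers(0, 2, n)
        half = n // 2
        scorer = fit_tabular(
            baselines.PairFeatureTable(pairs[:half], feats.X[:half], feats.feature_names),
            labels[:half],
            "logreg",
        )
        held = predict_tabular(
            scorer, baselines.PairFeatureTable(pairs[half:], feats.X[half:], feats.feature_names)
        )
        assert 0.45 <= auroc(labels[half:], held) <= 0.55

    def test_l1_recovers_sparse_signal(self):
        rng = np.random.default_rng(3)
        n, p_noise = 400, 10
        signal = rng.integers(0, 2, n)
        X = np.column_stack([signal, rng.integers(0, 2, (n, p_noise))]).astype(float)
        labels = signal.copy()
        pairs = np.column_stack([np.arange(n), np.zeros(n, int)])
        names = tuple(f"f{c}" for c in range(p_noise + 1))
        feats = baselines.PairFeatureTable(pairs, X, names)
        scorer = fit_tabular(feats, labels, "l1_logreg", TuningConfig(inner_k=3, seed=0))
        assert np.count_nonzero(scorer.coef_) <= 3

    def test_single_class_rejected(self, separable):
        feats, labels = separable
        with pytest.raises(ValueError, match="class"):
            fit_tabular(feats, np.ones_like(labels), "logreg")

    def test_unknown_kind_rejected(self, separable):
        feats, labels = separable
        with pytest.raises(ValueError, match="model_kind"):
            fit_tabular(feats, labels, "svm")

    def test_predict_width_mismatch_rejected(self, separable):
        feats, labels = separable
        scorer = fit_tabular(feats, labels, "logreg")
        narrow = baselines.PairFeatureTable(
            feats.pairs, feats.X[:, :-1], feats.feature_names[:-1]
        )
        with pytest.raises(ValueError, match="width"):
            predict_tabular(scorer, narrow)

    def test_empty_features_empty_scores(self, separable):
        feats, labels = separable
        scorer = fit_tabular(feats, labels, "logreg")
        empty = baselines.PairFeatureTable(
            np.empty((0, 2), int), np.empty((0, feats.X.shape[1])), feats.feature_names
        )
        assert len(predict_tabular(scorer, empty)) == 0

    def test_duplicate_rows_equal_scores(self, separable):
        feats, labels = separable
        scorer = fit_tabular(feats, labels, "logreg")
        dup = baselines.PairFeatureTable(
            np.vstack([feats.pairs[:1]] * 2), np.vstack([feats.X[:1]] * 2), feats.feature_names
        )
        s = predict_tabular(scorer, dup)
        assert s[0] == s[1]


class TestColdStartCompletion:
    def test_unseen_target_gets_base_rate(self):
        om = outcome_matrix(3, 3, [(0, 0, 1), (0, 1, 0), (1, 0, 1), (1, 1, 1)])
        res = soft_impute(om, lam=0.5)
        preds = predict_completion(res, om, np.array([[2, 0], [0, 2]]))
        assert preds[0] == pytest.approx(0.75)  # target 2 never observed
        assert preds[1] == pytest.approx(0.75)  # indication 2 never observed
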
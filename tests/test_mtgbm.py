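"""Shared-tree boosting engine: gradients, splits, leaves, oracle equivalence.

The reference oracle is an independently coded depth-wise recursive greedy
booster (second-order gain, Newton leaf values).  With the leaf cap
unbinding, best-first and depth-wise growth expand exactly the same set of
positive-gain splits, so per-round predictions must agree to float
precision.
"""

import numpy as np
import pytest

from pkmt.mtgbm import (BoostConfig, MultiTaskGBMRegressor, TaskGradients,
                        compute_task_gradients, find_best_split, fit_ensemble,
                        grow_shared_tree, hpo_single_task)


def oracle_boost(X, y, lr, l2, min_child, max_depth, rounds):
    """Brute-force second-order boosting (single task, no L1), returning the
    prediction vector after every round."""
    n = len(y)
    pred = np.full(n, y.mean())
    history = []
    for _ in range(rounds):
        g = pred - y

        def best_split(rows):
            G = g[rows].sum()
            parent = G * G / (len(rows) + l2)
            best = None
            for j in range(X.shape[1]):
                vals = np.unique(X[rows, j])
                for a, b in zip(vals[:-1], vals[1:]):
                    thr = (a + b) / 2.0
                    left = rows[X[rows, j] <= thr]
                    right = rows[X[rows, j] > thr]
                    if len(left) < min_child or len(right) < min_child:
                        continue
                    gain = (g[left].sum() ** 2 / (len(left) + l2)
                            + g[right].sum() ** 2 / (len(right) + l2) - parent)
                    if gain > 0 and (best is None or gain > best[0]):
                        best = (gain, left, right)
            return best

        tree_pred = np.zeros(n)

        def recurse(rows, depth):
            best = best_split(rows) if (depth < max_depth
                                        and len(rows) >= 2 * min_child) else None
            if best is None:
                tree_pred[rows] = -g[rows].sum() / (len(rows) + l2)
            else:
                recurse(best[1], depth + 1)
                recurse(best[2], depth + 1)

        recurse(np.arange(n), 0)
        pred = pred + lr * tree_pred
        history.append(pred.copy())
    return history


class TestGradients:
    def test_zero_at_perfect_fit(self):
        y = np.array([[1.0, 2.0]])
        tg = compute_task_gradients(y, y, np.ones((1, 2), bool))
        np.testing.assert_array_equal(tg.g, 0.0)
        np.testing.assert_array_equal(tg.h, 1.0)

    def test_squared_loss_derivatives(self):
        tg = compute_task_gradients(np.array([[0.0]]), np.array([[3.0]]),
                                    np.ones((1, 1), bool))
        assert tg.g[0, 0] == -3.0
        assert tg.h[0, 0] == 1.0

    def test_masked_rows_contribute_nothing(self):
        y = np.array([[1.0, np.nan]])
        masks = np.array([[True, False]])
        tg = compute_task_gradients(np.zeros((1, 2)), y, masks)
        assert tg.g[0, 1] == 0.0
        assert tg.h[0, 1] == 0.0

    def test_nan_in_unmasked_target_raises(self):
        with pytest.raises(ValueError, match="NaN"):
            compute_task_gradients(np.zeros((1, 1)), np.array([[np.nan]]),
                                   np.ones((1, 1), bool))


class TestSplitSearch:
    def test_known_four_point_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        tg = TaskGradients(g=np.array([[-1.0], [-1.0], [1.0], [1.0]]),
                           h=np.ones((4, 1)), masks=np.ones((4, 1), bool))
        cfg = BoostConfig(lambda_l1=0, lambda_l2=0, min_child_samples=1,
                          n_tasks=1)
        feat, thr, gain = find_best_split(X, np.arange(4), tg, cfg)
        assert (feat, thr) == (0, 1.5)
        assert gain == pytest.approx(4.0)

    def test_duplicated_task_doubles_gain_same_split(self, rng):
        X = rng.normal(size=(30, 3))
        g1 = rng.normal(size=(30, 1))
        cfg1 = BoostConfig(lambda_l2=1.0, min_child_samples=3, n_tasks=1)
        tg1 = TaskGradients(g=g1, h=np.ones((30, 1)), masks=np.ones((30, 1), bool))
        s1 = find_best_split(X, np.arange(30), tg1, cfg1)
        tg2 = TaskGradients(g=np.hstack([g1, g1]), h=np.ones((30, 2)),
                            masks=np.ones((30, 2), bool))
        s2 = find_best_split(X, np.arange(30), tg2, cfg1)
        assert s1[:2] == s2[:2]
        assert s2[2] == pytest.approx(2 * s1[2])

    def test_constant_features_yield_none(self):
        X = np.ones((10, 2))
        tg = TaskGradients(g=np.arange(10.0).reshape(-1, 1), h=np.ones((10, 1)),
                           masks=np.ones((10, 1), bool))
        cfg = BoostConfig(min_child_samples=1, n_tasks=1)
        assert find_best_split(X, np.arange(10), tg, cfg) is None


class TestLeafValues:
    def _single_leaf(self, g, h, cfg):
        X = np.ones((len(g), 1))  # unsplittable
        tg = TaskGradients(g=np.asarray(g, float).reshape(-1, 1),
                           h=np.asarray(h, float).reshape(-1, 1),
                           masks=np.ones((len(g), 1), bool))
        tree = grow_shared_tree(X, tg, cfg)
        return tree.values[0][0]

    def test_newton_step_is_leaf_mean(self):
        # targets {1, 3}, predictions 0 -> G = -4, H = 2 -> value 2
        cfg = BoostConfig(lambda_l1=0, lambda_l2=0, min_child_samples=1,
                          n_tasks=1)
        assert self._single_leaf([-1.0, -3.0], [1, 1], cfg) == pytest.approx(2.0)

    def test_l2_shrinkage(self):
        cfg = BoostConfig(lambda_l1=0, lambda_l2=2.0, min_child_samples=1,
                          n_tasks=1)
        assert self._single_leaf([-1.0, -3.0], [1, 1], cfg) == pytest.approx(1.0)

    def test_l1_soft_threshold_zeroes(self):
        cfg = BoostConfig(lambda_l1=5.0, lambda_l2=0.0, min_child_samples=1,
                          n_tasks=1)
        assert self._single_leaf([-1.0, -3.0], [1, 1], cfg) == 0.0


class TestFitEnsemble:
    def test_default_config_echoes_study_settings(self):
        cfg = BoostConfig()
        assert (cfg.learning_rate, cfg.num_leaves, cfg.max_depth) == (0.014, 44, 13)
        assert (cfg.lambda_l1, cfg.lambda_l2) == (0.71, 2.89)
        assert cfg.max_rounds == 15000

    @pytest.mark.parametrize("seed,n,p", [(0, 30, 3), (1, 50, 5), (2, 40, 4)])
    def test_single_task_matches_oracle_per_round(self, seed, n, p):
        gen = np.random.default_rng(seed)
        X = gen.normal(size=(n, p))
        y = X[:, 0] - 0.5 * X[:, 1] + 0.2 * gen.normal(size=n)
        lr, l2, mcs, depth, rounds = 0.3, 1.5, 3, 4, 10
        cfg = BoostConfig(learning_rate=lr, num_leaves=2 * n, max_depth=depth,
                          lambda_l1=0.0, lambda_l2=l2, min_child_samples=mcs,
                          max_rounds=rounds, n_tasks=1)
        ens = fit_ensemble(X, y.reshape(-1, 1), cfg=cfg)
        oracle = oracle_boost(X, y, lr, l2, mcs, depth, rounds)
        for r in range(1, rounds + 1):
            mine = ens.predict(X, n_rounds=r)[:, 0]
            np.testing.assert_allclose(mine, oracle[r - 1], atol=1e-9)

    def test_identical_task_reduction(self, toy_regression):
        Xt, yt, Xv, yv = toy_regression
        kw = dict(learning_rate=0.1, num_leaves=8, max_depth=4, lambda_l1=0.1,
                  lambda_l2=1.0, min_child_samples=5, max_rounds=60, patience=10)
        st = fit_ensemble(Xt, yt.reshape(-1, 1), Xv, yv.reshape(-1, 1),
                          BoostConfig(n_tasks=1, **kw))
        mt = fit_ensemble(Xt, np.column_stack([yt, yt]), Xv,
                          np.column_stack([yv, yv]), BoostConfig(n_tasks=2, **kw))
        p_mt = mt.predict(Xv)
        assert np.max(np.abs(p_mt[:, 0] - p_mt[:, 1])) <= 1e-12
        assert np.max(np.abs(p_mt[:, 0] - st.predict(Xv)[:, 0])) <= 1e-12

    def test_training_loss_monotone_without_l1(self, toy_regression):
        Xt, yt, _, _ = toy_regression
        cfg = BoostConfig(learning_rate=0.3, num_leaves=16, max_depth=5,
                          lambda_l1=0.0, lambda_l2=1.0, min_child_samples=3,
                          max_rounds=40, n_tasks=1)
        ens = fit_ensemble(Xt, yt.reshape(-1, 1), cfg=cfg)
        log = np.array(ens.train_log)
        assert (np.diff(log) <= 1e-12).all()

    def test_mask_neutrality_in_leaf_values(self):
        # second task masked on half the rows: its leaf values must be driven
        # only by the unmasked rows' gradients
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([[1.0, 1.0], [1.0, np.nan], [2.0, 4.0], [2.0, np.nan]])
        cfg = BoostConfig(learning_rate=1.0, num_leaves=2, max_depth=2,
                          lambda_l1=0.0, lambda_l2=0.0, min_child_samples=1,
                          max_rounds=1, n_tasks=2)
        ens = fit_ensemble(X, y, cfg=cfg)
        pred = ens.predict(X, n_rounds=1)
        # task 2 base = mean(1, 4) = 2.5; leaves restore 1.0 and 4.0 exactly
        np.testing.assert_allclose(pred[:, 1], [1.0, 1.0, 4.0, 4.0], atol=1e-12)

    def test_early_stopping_and_best_iteration(self, toy_regression):
        Xt, yt, Xv, yv = toy_regression
        cfg = BoostConfig(learning_rate=0.3, num_leaves=16, max_depth=5,
                          lambda_l1=0.0, lambda_l2=0.5, min_child_samples=3,
                          max_rounds=500, patience=15, n_tasks=1)
        ens = fit_ensemble(Xt, yt.reshape(-1, 1), Xv, yv.reshape(-1, 1), cfg)
        assert len(ens.trees) < 500
        assert ens.best_iteration == int(np.argmin(ens.val_log)) + 1

    def test_missing_whole_task_raises(self):
        X = np.zeros((5, 1))
        y = np.column_stack([np.ones(5), np.full(5, np.nan)])
        with pytest.raises(ValueError, match="unmasked"):
            fit_ensemble(X, y, cfg=BoostConfig(n_tasks=2, max_rounds=1))


class TestRegressorFrontEnd:
    def test_empty_ensemble_predicts_base(self, toy_regression):
        Xt, yt, _, _ = toy_regression
        model = MultiTaskGBMRegressor(n_tasks=1, max_rounds=0, patience=5)
        model.fit(Xt, yt.reshape(-1, 1))
        np.testing.assert_allclose(model.predict(Xt), yt.mean())

    def test_column_mismatch_raises(self, toy_regression):
        Xt, yt, _, _ = toy_regression
        model = MultiTaskGBMRegressor(n_tasks=1, max_rounds=2, num_leaves=4,
                                      min_child_samples=5)
        model.fit(Xt, yt.reshape(-1, 1))
        with pytest.raises(ValueError, match="feature columns"):
            model.predict(Xt[:, :2])

    def test_training_log_consistent_with_predictions(self, toy_regression):
        Xt, yt, _, _ = toy_regression
        model = MultiTaskGBMRegressor(n_tasks=1, max_rounds=10, num_leaves=8,
                                      learning_rate=0.2, min_child_samples=5,
                                      lambda_l1=0.0)
        model.fit(Xt, yt.reshape(-1, 1))
        pred = model.ensemble_.predict(Xt, n_rounds=10)[:, 0]
        assert np.mean((pred - yt) ** 2) == pytest.approx(
            model.ensemble_.train_log[-1])

    def test_sklearn_get_set_params(self):
        model = MultiTaskGBMRegressor()
        params = model.get_params()
        assert params["num_leaves"] == 44
        model.set_params(num_leaves=10)
        assert model.num_leaves == 10


class TestHPO:
    def _data(self):
        gen = np.random.default_rng(4)
        X = gen.normal(size=(60, 3))
        # model scale = log1p of a positive quantity, so expm1 inverts validly
        y = np.log1p(np.exp(X[:, 0] + 0.3 * gen.normal(size=60)))
        return X[:45], y[:45], X[45:], y[45:]

    def test_single_trial_and_determinism(self):
        Xt, yt, Xv, yv = self._data()
        inv = np.expm1
        kw = dict(n_trials=2, max_rounds=30, patience=10, seed=7)
        a = hpo_single_task(Xt, yt.reshape(-1, 1), Xv, yv.reshape(-1, 1), inv, **kw)
        b = hpo_single_task(Xt, yt.reshape(-1, 1), Xv, yv.reshape(-1, 1), inv, **kw)
        assert a == b
        assert a.n_tasks == 1

    def test_point_space_returned(self):
        Xt, yt, Xv, yv = self._data()
        space = {"learning_rate": (0.02, 0.02), "num_leaves": (8, 8),
                 "max_depth": (6, 6), "min_child_samples": (10, 10),
                 "lambda_l1": (0.5, 0.5), "lambda_l2": (1.0, 1.0)}
        cfg = hpo_single_task(Xt, yt.reshape(-1, 1), Xv, yv.reshape(-1, 1),
                              np.expm1, search_space=space, n_trials=3,
                              max_rounds=20, seed=0)
        assert cfg.learning_rate == pytest.approx(0.02)
        assert (cfg.num_leaves, cfg.max_depth, cfg.min_child_samples) == (8, 6, 10)
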
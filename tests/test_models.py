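import numpy as np
import pytest

from callopt.metrics import r_squared, rmse, split_train_test
from callopt.models import (
    GRNN,
    MLP,
    RBFNetwork,
    TrainingConfig,
    compare_models,
    make_model,
    select_spread,
    treatment_aggregate,
)


def grnn_oracle(patterns, targets, query, sigma):
    """Direct-summation Nadaraya-Watson average (independent of the model)."""
    num = den = 0.0
    for x, y in zip(patterns, targets):
        w = np.exp(-np.sum((query - x) ** 2) / (2 * sigma**2))
        num += w * y
        den += w
    return num / den


class TestGRNN:
    def test_single_pattern_returns_its_target(self):
        m = GRNN(spread=0.5, normalize=False).fit([[0.2, 0.2, 0.2, 0.2]], [7.0])
        assert m.predict([[1.0, 1.0, 1.0, 1.0]]) == pytest.approx([7.0])

    def test_equidistant_patterns_average(self):
        X = [[0.0, 0, 0, 0], [1.0, 0, 0, 0]]
        m = GRNN(spread=0.3, normalize=False).fit(X, [10.0, 20.0])
        assert m.predict([[0.5, 0, 0, 0]]) == pytest.approx([15.0])

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((5, 4)), rng.uniform(0, 100, 5)
        m = GRNN(spread=0.3, normalize=False).fit(X, y)
        for q in rng.random((10, 4)):
            assert abs(m.predict([q])[0] - grnn_oracle(X, y, q, 0.3)) < 1e-10

    def test_predictions_bounded_by_target_range(self):
        rng = np.random.default_rng(1)
        for sigma in (0.01, 0.1, 1.0, 10.0):
            X, y = rng.random((30, 4)), rng.uniform(-5, 5, 30)
            m = GRNN(spread=sigma, normalize=False).fit(X, y)
            p = m.predict(rng.random((50, 4)) * 2 - 0.5)
            assert p.min() >= y.min() - 1e-9 and p.max() <= y.max() + 1e-9

    def test_large_spread_predicts_target_mean(self):
        rng = np.random.default_rng(2)
        X, y = rng.random((20, 4)), rng.uniform(0, 100, 20)
        m = GRNN(spread=1e4, normalize=False).fit(X, y)
        assert m.predict(rng.random((5, 4))) == pytest.approx(y.mean(), abs=1e-3)

    def test_vanishing_spread_returns_nearest_target(self):
        X = np.array([[0.0, 0, 0, 0], [1.0, 0, 0, 0], [0.4, 0, 0, 0]])
        m = GRNN(spread=1e-4, normalize=False).fit(X, [1.0, 2.0, 3.0])
        assert m.predict([[0.45, 0, 0, 0]]) == pytest.approx([3.0])
        # far outside the pattern cloud: still finite, still the nearest target
        assert m.predict([[50.0, 0, 0, 0]]) == pytest.approx([2.0])

    def test_predict_is_pure_and_empty_fit_rejected(self):
        rng = np.random.default_rng(3)
        m = GRNN(spread=0.2, normalize=False).fit(rng.random((8, 4)), rng.random(8))
        q = rng.random((4, 4))
        assert np.array_equal(m.predict(q), m.predict(q))
        with pytest.raises(ValueError, match="empty"):
            GRNN(spread=0.2).fit(np.empty((0, 4)), [])
        with pytest.raises(ValueError, match="not fitted"):
            GRNN().predict([[0, 0, 0, 0]])


class TestSpreadSelection:
    def test_selected_spread_no_worse_than_grid_endpoints(self, dense_surface):
        reps, _ = dense_surface
        sub = reps.sample(60, random_state=0)
        X = sub[["bap", "kin", "naa", "iba"]].to_numpy()
        y = sub["cfr"].to_numpy()
        grid = [0.02, 0.1, 0.3, 1.0]

        def cv_rmse(sigma):
            from callopt.metrics import kfold_indices

            errs = []
            for f in kfold_indices(len(y), 5, seed=0):
                m = GRNN(spread=sigma, normalize=False).fit(X[f.train], y[f.train])
                errs.append(rmse(y[f.test], m.predict(X[f.test])))
            return np.mean(errs)

        star = select_spread(X, y, grid, k=5, seed=0)
        assert cv_rmse(star) <= cv_rmse(grid[0]) + 1e-9
        assert cv_rmse(star) <= cv_rmse(grid[-1]) + 1e-9

    def test_duplicate_grid_values_deduplicated(self):
        rng = np.random.default_rng(5)
        X, y = rng.random((30, 4)), rng.random(30)
        a = select_spread(X, y, [0.1, 0.1, 0.5, 0.5], k=3, seed=0)
        b = select_spread(X, y, [0.1, 0.5], k=3, seed=0)
        assert a == b

    def test_interior_optimum_on_noisy_surface(self, table):
        """Bias-variance: neither the sharpest nor smoothest sigma wins."""
        from callopt.synthetic import reconstruct_replicates

        reps = reconstruct_replicates(table, n_reps=7, seed=0)
        X = reps[["bap", "kin", "naa", "iba"]].to_numpy()
        y = reps["cfr"].to_numpy()
        grid = list(np.geomspace(0.005, 5.0, 15))
        star = select_spread(X, y, grid, k=5, seed=0)
        assert grid[0] < star < grid[-1]

    def test_degenerate_grids_rejected(self):
        rng = np.random.default_rng(6)
        X, y = rng.random((10, 4)), rng.random(10)
        with pytest.raises(ValueError):
            select_spread(X, y, [0.3], k=2)
        with pytest.raises(ValueError):
            select_spread(X, y, [-0.1, 0.3], k=2)


class TestRBF:
    def test_interpolation_regime_recovers_targets(self):
        rng = np.random.default_rng(7)
        X, y = rng.random((12, 4)), rng.uniform(0, 10, 12)
        m = RBFNetwork(n_centers=12, fixed_width=0.05, ridge=1e-12,
                       normalize=False, seed=0).fit(X, y)
        assert np.max(np.abs(m.predict(X) - y)) < 1e-6

    def test_single_center_manual_network(self):
        m = RBFNetwork(normalize=False)
        m.centers_ = np.zeros((1, 4))
        m.widths_ = np.array([1.0])
        m.weights_ = np.array([1.0])
        m.bias_ = 0.0
        assert m.predict([[0.0, 0, 0, 0]]) == pytest.approx([1.0])
        assert m.predict([[1.0, 0, 0, 0]]) == pytest.approx([np.exp(-0.5)])

    def test_weight_solve_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X, y = rng.random((6, 4)), rng.random(6)
        m = RBFNetwork(n_centers=3, ridge=1e-8, normalize=False, seed=0).fit(X, y)
        phi = np.hstack([m._design(m.scaler.apply(X) if m.scaler else X),
                         np.ones((6, 1))])
        A = phi.T @ phi + 1e-8 * np.eye(4)
        coef = np.linalg.lstsq(A, phi.T @ y, rcond=None)[0]  # independent solver
        assert np.append(m.weights_, m.bias_) == pytest.approx(coef, abs=1e-8)

    def test_too_many_centers_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="n_centers"):
            RBFNetwork(n_centers=10, normalize=False).fit(rng.random((5, 4)), rng.random(5))


class TestMLP:
    def test_zeroed_output_layer_predicts_zero_without_training(self):
        m = MLP(TrainingConfig(seed=0), normalize=False)
        rng = np.random.default_rng(0)
        X = rng.random((5, 4))
        m._init_weights(4, rng)
        m.W2 = np.zeros_like(m.W2)
        m.b2 = 0.0
        loss, _ = m._loss_and_grads(X, np.zeros(5))
        assert loss == 0.0
        _, yhat = m._forward(X)
        assert np.all(yhat == 0)

    def test_analytic_gradient_matches_finite_differences(self):
        m = MLP(TrainingConfig(seed=1), normalize=False)
        rng = np.random.default_rng(1)
        X, y = rng.random((3, 4)), rng.normal(size=3)
        m._init_weights(4, rng)
        _, (gW1, gb1, gW2, gb2) = m._loss_and_grads(X, y)
        eps = 1e-6

        def loss_with(attr, idx, delta):
            arr = getattr(m, attr)
            orig = arr[idx] if np.ndim(arr) else arr
            if np.ndim(arr):
                arr[idx] = orig + delta
            else:
                setattr(m, attr, orig + delta)
            val, _ = m._loss_and_grads(X, y)
            if np.ndim(arr):
                arr[idx] = orig
            else:
                setattr(m, attr, orig)
            return val

        checks = [("W1", (2, 17), gW1[2, 17]), ("W1", (0, 99), gW1[0, 99]),
                  ("b1", (5,), gb1[5]), ("W2", (33,), gW2[33]), ("b2", None, gb2)]
        for attr, idx, analytic in checks:
            num = (loss_with(attr, idx, eps) - loss_with(attr, idx, -eps)) / (2 * eps)
            assert analytic == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_fits_a_noiseless_linear_function(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 4))
        y = X[:, 0]
        m = MLP(TrainingConfig(seed=2), normalize=False).fit(X, y)
        assert rmse(y, m.predict(X)) < 0.05
        assert m.loss_history_[-1] <= m.loss_history_[0]

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = rng.random((30, 4)), rng.random(30)
        cfg = TrainingConfig(seed=7, epochs=50)
        a = MLP(cfg, normalize=False).fit(X, y).predict(X)
        b = MLP(TrainingConfig(seed=7, epochs=50), normalize=False).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_divergence_raises_with_advice(self):
        rng = np.random.default_rng(4)
        X, y = rng.random((30, 4)), rng.uniform(0, 100, 30)
        with pytest.raises(FloatingPointError, match="learning rate"):
            MLP(TrainingConfig(seed=0, learning_rate=1e4, epochs=50),
                normalize=False).fit(X, y)


class TestRecoveryAndComparison:
    @pytest.mark.parametrize("name", ["grnn", "rbf", "mlp"])
    def test_models_recover_a_noiseless_surface(self, dense_surface, name):
        """On clean data from a smooth surface every surrogate must excel."""
        reps, _ = dense_surface
        X = reps[["bap", "kin", "naa", "iba"]].to_numpy()
        y = reps["cfr"].to_numpy()
        sp = split_train_test(len(y), ratio=0.8, seed=0)
        model = make_model(name, seed=0)
        model.fit(X[sp.train], y[sp.train])
        assert r_squared(y[sp.test], model.predict(X[sp.test])) > 0.95

    def test_comparison_structure_and_winner(self, replicates):
        comp = compare_models(replicates, seed=1, model_names=("GRNN", "RBF"))
        assert len(comp.reports) == 2 * 2 * 2
        assert set(comp.best_model) == {"cfr", "cfw"}
        assert comp.get("GRNN", "cfr", "test").n > 0
        with pytest.raises(KeyError):
            comp.get("GRNN", "cfr", "validation")

    def test_treatment_aggregate_matches_printed_shape(self, replicates):
        Xa, ya = treatment_aggregate(replicates, "cfr")
        assert Xa.shape == (33, 4) and ya.shape == (33,)
        Xs, ys = treatment_aggregate(replicates, "cfr", idx=np.arange(7))
        assert Xs.shape == (1, 4)
        assert ys[0] == pytest.approx(replicates.cfr.iloc[:7].mean())

    def test_too_small_dataset_rejected(self, replicates):
        with pytest.raises(ValueError, match="20"):
            compare_models(replicates.head(10))
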
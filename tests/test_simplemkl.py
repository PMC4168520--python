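"""The MKL solver: inner QP, reduced gradient, line search, full fits."""

import numpy as np
import pytest

from conftest import grid_search_objective
from neuromkl.kernels import KernelSpec, build_bank, combine, default_specs
from neuromkl.simplemkl import (
    MKLModel,
    SolverSettings,
    decision_function,
    descent_direction,
    duality_gap,
    fit,
    line_search_update,
    load_model,
    objective_and_gradient,
    predict,
    save_model,
    svm_dual_solve,
)


class TestInnerQP:
    def test_two_point_symmetric_problem(self):
        # x = +1, -1 on the line with linear kernel: the 1-D feasible set
        # a1 = a2 gives the maximum at a = 0.5, zero bias.
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        y = np.array([1.0, -1.0])
        sol = svm_dual_solve(K, y, C=1000.0)
        np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-8)
        assert sol.b == pytest.approx(0.0, abs=1e-8)

    def test_kkt_constraints_hold(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        K = build_bank(X, [KernelSpec("rbf", width=1.0)]).grams[0]
        for C in (1.0, 100.0):
            sol = svm_dual_solve(K, y, C)
            assert abs(np.dot(sol.alpha, y)) < 1e-8
            assert sol.alpha.min() >= -1e-12 and sol.alpha.max() <= C + 1e-12

    def test_separable_data_no_margin_violations(self, separable_2class):
        X, y = separable_2class
        K = build_bank(X, [KernelSpec("poly", degree=1)]).grams[0]
        sol = svm_dual_solve(K, y.astype(float), C=1e6)
        margins = y * (K @ (sol.alpha * y) + sol.b)
        assert margins.min() >= 1.0 - 1e-6  # hinge loss zero in the separable limit

    def test_duplicate_support_point_keeps_objective(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        K5 = build_bank(X, [KernelSpec("rbf", width=1.0)], normalize=False).grams[0]
        base = svm_dual_solve(K5, y, C=10.0)
        X6 = np.vstack([X, X[0]])
        y6 = np.append(y, 1.0)
        K6 = build_bank(X6, [KernelSpec("rbf", width=1.0)], normalize=False).grams[0]
        dup = svm_dual_solve(K6, y6, C=10.0)
        assert dup.objective == pytest.approx(base.objective, abs=1e-6)

    def test_matches_reference_svm_scores(self, rng):
        # independent cross-check against libsvm via scikit-learn
        from sklearn.svm import SVC

        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        K = build_bank(X, [KernelSpec("rbf", width=1.5)]).grams[0]
        sol = svm_dual_solve(K, y, C=10.0)
        ref = SVC(kernel="precomputed", C=10.0, tol=1e-8).fit(K, y)
        mine = K @ (sol.alpha * y) + sol.b
        np.testing.assert_allclose(mine, ref.decision_function(K), atol=1e-4)

    def test_one_class_labels_raise(self):
        with pytest.raises(ValueError, match="single class"):
            svm_dual_solve(np.eye(3), np.ones(3), C=1.0)

    def test_nonsquare_kernel_raises(self):
        with pytest.raises(ValueError, match="square"):
            svm_dual_solve(np.ones((2, 3)), np.array([1.0, -1.0]), C=1.0)


class TestGradient:
    def test_zero_alpha_gives_zero(self, rng):
        from neuromkl.simplemkl import SVMDualSolution

        X = rng.normal(size=(4, 2))
        bank = build_bank(X, default_specs()[:2])
        dual = SVMDualSolution(np.zeros(4), 0.0, np.array([]), 1.0, 0.0)
        J, g = objective_and_gradient(dual, bank, np.array([1, -1, 1, -1.0]), np.array([0.5, 0.5]))
        assert J == 0.0
        np.testing.assert_array_equal(g, 0.0)

    def test_identity_kernel_worked_value(self):
        # n=2, alpha=(1,1), y=(+1,-1), K=I: g = -1/2 a'diag(y)Kdiag(y)a = -1
        from neuromkl.kernels import KernelBank
        from neuromkl.simplemkl import SVMDualSolution

        bank = KernelBank(
            specs=[KernelSpec("poly", degree=1)],
            grams=[np.eye(2)],
            n=2,
            X_train=np.zeros((2, 1)),
            scales=np.ones(1),
        )
        dual = SVMDualSolution(np.ones(2), 0.0, np.array([0, 1]), 2.0, 0.0)
        _, g = objective_and_gradient(dual, bank, np.array([1.0, -1.0]), np.array([1.0]))
        assert g[0] == pytest.approx(-1.0)

    def test_gradient_nonpositive_for_psd_kernels(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        bank = build_bank(X, default_specs())
        dual = svm_dual_solve(combine(bank, np.full(bank.M, 1 / bank.M)), y, 10.0)
        _, g = objective_and_gradient(dual, bank, y, np.full(bank.M, 1 / bank.M))
        assert np.all(g <= 1e-10)


class TestDescentDirection:
    def test_equal_partials_stationary(self):
        D = descent_direction(np.array([0.3, 0.7]), np.array([-2.0, -2.0]))
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_worked_two_kernel_case(self):
        # d=(0.5,0.5): mu = 0 (first maximum); D_1 = -g1+g0 = 2-1 = 1
        D = descent_direction(np.array([0.5, 0.5]), np.array([-1.0, -2.0]))
        np.testing.assert_allclose(D, [-1.0, 1.0])

    def test_direction_sums_to_zero(self, rng):
        for _ in range(20):
            d = rng.dirichlet(np.ones(5))
            g = rng.normal(size=5)
            assert descent_direction(d, g).sum() == pytest.approx(0.0, abs=1e-10)

    def test_zero_weight_with_adverse_gradient_frozen(self):
        d = np.array([0.0, 0.6, 0.4])
        g = np.array([5.0, -1.0, -1.0])  # raising d_0 would increase J
        D = descent_direction(d, g)
        assert D[0] == 0.0

    def test_off_simplex_raises(self):
        with pytest.raises(ValueError, match="simplex"):
            descent_direction(np.array([0.9, 0.9]), np.zeros(2))


class TestLineSearch:
    def test_zero_direction_keeps_weights(self, separable_2class):
        X, y = separable_2class
        bank = build_bank(X, default_specs()[:2])
        settings = SolverSettings(C=10.0)
        d = np.array([0.5, 0.5])
        d_new, _, _, moved = line_search_update(d, np.zeros(2), bank, y.astype(float), settings)
        assert not moved
        np.testing.assert_array_equal(d_new, d)

    def test_boundary_hit_zeroes_component(self, separable_2class):
        X, y = separable_2class
        bank = build_bank(X, default_specs()[:2])
        settings = SolverSettings(C=10.0)
        d = np.array([0.2, 0.8])
        D = np.array([-1.0, 1.0])
        d_new, _, J_new, moved = line_search_update(d, D, bank, y.astype(float), settings)
        assert abs(d_new.sum() - 1.0) < 1e-10 and d_new.min() >= 0.0
        if moved and d_new[0] == 0.0:
            assert d_new[1] == pytest.approx(1.0)


class TestDualityGap:
    def test_single_kernel_gap_zero(self, separable_2class):
        X, y = separable_2class
        bank = build_bank(X, [KernelSpec("rbf", width=1.0)])
        dual = svm_dual_solve(bank.grams[0], y.astype(float), 10.0)
        assert duality_gap(dual, bank, np.array([1.0]), y) == pytest.approx(0.0)

    def test_gap_matches_bruteforce_quadratic_forms(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.where(rng.random(10) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        bank = build_bank(X, default_specs()[:3])
        d = np.array([0.2, 0.5, 0.3])
        dual = svm_dual_solve(combine(bank, d), y, 10.0)
        ay = dual.alpha * y
        q = [ay @ K @ ay for K in bank.grams]
        expect = max(q) - np.dot(d, q)
        assert duality_gap(dual, bank, d, y) == pytest.approx(expect, abs=1e-12)


class TestFit:
    def test_matches_grid_search_oracle_small_instance(self, rng):
        X = rng.normal(size=(14, 2))
        y = np.where(rng.random(14) < 0.5, 1, -1)
        y[:2] = [1, -1]
        specs = [KernelSpec("rbf", width=1.0), KernelSpec("poly", degree=2)]
        model = fit(X, y, specs, SolverSettings(C=10.0, standardize=False))
        J_grid = grid_search_objective(model.bank, model.y_train, 10.0)
        assert model.J <= J_grid + 1e-3

    def test_noise_kernel_downweighted(self, separable_2class):
        X, y = separable_2class
        g = np.random.default_rng(5)
        X_noise = np.hstack([X[:, :1] * 0, g.normal(size=(len(y), 1))])
        # informative kernel on the real features, noise kernel on pure noise
        Xa = np.hstack([X, g.normal(size=(len(y), 1))])
        specs = [KernelSpec("rbf", width=2.0)]
        bank_inf = build_bank(Xa[:, :3], specs)
        bank_noise = build_bank(Xa[:, 3:], specs)
        from neuromkl.kernels import KernelBank

        bank = KernelBank(
            specs=specs * 2,
            grams=[bank_inf.grams[0], bank_noise.grams[0]],
            n=len(y),
            X_train=Xa,
            scales=np.ones(2),
        )
        settings = SolverSettings(C=10.0)
        d = np.array([0.5, 0.5])
        dual = svm_dual_solve(combine(bank, d), y.astype(float), 10.0)
        for _ in range(30):
            _, g_vec = objective_and_gradient(dual, bank, y.astype(float), d)
            D = descent_direction(d, g_vec)
            d, dual, _, moved = line_search_update(d, D, bank, y.astype(float), settings)
            if not moved:
                break
        assert d[0] > d[1]

    def test_simplex_and_monotonicity_invariants(self, rng):
        X = rng.normal(size=(24, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=24) > 0, 1, -1)
        y[:2] = [1, -1]
        model = fit(X, y, default_specs()[:5], SolverSettings(C=10.0))
        assert abs(model.d.sum() - 1.0) < 1e-10
        assert model.d.min() >= -1e-12
        diffs = np.diff(model.J_history)
        assert np.all(diffs <= 1e-9)
        if model.converged:
            ay = model.dual.alpha * model.y_train
            combined = sum(
                dm * (ay @ K @ ay) for dm, K in zip(model.d, model.bank.grams)
            )
            assert model.gap <= max(0.01 * abs(combined), 1e-4) + 1e-9

    def test_single_kernel_reduces_to_plain_svm(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        spec = [KernelSpec("rbf", width=2.0)]
        model = fit(X, y, spec, SolverSettings(C=10.0))
        X_test = rng.normal(size=(100, 3))
        scores = decision_function(model, X_test)
        # plain SVM: same standardization, same kernel, direct dual solve
        mean, std = model.feature_mean, model.feature_std
        Xs = (X - mean) / std
        bank = build_bank(Xs, spec)
        dual = svm_dual_solve(bank.grams[0], model.y_train, 10.0)
        Kt = bank.cross((X_test - mean) / std)[0]
        plain = Kt @ (dual.alpha * model.y_train) + dual.b
        np.testing.assert_allclose(scores, plain, atol=1e-6)

    def test_margin_sv_score_near_label(self, separable_2class):
        X, y = separable_2class
        model = fit(X, y, default_specs()[:4], SolverSettings(C=100.0))
        free = (model.dual.alpha > 1e-8) & (model.dual.alpha < 100.0 - 1e-8)
        if free.any():
            i = int(np.flatnonzero(free)[0])
            score = decision_function(model, X[i : i + 1])[0]
            assert score == pytest.approx(model.y_train[i], abs=1e-3)

    def test_predict_sign_convention(self, separable_2class):
        X, y = separable_2class
        model = fit(X, y, default_specs()[:3], SolverSettings(C=10.0))
        assert set(predict(model, X)) <= {-1, 1}
        assert np.mean(predict(model, X) == y) == 1.0

    def test_all_one_class_raises(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit(rng.normal(size=(6, 2)), np.ones(6), default_specs()[:2])

    def test_feature_dim_mismatch_on_predict(self, separable_2class):
        X, y = separable_2class
        model = fit(X, y, default_specs()[:2], SolverSettings(C=10.0))
        with pytest.raises(ValueError, match="dimension"):
            decision_function(model, np.ones((2, 5)))


class TestSerialization:
    def test_roundtrip_preserves_scores(self, separable_2class, tmp_path):
        X, y = separable_2class
        model = fit(X, y, default_specs()[:4], SolverSettings(C=10.0))
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        g = np.random.default_rng(2)
        X_test = g.normal(size=(20, 3))
        np.testing.assert_allclose(
            decision_function(model, X_test), decision_function(loaded, X_test), atol=1e-10
        )
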
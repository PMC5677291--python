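"""ELM / kernel-ELM algebra: closed forms, limits, equivalences."""
import numpy as np
import pytest

from stresskit.errors import InvalidArgumentError
from stresskit.kelm import (load_model, one_hot, rbf_kernel, save_model,
                            standardize, train_elm, train_kelm)


class TestRBFKernel:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(0).standard_normal((5, 3))
        K = rbf_kernel(x, x, gamma=0.7)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)

    def test_gamma_zero_all_ones(self):
        x = np.random.default_rng(1).standard_normal((4, 2))
        np.testing.assert_allclose(rbf_kernel(x, x, 0.0), 1.0)

    def test_unit_distance_closed_form(self):
        K = rbf_kernel(np.array([[0.0]]), np.array([[1.0]]), gamma=1.0)
        assert K[0, 0] == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            rbf_kernel(np.ones((2, 3)), np.ones((2, 4)), 1.0)


class TestELM:
    def test_separable_problem_fit(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)),
                       rng.normal(4, 0.3, (20, 4))])
        y = np.repeat([0, 1], 20)
        model = train_elm(X, y, L=50, C=1e3, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 4))
        y = rng.integers(0, 3, 15)
        a = train_elm(X, y, L=20, C=10.0, seed=7)
        b = train_elm(X, y, L=20, C=10.0, seed=7)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b, b.b)
        np.testing.assert_array_equal(a.B_hat, b.B_hat)

    def test_ridge_approaches_pseudoinverse(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 5))
        y = rng.integers(0, 3, 12)
        model = train_elm(X, y, L=30, C=1e12, seed=1)
        H = model.hidden(X)
        T = one_hot(y, np.unique(y))
        B_pinv = np.linalg.pinv(H) @ T
        rel = np.abs(model.B_hat - B_pinv).max() / np.abs(B_pinv).max()
        assert rel < 1e-6

    def test_wide_and_tall_solutions_agree(self):
        """The N-side and L-side ridge identities give the same weights."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        lo = train_elm(X, y, L=10, C=100.0, seed=2)   # L < N path
        H = lo.hidden(X)
        T = one_hot(y, np.unique(y))
        n_side = H.T @ np.linalg.solve(np.eye(30) / 100.0 + H @ H.T, T)
        np.testing.assert_allclose(lo.B_hat, n_side, atol=1e-8)

    def test_invalid_C(self):
        with pytest.raises(InvalidArgumentError):
            train_elm(np.ones((3, 2)), [0, 1, 0], L=5, C=0.0)


class TestKELM:
    def test_interpolation_limit_reproduces_onehot(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((3, 4))
        y = np.array([0, 1, 2])
        model = train_kelm(X, y, C=1e9, gamma=1.0)
        S = model.decision_scores(X)
        np.testing.assert_allclose(S, np.eye(3), atol=1e-4)

    def test_matches_elm_through_linear_kernel(self):
        """With the hidden map's inner-product kernel, K-ELM equals ELM."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            X = rng.standard_normal((n, 6))
            y = rng.integers(0, 4, n)
            if len(np.unique(y)) < 2:
                continue
            elm = train_elm(X, y, L=int(rng.integers(5, 30)), C=50.0, seed=3)
            H = elm.hidden(X)
            kelm = train_kelm(H, y, C=50.0, gamma=0.0, kernel="linear")
            np.testing.assert_allclose(elm.decision_scores(X),
                                       kelm.decision_scores(H), atol=1e-8)

    def test_single_training_point(self):
        model = train_kelm(np.array([[1.0, 2.0]]), ["MIS-S"], C=10.0,
                           gamma=0.5)
        s = model.decision_scores(np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert s.shape == (2, 1)
        assert model.predict(np.array([[9.0, 9.0]]))[0] == "MIS-S"

    def test_training_point_recovered_at_large_C(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 3))
        y = rng.integers(0, 3, 10)
        model = train_kelm(X, y, C=1e9, gamma=1.0)
        assert np.array_equal(model.predict(X), y)

    def test_large_gamma_nearest_neighbor(self):
        # gamma large enough that only the nearest training point's
        # kernel value survives (but not so large it underflows to 0)
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0, 1, 2])
        model = train_kelm(X, y, C=1e6, gamma=50.0)
        assert model.predict(np.array([[0.1], [1.9]])).tolist() == [0, 2]

    def test_tied_scores_take_lowest_class(self):
        # two duplicated training points with different labels and a
        # symmetric query produce exactly tied scores
        X = np.array([[-1.0], [1.0]])
        y = np.array([1, 0])
        model = train_kelm(X, y, C=1.0, gamma=0.3)
        assert model.predict(np.array([[0.0]]))[0] == 0

    def test_ridge_path_monotone_in_C(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 4))
        y = rng.integers(0, 3, 25)
        T = one_hot(y, np.unique(y))
        errs = []
        for C in (1e-2, 1e0, 1e2, 1e4):
            m = train_kelm(X, y, C=C, gamma=0.5)
            errs.append(np.sum((m.decision_scores(X) - T) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 4))
        y = rng.integers(0, 3, 20)
        perm = rng.permutation(20)
        a = train_kelm(X, y, C=10.0, gamma=0.5)
        b = train_kelm(X[perm], y[perm], C=10.0, gamma=0.5)
        np.testing.assert_allclose(a.alpha[perm], b.alpha, atol=1e-9)
        Q = rng.standard_normal((6, 4))
        np.testing.assert_allclose(a.decision_scores(Q),
                                   b.decision_scores(Q), atol=1e-9)

    def test_solve_equals_explicit_inverse(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 5))
        y = rng.integers(0, 4, 40)
        m = train_kelm(X, y, C=10.0, gamma=0.3)
        omega = rbf_kernel(X, X, 0.3)
        alpha_inv = np.linalg.inv(np.eye(40) / 10.0 + omega) @ one_hot(
            y, np.unique(y))
        np.testing.assert_allclose(m.alpha, alpha_inv, atol=1e-8)


class TestStandardize:
    def test_train_stats_applied(self):
        rng = np.random.default_rng(12)
        tr = rng.normal(5.0, 2.0, (50, 3))
        strain, _ = standardize(tr)
        np.testing.assert_allclose(strain.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(strain.std(axis=0, ddof=1), 1.0,
                                   atol=1e-12)

    def test_query_uses_train_statistics(self):
        tr = np.array([[0.0], [2.0]])
        q = np.array([[4.0]])
        _, sq = standardize(tr, q)
        # train mean 1, sd sqrt(2): query maps to (4-1)/sqrt(2)
        assert sq[0, 0] == pytest.approx(3.0 / np.sqrt(2.0))

    def test_constant_column_passes_through(self):
        tr = np.column_stack([np.ones(10), np.arange(10.0)])
        strain, sq = standardize(tr, tr)
        np.testing.assert_allclose(strain[:, 0], 0.0)
        assert np.all(np.isfinite(sq))


class TestSerialization:
    def test_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((15, 4))
        y = rng.integers(0, 3, 15)
        m = train_kelm(X, y, C=100.0, gamma=0.2,
                       standardize_features=True)
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.alpha, m.alpha)
        np.testing.assert_array_equal(back.X_train, m.X_train)
        Q = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(back.predict(Q), m.predict(Q).astype(str))
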
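import numpy as np
import pytest

from ufiberlab.rcca import (fit_rcca, grid_search_lambdas,
                            permutation_loading_cis)


def test_identity_pairing_perfect_correlation():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 3))
    res = fit_rcca(X, X.copy(), 0.0, 0.0)
    assert res.canonical_corr == pytest.approx(1.0, abs=1e-9)


def test_scalar_case_reduces_to_pearson():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(25, 1))
    y = 0.5 * x + rng.normal(size=(25, 1))
    res = fit_rcca(x, y, 0.0, 0.0)
    assert res.canonical_corr == pytest.approx(
        abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-9)


def test_matches_sklearn_cca_unregularized():
    from sklearn.cross_decomposition import CCA
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 3))
    Y = rng.normal(size=(40, 4)) + X[:, :1]
    res = fit_rcca(X, Y, 0.0, 0.0)
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    u, v = CCA(n_components=1).fit(Xs, Ys).transform(Xs, Ys)
    assert res.canonical_corr == pytest.approx(
        abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1]), abs=1e-6)


def test_matches_bruteforce_weight_grid():
    """n=20, p=2, q=3: dense scan over unit weight vectors."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 2))
    Y = rng.normal(size=(20, 3)) + 0.5 * X[:, :1]
    res = fit_rcca(X, Y, 0.0, 0.0)
    Xs = (X - X.mean(0)) / X.std(0)
    Ys = (Y - Y.mean(0)) / Y.std(0)
    best = 0.0
    thetas = np.linspace(0, np.pi, 400, endpoint=False)
    # unit b vectors from a spherical Fibonacci grid
    k = np.arange(20000)
    phi_g = np.arccos(1 - 2 * (k + 0.5) / 20000)
    lam_g = np.pi * (1 + 5**0.5) * k
    B = np.column_stack([np.sin(phi_g) * np.cos(lam_g),
                         np.sin(phi_g) * np.sin(lam_g), np.cos(phi_g)])
    V = Ys @ B.T
    V = V - V.mean(0)
    Vn = V / np.linalg.norm(V, axis=0)
    for th in thetas:
        u = Xs @ np.array([np.cos(th), np.sin(th)])
        u = u - u.mean()
        un = u / np.linalg.norm(u)
        best = max(best, np.abs(un @ Vn).max())
    assert res.canonical_corr == pytest.approx(best, abs=1e-3)


def test_sign_convention_and_variate_scaling():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 4))
    Y = rng.normal(size=(30, 5)) + X[:, :2] @ rng.normal(size=(2, 5)) * 0.5
    res = fit_rcca(X, Y, 0.1, 0.1)
    i = int(np.argmax(np.abs(res.u_weights)))
    assert res.u_weights[i] > 0
    assert np.std(res.U) == pytest.approx(1.0)
    assert np.std(res.V) == pytest.approx(1.0)
    assert np.corrcoef(res.U, res.V)[0, 1] >= 0
    assert np.all(np.abs(res.loadings_x) <= 1 + 1e-12)
    assert np.all(np.abs(res.loadings_y) <= 1 + 1e-12)


def test_canonical_corr_invariant_to_column_scaling():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(25, 3))
    Y = rng.normal(size=(25, 4)) + X[:, :1]
    base = fit_rcca(X, Y, 0.2, 0.2).canonical_corr
    X2 = X * np.array([10.0, 0.2, 3.0]) + np.array([5.0, -2.0, 0.0])
    Y2 = Y * np.array([0.5, 8.0, 1.0, 2.0]) - 7.0
    assert fit_rcca(X2, Y2, 0.2, 0.2).canonical_corr == pytest.approx(
        base, abs=1e-9)


def test_singular_unregularized_raises():
    rng = np.random.default_rng(6)
    with pytest.raises(np.linalg.LinAlgError, match="lambda"):
        fit_rcca(rng.normal(size=(10, 3)), rng.normal(size=(10, 50)), 0.0, 0.0)


def test_missing_values_rejected():
    X = np.zeros((10, 2))
    Y = np.zeros((10, 2))
    Y[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_rcca(X, Y, 0.1, 0.1)


class TestGridSearch:
    def test_single_pair_grid_returned_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 3))
        lam, res = grid_search_lambdas(X, Y, grid=[(0.7, 1.3)])
        assert lam == (0.7, 1.3)
        assert (res.lambda_x, res.lambda_y) == (0.7, 1.3)

    def test_recovers_planted_latent_factor(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(40, 1))
        X = np.hstack([z + 0.3 * rng.normal(size=(40, 2)),
                       rng.normal(size=(40, 3))])
        Y = z @ rng.normal(size=(1, 500)) * 0.5 + rng.normal(size=(40, 500)) * 0.5
        lam, res = grid_search_lambdas(X, Y, seed=0)
        assert res.cv_corr > 0.5

    def test_pure_noise_cv_near_zero(self):
        rng = np.random.default_rng(9)
        cvs = []
        for rep in range(8):
            X = rng.normal(size=(30, 4))
            Y = rng.normal(size=(30, 40))
            _, res = grid_search_lambdas(X, Y, seed=rep)
            cvs.append(res.cv_corr)
        assert abs(np.mean(cvs)) < 0.15

    def test_fold_size_guard(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="fold"):
            grid_search_lambdas(rng.normal(size=(8, 2)),
                                rng.normal(size=(8, 2)),
                                grid=[(0.1, 0.1), (1, 1)], k_folds=5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 20)) + X[:, :1]
        lam1, r1 = grid_search_lambdas(X, Y, seed=3)
        lam2, r2 = grid_search_lambdas(X, Y, seed=3)
        assert lam1 == lam2
        assert np.array_equal(r1.u_weights, r2.u_weights)


class TestPermutationCIs:
    def test_zero_permutations_noop(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 5))
        res = permutation_loading_cis(X, Y, (0.5, 0.5), n_perm=0)
        assert res.ci99_x is None
        base = fit_rcca(X, Y, 0.5, 0.5)
        assert np.array_equal(res.loadings_x, base.loadings_x)

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="permutations"):
            permutation_loading_cis(X, Y, (0.5, 0.5), n_perm=50)

    def test_planted_driver_flagged_with_negative_vertex_loadings(self):
        rng = np.random.default_rng(14)
        amp = rng.normal(size=60)
        X = np.column_stack([-amp + 0.3 * rng.normal(size=60),
                             rng.normal(size=(60, 5)).T.reshape(5, 60).T])
        Y = amp[:, None] * np.ones((1, 30)) + 0.3 * rng.normal(size=(60, 30))
        res = permutation_loading_cis(X, Y, (1.0, 1.0), n_perm=300, seed=0)
        flags = res.flagged_x()
        assert flags[0]
        assert flags[1:].sum() <= 1
        # negative anatomo-behavioral association shows on the vertex side
        assert np.all(res.loadings_y < 0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 10))
        a = permutation_loading_cis(X, Y, (1.0, 1.0), n_perm=150, seed=4)
        b = permutation_loading_cis(X, Y, (1.0, 1.0), n_perm=150, seed=4)
        assert np.array_equal(a.ci99_x, b.ci99_x)
        assert np.array_equal(a.ci99_y, b.ci99_y)
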
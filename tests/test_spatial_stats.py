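import numpy as np
import pytest
from scipy import stats

from fruitscape.spatial_stats import (
    build_weights,
    correlogram,
    modified_ttest,
    morans_i,
    sar_error_fit,
    vif,
)

from _oracles import brute_moran


def grid_centroids(side: int, spacing: float = 50.0) -> np.ndarray:
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([gx.ravel() * spacing, gy.ravel() * spacing])


def smooth_field(rng, side: int, scale: float = 0.15) -> np.ndarray:
    """Spatially autocorrelated Gaussian field on a side x side grid."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=(side, side)), sigma=side * scale,
                        mode="nearest")
    return (f / f.std()).ravel()


class TestWeights:
    def test_rook_neighbors_at_cell_distance(self):
        w = build_weights(grid_centroids(3), 50.0, style="binary")
        # interior cell (index 4) has 4 rook neighbors
        assert len(w.neighbors[4]) == 4
        assert len(w.neighbors[0]) == 2

    def test_queen_neighbors_at_diagonal_distance(self):
        w = build_weights(grid_centroids(3), 71.0, style="binary")
        assert len(w.neighbors[4]) == 8

    def test_row_standardized_interior_weights(self):
        w = build_weights(grid_centroids(3), 50.0)
        np.testing.assert_allclose(w.weights[4], 0.25)
        assert w.dense()[4].sum() == pytest.approx(1.0)

    def test_symmetric_before_standardization(self):
        pts = np.random.default_rng(0).uniform(0, 500, (40, 2))
        w = build_weights(pts, 150.0, style="binary")
        W = w.dense()
        np.testing.assert_array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_all_isolated_is_error(self):
        with pytest.raises(ValueError):
            build_weights(grid_centroids(3), 10.0)


class TestMoran:
    def test_checkerboard_is_minus_one(self):
        cents = grid_centroids(4)
        vals = ((cents[:, 0] / 50 + cents[:, 1] / 50) % 2 * 2 - 1).astype(float)
        w = build_weights(cents, 50.0, style="binary")
        res = morans_i(vals, w)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected == pytest.approx(-1 / 15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 400, (25, 2))
        vals = rng.normal(size=25)
        for style in ("binary", "row-standardized"):
            w = build_weights(pts, 180.0, style=style)
            assert morans_i(vals, w).I == pytest.approx(
                brute_moran(vals, w.dense()), abs=1e-12
            )

    def test_scale_and_shift_invariance(self, rng):
        cents = grid_centroids(5)
        vals = rng.normal(size=25)
        w = build_weights(cents, 50.0)
        a = morans_i(vals, w).I
        b = morans_i(2 * vals + 7, w).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_expectation_for_iid_values(self):
        rng = np.random.default_rng(5)
        cents = grid_centroids(20)
        w = build_weights(cents, 50.0)
        draws = [morans_i(rng.normal(size=400), w) for _ in range(20)]
        sd = np.sqrt(draws[0].variance)
        for d in draws:
            assert abs(d.I - (-1 / 399)) < 4 * sd

    def test_constant_vector_rejected(self):
        w = build_weights(grid_centroids(3), 50.0)
        with pytest.raises(ValueError):
            morans_i(np.ones(9), w)


class TestCorrelogram:
    def test_smooth_gradient_positive_first_class(self):
        cents = grid_centroids(10)
        vals = cents[:, 1] + 0.5 * cents[:, 0]
        cg = correlogram(vals, cents, n_classes=10)
        first_valid = cg.moran[~np.isnan(cg.moran)][0]
        assert first_valid > 0
        assert cg.crossed

    def test_iid_values_flagged_early(self):
        rng = np.random.default_rng(2)
        cents = grid_centroids(12)
        cg = correlogram(rng.normal(size=144), cents)
        # no positive-to-negative structure: crossing at/near the first class
        assert cg.zero_crossing_km <= cg.midpoints_km[2]

    def test_deterministic(self, rng):
        cents = grid_centroids(8)
        vals = rng.normal(size=64)
        a = correlogram(vals, cents)
        b = correlogram(vals, cents)
        np.testing.assert_array_equal(a.moran, b.moran)
        assert a.zero_crossing_km == b.zero_crossing_km


class TestModifiedT:
    def test_forced_identity_equals_classical(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        cents = rng.uniform(0, 500, (40, 2))
        res = modified_ttest(x, y, cents, force_identity=True)
        r_cl, p_cl = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_cl, abs=1e-12)
        assert res.p == pytest.approx(p_cl, abs=1e-10)
        assert res.df == pytest.approx(38)

    def test_iid_effective_size_near_n(self):
        rng = np.random.default_rng(8)
        cents = grid_centroids(17)  # n = 289
        n = len(cents)
        ms = []
        for _ in range(30):
            res = modified_ttest(rng.normal(size=n), rng.normal(size=n), cents)
            ms.append(res.m_hat)
        assert np.mean(ms) > 0.75 * n
        assert max(ms) <= 1.05 * n

    def test_smooth_gradients_shrink_effective_size(self):
        rng = np.random.default_rng(9)
        side = 15
        cents = grid_centroids(side)
        x = smooth_field(rng, side)
        y = smooth_field(rng, side)
        res = modified_ttest(x, y, cents)
        assert res.m_hat < 0.5 * len(cents)

    def test_identical_variables_flagged(self, rng):
        x = rng.normal(size=30)
        cents = rng.uniform(0, 500, (30, 2))
        res = modified_ttest(x, x, cents)
        assert res.p == 0.0
        assert res.flag == "perfect correlation"

    def test_constant_rejected(self, rng):
        cents = rng.uniform(0, 500, (30, 2))
        with pytest.raises(ValueError):
            modified_ttest(np.ones(30), rng.normal(size=30), cents)


def simulate_sar(rng, side=30, lam=0.7, beta=(0.2, 0.5, -0.3), sigma=0.3):
    cents = grid_centroids(side)
    n = side * side
    w = build_weights(cents, 50.0)
    W = w.dense()
    X = rng.normal(size=(n, 2))
    eps = rng.normal(0, sigma, n)
    u = np.linalg.solve(np.eye(n) - lam * W, eps)
    y = beta[0] + X @ np.array(beta[1:]) + u
    return X, y, w


class TestSAR:
    def test_zero_lambda_matches_ols(self):
        rng = np.random.default_rng(3)
        X, y, w = simulate_sar(rng, side=20, lam=0.0)
        fit = sar_error_fit(X, y, w)
        D = np.column_stack([np.ones(len(y)), X])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        assert abs(fit.lam) < 0.1
        assert np.max(np.abs(fit.coefficients - ols)) < 1e-2

    def test_parameter_recovery(self):
        rng = np.random.default_rng(17)
        X, y, w = simulate_sar(rng, side=30, lam=0.7, beta=(0.0, 0.5, -0.3))
        fit = sar_error_fit(X, y, w)
        assert 0.55 <= fit.lam <= 0.85
        assert abs(fit.coefficients[1] - 0.5) < 3 * fit.std_errors[1]
        assert abs(fit.coefficients[2] + 0.3) < 3 * fit.std_errors[2]

    def test_innovations_less_autocorrelated_than_ols_residuals(self):
        rng = np.random.default_rng(23)
        X, y, w = simulate_sar(rng, side=15, lam=0.6)
        fit = sar_error_fit(X, y, w)
        assert abs(fit.moran_sar_innovations.I) < abs(fit.moran_ols_residuals.I)

    def test_profile_maximality_and_ols_loglik_identity(self):
        rng = np.random.default_rng(29)
        X, y, w = simulate_sar(rng, side=12, lam=0.5)
        fit = sar_error_fit(X, y, w)
        # profile at lambda = 0 must equal the Gaussian OLS loglik exactly
        D = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        e = y - D @ beta
        s2 = e @ e / len(y)
        ll0 = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
        n = len(y)
        W = w.dense()
        eigs = np.linalg.eigvals(W).real

        def profile(lam):
            A = np.eye(n) - lam * W
            b = np.linalg.lstsq(A @ D, A @ y, rcond=None)[0]
            ee = A @ y - A @ D @ b
            return (-0.5 * n * (np.log(2 * np.pi * (ee @ ee / n)) + 1)
                    + np.sum(np.log(1 - lam * eigs)))

        assert profile(0.0) == pytest.approx(ll0, abs=1e-10)
        assert fit.loglik >= profile(0.0) - 1e-9


class TestVIF:
    def test_orthogonal_columns_unity(self):
        n = 64
        X = np.column_stack([
            np.tile([1, -1], n // 2),
            np.repeat([1, -1], n // 2),
        ]).astype(float)
        out = vif(X)
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in out.values())

    def test_bivariate_closed_form(self):
        # correlation exactly 0.8 -> VIF = 1 / (1 - 0.64)
        rng = np.random.default_rng(4)
        a = rng.normal(size=5000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        # orthogonalize to exact sample correlation 0.8
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        resid = b - (a @ b / len(a)) * a
        b_exact = 0.8 * a + np.sqrt(1 - 0.64) * resid / resid.std()
        out = vif(np.column_stack([a, b_exact]), names=["a", "b"])
        assert out["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-6)

    def test_duplicate_column_infinite(self, rng):
        x = rng.normal(size=50)
        out = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(out["x0"]) and np.isinf(out["x1"])
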
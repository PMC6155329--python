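import math

import numpy as np
import pytest

import chromou as co
from chromou.ou import LN2, _ou_correlation

from conftest import star_tree

LOG2PI = math.log(2 * math.pi)


class TestCovariances:
    def test_hand_evaluation_two_tips(self):
        tree = co.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        tm = co.time_matrices(tree)
        # alpha = 1 means t_half = ln 2; A-B share s = 0.5 at distance d = 1
        V = co.ou_covariance(tm, LN2 / 1.0, 1.0)
        assert V[0, 1] == pytest.approx(math.exp(-1) * (1 - math.exp(-1)), abs=1e-12)

    def test_strong_selection_limit_is_white_noise(self, yule):
        tm = co.time_matrices(yule(20, 1))
        V = co.ou_covariance(tm, 1e-4, 0.7)
        np.testing.assert_allclose(V, 0.7 * np.eye(20), atol=1e-12)

    def test_weak_selection_limit_is_brownian(self, yule):
        tm = co.time_matrices(yule(50, 2))
        t_half = 1e4
        v_y = 1.0
        sigma2 = 2 * (LN2 / t_half) * v_y
        V_ou = co.ou_covariance(tm, t_half, v_y)
        V_bm = co.bm_covariance(tm, sigma2)
        assert np.abs(V_ou - V_bm).max() < 1e-6

    def test_diagonal_formula(self, yule):
        tm = co.time_matrices(yule(10, 3))
        t_half = 0.3
        V = co.ou_covariance(tm, t_half, 0.5)
        alpha = LN2 / t_half
        np.testing.assert_allclose(
            np.diag(V), 0.5 * (1 - math.exp(-2 * alpha)), atol=1e-12
        )

    def test_bm_star_tree_diagonal(self):
        tm = co.time_matrices(star_tree(5))
        V = co.bm_covariance(tm, 2.0)
        np.testing.assert_allclose(V, 2.0 * np.eye(5))

    def test_bm_half_shared_time(self):
        tree = co.parse_newick("((A:0.5,B:0.5):0.5,C:1);")
        V = co.bm_covariance(co.time_matrices(tree), 2.0)
        assert V[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_bad_parameters_rejected(self, yule, bad):
        tm = co.time_matrices(yule(5, 4))
        with pytest.raises(ValueError):
            co.bm_covariance(tm, bad)
        with pytest.raises(ValueError):
            co.ou_covariance(tm, 0.5, bad)
        with pytest.raises(ValueError):
            co.ou_covariance(tm, bad, 0.5)


class TestObservationVariance:
    def test_zero_me_is_identity_operation(self):
        V = np.eye(3)
        np.testing.assert_array_equal(
            co.add_observation_variance(V, [0, 0, 0]), V
        )

    def test_diagonal_increment(self):
        V = np.eye(3)
        out = co.add_observation_variance(V, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(np.diag(out), [1.1, 1.2, 1.3])
        assert out[0, 1] == 0.0

    def test_psd_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.normal(size=(6, 6))
            V = A @ A.T
            me = rng.uniform(0, 1, 6)
            out = co.add_observation_variance(V, me)
            assert np.linalg.eigvalsh(out).min() > -1e-10

    def test_negative_me_rejected(self):
        with pytest.raises(ValueError):
            co.add_observation_variance(np.eye(2), [-0.1, 0.0])


class TestRhoFactor:
    def test_hand_value(self):
        assert co.rho_factor(LN2) == pytest.approx(1 - 0.5 / LN2, abs=1e-12)

    def test_limits(self):
        assert co.rho_factor(1e6) == pytest.approx(1.0, abs=1e-5)
        assert co.rho_factor(1e-8) == pytest.approx(0.0, abs=1e-7)

    def test_strictly_increasing(self):
        grid = np.geomspace(1e-4, 1e4, 1000)
        vals = np.array([co.rho_factor(a) for a in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            co.rho_factor(0.0)


class TestDesignMatrix:
    def test_intercept_is_ones(self, balanced4):
        X = co.design_matrix(co.ModelSpec("intercept_ou"), None, tree=balanced4)
        np.testing.assert_array_equal(X, np.ones((4, 1)))

    def test_single_regime_categorical_reduces_to_intercept(self, balanced4):
        p = co.fitch_reconstruct(balanced4, {t: "only" for t in balanced4.tip_labels})
        X = co.design_matrix(
            co.ModelSpec("categorical_ou", ("hl",)), 2.0, tree=balanced4, painting=p
        )
        np.testing.assert_allclose(X, np.ones((4, 1)), atol=1e-12)

    def test_continuous_strong_selection_is_raw_predictor(self):
        x = np.array([1.0, 2.0, 3.0])
        X = co.design_matrix(
            co.ModelSpec("continuous_ou", ("temp",)), 1e8, predictor=x, n=3
        )
        np.testing.assert_allclose(X[:, 1], x, rtol=1e-7)

    def test_ancova_column_count(self, balanced4):
        states = dict(zip(balanced4.tip_labels, ["u", "v", "u", "w"]))
        p = co.fitch_reconstruct(balanced4, states)
        X = co.design_matrix(
            co.ModelSpec("ancova_ou", ("hl", "temp")),
            1.0,
            tree=balanced4,
            painting=p,
            predictor=np.arange(4.0),
        )
        assert X.shape == (4, 3 + 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            co.design_matrix(
                co.ModelSpec("continuous_ou", ("temp",)),
                1.0,
                predictor=np.arange(3.0),
                n=5,
            )


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        beta, se, _ = co.gls_fit(X, y, np.eye(20))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_closed_form_bivariate_normal(self):
        # X = [1, 1], V = I, y = (1, 3): beta = 2, residuals (-1, 1)
        beta, se, ll = co.gls_fit(np.ones((2, 1)), np.array([1.0, 3.0]), np.eye(2))
        assert beta[0] == pytest.approx(2.0)
        assert ll == pytest.approx(-0.5 * (2 * LOG2PI + 0.0 + 2.0), abs=1e-12)

    def test_duplicated_column_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="collinear"):
            co.gls_fit(X, np.arange(5.0), np.eye(5))

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            co.gls_fit(np.ones((3, 1)), np.zeros(3), np.zeros((3, 3)))

    def test_shift_equivariance(self, yule):
        tree = yule(15, 8)
        tm = co.time_matrices(tree)
        V = co.ou_covariance(tm, 0.3, 0.5)
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        b1, _, _ = co.gls_fit(X, y, V)
        b2, _, _ = co.gls_fit(X, y + 5.0, V)
        assert b2[0] == pytest.approx(b1[0] + 5.0)
        assert b2[1] == pytest.approx(b1[1])


class TestFitModel:
    def test_recovery_on_moderate_inertia(self, yule):
        # single replicate sanity; the replicated version lives in the
        # acceptance suite
        tree = yule(150, 77)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        y = co.simulate_ou_trait(tree, paint, 0.25, 0.3, {"a": 3.4}, 78)
        fit = co.fit_model(tree, y, None, co.ModelSpec("intercept_ou"))
        assert 0.05 < fit.t_half < 1.5
        assert fit.support_lo <= fit.t_half <= fit.support_hi
        assert fit.k_params == 3
        assert fit.v_y > 0

    def test_white_noise_on_star_tree_hits_grid_floor(self):
        tree = star_tree(40)
        rng = np.random.default_rng(3)
        y = rng.normal(3.0, 0.5, 40)
        fit = co.fit_model(tree, y, None, co.ModelSpec("intercept_ou"))
        assert fit.boundary_warning is not None
        assert fit.t_half == pytest.approx(fit.grid.t_half_min)

    def test_support_region_contains_mle_and_grows_with_grid(self, yule):
        tree = yule(60, 9)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        y = co.simulate_ou_trait(tree, paint, 0.3, 0.2, {"a": 3.0}, 10)
        narrow = co.fit_model(
            tree, y, None, co.ModelSpec("intercept_ou"),
            grid=co.GridConfig(n_points=32, t_half_min=0.05, t_half_max=10.0),
        )
        wide = co.fit_model(
            tree, y, None, co.ModelSpec("intercept_ou"),
            grid=co.GridConfig(n_points=64, t_half_min=0.01, t_half_max=100.0),
        )
        for fit in (narrow, wide):
            if np.isfinite(fit.t_half):
                assert fit.support_lo <= fit.t_half <= fit.support_hi
        # interpolated endpoints are nearly grid-independent, so widening
        # the grid can only grow the region (up to interpolation error)
        assert wide.support_lo <= narrow.support_lo * 1.05
        hi_n = narrow.support_hi if np.isfinite(narrow.support_hi) else 10.0
        hi_w = wide.support_hi if np.isfinite(wide.support_hi) else 100.0
        assert hi_w >= hi_n * 0.95

    def test_slope_attenuation_invariant(self, yule):
        tree = yule(80, 11)
        pred = co.simulate_bm_trait(tree, 1.0, 12)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        y = co.simulate_ou_trait(tree, paint, 0.2, 0.3, {"a": 3.0}, 13)
        y = y + 0.3 * pred
        fit = co.fit_model(
            tree, y, None, co.ModelSpec("continuous_ou", ("p",)), predictor=pred
        )
        assert abs(fit.b_optimal) >= abs(fit.b_phylogenetic)
        assert fit.b_phylogenetic == pytest.approx(fit.rho * fit.b_optimal)
        assert fit.k_params == 4

    def test_intercept_ou_at_infinite_half_life_matches_bm_loglik(self, yule):
        tree = yule(40, 14)
        tm = co.time_matrices(tree)
        y = co.simulate_bm_trait(tree, 0.5, 15) + 3.0
        bm = co.fit_model(tree, y, None, co.ModelSpec("brownian"))
        t_half = 1e4
        v_y = bm.sigma2_bm / (2 * LN2 / t_half)
        V = co.ou_covariance(tm, t_half, v_y)
        _, _, ll = co.gls_fit(np.ones((40, 1)), y, V)
        assert ll == pytest.approx(bm.loglik, abs=1e-4)

    def test_observation_variance_changes_fit(self, yule):
        tree = yule(50, 16)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        y = co.simulate_ou_trait(tree, paint, 0.3, 0.2, {"a": 3.0}, 17)
        f0 = co.fit_model(tree, y, None, co.ModelSpec("intercept_ou"))
        f1 = co.fit_model(
            tree, y, np.full(50, 0.05), co.ModelSpec("intercept_ou")
        )
        assert f1.loglik != pytest.approx(f0.loglik)
        assert f1.v_y < f0.v_y  # part of the variance is explained by noise

    def test_tiny_tree_rejected(self):
        tree = co.parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            co.fit_model(tree, np.array([1.0, 2.0]), None, co.ModelSpec("intercept_ou"))

    def test_unscaled_tree_rejected(self):
        tree = co.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="unit-height"):
            co.fit_model(tree, np.arange(3.0), None, co.ModelSpec("intercept_ou"))


class TestRSquared:
    def test_null_model_zero(self, yule):
        tree = yule(10, 20)
        V = co.ou_covariance(co.time_matrices(tree), 0.3, 0.5)
        rng = np.random.default_rng(4)
        y = rng.normal(size=10)
        assert co.r_squared(np.ones((10, 1)), y, V) == pytest.approx(0.0)

    def test_perfect_fit_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), y])
        assert co.r_squared(X, y, np.eye(4)) == pytest.approx(1.0)

    def test_hand_computed_four_tip_example(self, balanced4):
        V = co.ou_covariance(co.time_matrices(balanced4), 0.4, 0.6)
        X = np.column_stack([np.ones(4), np.array([0.0, 1.0, 0.5, 2.0])])
        y = np.array([3.1, 3.4, 2.9, 3.8])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        ones = np.ones((4, 1))
        b0 = np.linalg.solve(ones.T @ Vi @ ones, ones.T @ Vi @ y)
        r0 = y - (ones @ b0)
        expected = 1 - (r @ Vi @ r) / (r0 @ Vi @ r0)
        assert co.r_squared(X, y, V) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            co.r_squared(np.ones((4, 1)), np.full(4, 2.0), np.eye(4))
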
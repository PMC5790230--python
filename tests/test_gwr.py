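"""GWR mechanics, diagnostics, forward selection and variation partitioning."""

import numpy as np
import pytest

from cropsuit.grids import GridSpec
from cropsuit.gwr import (
    GWRegressor,
    aicc,
    bisquare_weight,
    fit_ols,
    forward_select,
    gwr_vs_ols_ftest,
    municipality_suitability,
    variation_partition,
)


def simulate(n, rng, lat_slope=0.0, noise_sd=0.1):
    """Productivity-like data: y = 1 + (1 + lat_slope*lat) * x + noise."""
    coords = np.column_stack([rng.uniform(-60, -50, n), rng.uniform(-10, 0, n)])
    x = rng.normal(size=n)
    beta = 1.0 + lat_slope * coords[:, 1]
    y = 1.0 + beta * x + noise_sd * rng.normal(size=n)
    return x[:, None], y, coords, beta


class TestBisquare:
    @pytest.mark.parametrize("d, expected", [(0.0, 1.0), (5.0, 0.0), (2.5, 0.5625), (7.0, 0.0)])
    def test_closed_forms(self, d, expected):
        assert bisquare_weight(d, 5.0) == pytest.approx(expected)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            bisquare_weight(1.0, 0.0)


class TestAicc:
    def test_toy_closed_form(self):
        n, rss, v1 = 20, 5.0, 4.0
        sigma = np.sqrt(rss / n)
        expected = 2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + v1) / (n - 2 - v1)
        assert aicc(n, rss, v1) == pytest.approx(expected)

    def test_monotone_in_rss(self):
        assert aicc(20, 2.5, 4.0) < aicc(20, 5.0, 4.0)

    def test_overparameterized_signals(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            aicc(10, 1.0, 9.0)


class TestOlsLimit:
    def test_gwr_converges_to_statsmodels_ols(self, rng):
        """At huge bandwidth every local fit equals the global OLS fit."""
        import statsmodels.api as sm

        X, y, coords, _ = simulate(120, rng, lat_slope=0.2)
        gwr = GWRegressor(bandwidth=1e6).fit(X, y, coords)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            gwr.coef_local_, np.tile(ref.params, (120, 1)), atol=1e-6
        )
        assert gwr.r2_ == pytest.approx(ref.rsquared, abs=1e-6)
        assert gwr.v1_ == pytest.approx(2.0, abs=1e-6)
        ols = fit_ols(X, y)
        assert gwr.aicc_ == pytest.approx(ols.aicc, abs=1e-6)
        assert gwr.adj_r2_ == pytest.approx(ref.rsquared_adj, abs=1e-6)

    def test_ftest_near_zero_for_identical_fits(self, rng):
        X, y, coords, _ = simulate(80, rng)
        gwr = GWRegressor(bandwidth=1e6).fit(X, y, coords)
        F, p = gwr_vs_ols_ftest(gwr, fit_ols(X, y))
        assert F < 1e-3 or p > 0.99


class TestGWRFit:
    def test_parameter_recovery_latitude_varying_slope(self, rng):
        """Local slopes recover beta(u) = 1 + 0.1 * lat on simulated data."""
        X, y, coords, beta = simulate(400, rng, lat_slope=0.1, noise_sd=0.1)
        gwr = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        slopes = gwr.coef_local_[:, 1]
        fit = np.polyfit(coords[:, 1], slopes, 1)
        assert fit[0] == pytest.approx(0.1, abs=0.03)
        rho = np.corrcoef(
            np.argsort(np.argsort(slopes)), np.argsort(np.argsort(beta))
        )[0, 1]
        assert rho > 0.8

    def test_strong_nonstationarity_detected(self, rng):
        X, y, coords, _ = simulate(200, rng, lat_slope=0.3, noise_sd=0.1)
        gwr = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        _, p = gwr_vs_ols_ftest(gwr, fit_ols(X, y))
        assert p < 0.001

    def test_duplicated_observations_same_surface(self, rng):
        X, y, coords, _ = simulate(60, rng, lat_slope=0.2)
        a = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        b = GWRegressor(bandwidth=5.0).fit(
            np.vstack([X, X]), np.concatenate([y, y]), np.vstack([coords, coords])
        )
        np.testing.assert_allclose(a.coef_local_, b.coef_local_[:60], atol=1e-8)

    def test_permutation_invariance(self, rng):
        X, y, coords, _ = simulate(70, rng, lat_slope=0.2)
        perm = rng.permutation(70)
        a = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        b = GWRegressor(bandwidth=5.0).fit(X[perm], y[perm], coords[perm])
        np.testing.assert_allclose(a.coef_local_[perm], b.coef_local_, atol=1e-10)
        assert a.v1_ == pytest.approx(b.v1_)
        assert a.rss_ == pytest.approx(b.rss_)

    def test_local_r2_in_range_and_global_limit(self, rng):
        X, y, coords, _ = simulate(100, rng, lat_slope=0.2)
        gwr = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        assert np.nanmin(gwr.local_r2_) >= -1e-9
        assert np.nanmax(gwr.local_r2_) <= 1 + 1e-9
        wide = GWRegressor(bandwidth=1e6).fit(X, y, coords)
        np.testing.assert_allclose(wide.local_r2_, wide.r2_, atol=1e-6)

    def test_effective_params_between_p_and_n(self, rng):
        X, y, coords, _ = simulate(150, rng, lat_slope=0.2)
        gwr = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        assert 2.0 - 1e-9 <= gwr.v1_ <= 150
        assert gwr.adj_r2_ <= gwr.r2_

    def test_full_model_rss_never_exceeds_nested(self, rng):
        """Adding a covariate cannot worsen any local weighted fit."""
        X, y, coords, _ = simulate(120, rng, lat_slope=0.1)
        extra = rng.normal(size=(120, 1))
        nested = GWRegressor(bandwidth=5.0).fit(X, y, coords)
        full = GWRegressor(bandwidth=5.0).fit(np.hstack([X, extra]), y, coords)
        assert full.rss_ <= nested.rss_ + 1e-8

    def test_bandwidth_too_small_signals(self, rng):
        X, y, coords, _ = simulate(50, rng)
        with pytest.raises(ValueError, match="bandwidth too small"):
            GWRegressor(bandwidth=1e-6).fit(X, y, coords)


class TestForwardSelect:
    def test_true_predictor_found_first(self, rng):
        n = 500
        C = rng.normal(size=(n, 6))
        y = 1.0 + 2.0 * C[:, 3] + rng.normal(size=n)
        selected = forward_select(y, C)
        assert selected[0] == "x3"

    def test_pure_noise_selection_is_sparse(self, rng):
        """With 5 pure-noise candidates the AICc penalty (~2 per term) admits
        a first spurious term only when the best of five chi-square(1) gains
        exceeds it — about 57% of replicates — and almost never a second;
        selections stay sparse and a large minority are empty."""
        empties, n_selected = 0, []
        for _ in range(100):
            C = rng.normal(size=(300, 5))
            y = rng.normal(size=300)
            sel = forward_select(y, C)
            n_selected.append(len(sel))
            if not sel:
                empties += 1
        # P(empty) ~ P(chi2_1 < 2.04)^5 ~ 0.43; binomial 3 sigma ~ 0.15
        assert 28 <= empties <= 58
        assert np.mean(n_selected) < 1.5

    def test_duplicated_column_never_enters_after_original(self, rng):
        C = rng.normal(size=(200, 2))
        C = np.column_stack([C[:, 0], C[:, 0], C[:, 1]])
        y = 1 + C[:, 0] + 0.5 * C[:, 2] + 0.1 * rng.normal(size=200)
        selected = forward_select(y, C, names=["a", "a_dup", "b"])
        assert "a_dup" not in selected


class TestVariationPartition:
    def test_reconstructed_totals_worked_example(self):
        """Components from the printed totals: full model 0.30 with pure
        effects 0.05 (climate) and 0.11 (technology) imply component fits
        0.19 and 0.25 and a shared effect of 0.14."""
        part = variation_partition(0.30, 0.19, 0.25)
        assert part.pure_climate == pytest.approx(0.05)
        assert part.pure_technology == pytest.approx(0.11)
        assert part.shared == pytest.approx(0.14)
        assert part.pure_climate + part.pure_technology + part.shared == pytest.approx(
            part.r2_all
        )

    def test_orthogonal_predictors_share_nothing(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = a + b + 0.5 * rng.normal(size=n)
        part = variation_partition(
            fit_ols(np.column_stack([a, b]), y).adj_r2,
            fit_ols(a, y).adj_r2,
            fit_ols(b, y).adj_r2,
        )
        assert part.shared == pytest.approx(0.0, abs=0.05)

    def test_identical_groups_all_shared(self, rng):
        a = rng.normal(size=500)
        y = a + 0.3 * rng.normal(size=500)
        r2 = fit_ols(a, y).adj_r2
        part = variation_partition(r2, r2, r2)
        assert part.pure_climate == pytest.approx(0.0, abs=1e-12)
        assert part.shared == pytest.approx(r2)

    def test_local_closure_exact(self, rng):
        la, ls, lt = rng.random(50), rng.random(50), rng.random(50)
        part = variation_partition(0.3, 0.2, 0.25, la, ls, lt)
        total = (
            part.local["pure_climate"]
            + part.local["pure_technology"]
            + part.local["shared"]
        )
        # closure by construction: exact up to one float rounding step
        np.testing.assert_allclose(total, la, rtol=0, atol=1e-15)

    def test_negative_components_unclamped_but_clampable(self):
        part = variation_partition(0.3, 0.35, 0.2)
        assert part.pure_technology == pytest.approx(-0.05)
        assert part.clamped()["pure_technology"] == 0.0


class TestMunicipalitySuitability:
    def test_cell_center_lookup_and_shared_cell(self):
        grid = GridSpec(-60, 0, 0.5, 4, 4)
        suit = np.arange(16, dtype=float).reshape(4, 4)
        values, inside = municipality_suitability(
            suit, grid, [(-59.75, -0.25), (-59.8, -0.3), (-70.0, -0.25)]
        )
        assert values[0] == values[1] == 0.0
        assert not inside[2] and np.isnan(values[2])

    def test_consistent_with_snapping(self, rng):
        from cropsuit.grids import snap_to_grid

        grid = GridSpec(-60, 0, 0.5, 10, 10)
        suit = rng.random((10, 10))
        pts = np.column_stack([rng.uniform(-59.99, -55.01, 30), rng.uniform(-4.99, -0.01, 30)])
        values, inside = municipality_suitability(suit, grid, pts)
        assert inside.all()
        cells = snap_to_grid(pts, grid, collapse_duplicates=False)
        np.testing.assert_array_equal(values, suit[cells[:, 0], cells[:, 1]])
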
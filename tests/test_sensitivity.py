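import numpy as np
import pytest
import xarray as xr

from defocarb import (AGBClimateModel, apply_domain_filters,
                      collinearity_diagnostics, derived_covariates,
                      dry_biomass_to_carbon, make_field, vegc_to_agb)


def toy_model(map_v, mat_v, agb_v):
    return AGBClimateModel(np.asarray(agb_v, float), np.asarray(map_v, float),
                           np.asarray(mat_v, float))


def synthetic_cells(n, a=0.02, b=-0.3, c=10.0, noise=0.0, seed=0,
                    map_range=(100.0, 3100.0)):
    rng = np.random.default_rng(seed)
    map_v = rng.uniform(*map_range, n)
    mat_v = 28.0 - 2.0 * (map_v - map_range[0]) / np.ptp(map_range) \
        + rng.normal(0, 1.5, n)
    agb = c + a * map_v + b * mat_v + rng.normal(0, noise, n)
    return map_v, mat_v, agb


class TestConversions:
    @pytest.mark.parametrize("tc,expect", [(1.0, 80.0), (0.0, 40.0),
                                           (0.5, 60.0)])
    def test_vegc_to_agb_blend(self, tc, expect):
        vc = make_field([[100.0]], [0.0], [0.0], "vegc")
        out = vegc_to_agb(vc, xr.full_like(vc, tc))
        assert out.item() == pytest.approx(expect)

    def test_vegc_invalid_cover_rejected(self):
        vc = make_field([[100.0]], [0.0], [0.0], "vegc")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            vegc_to_agb(vc, xr.full_like(vc, 1.2))

    @pytest.mark.parametrize("dry,expect", [(100.0, 50.0), (0.0, 0.0),
                                            (37.0, 18.5)])
    def test_dry_biomass_factor(self, dry, expect):
        assert dry_biomass_to_carbon(dry) == pytest.approx(expect)

    def test_negative_dry_biomass_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            dry_biomass_to_carbon(-1.0)


class TestDomainFilters:
    def test_filters_applied(self, bundle):
        m = apply_domain_filters(bundle)
        map_v = bundle["MAP"].values[m.values]
        land = bundle["land_fraction"].values[m.values]
        assert map_v.min() >= 100.0
        assert land.min() >= 0.5

    def test_dry_and_ocean_cells_excluded(self):
        lat = np.array([0.0, 1.0])
        lon = np.array([0.0, 1.0])
        b = xr.Dataset({
            "MAP": make_field([[80.0, 2000.0], [2000.0, 2000.0]], lat, lon,
                              "MAP"),
            "MAT": make_field(np.full((2, 2), 25.0), lat, lon, "MAT"),
            "AGB": make_field(np.full((2, 2), 50.0), lat, lon, "AGB"),
            "land_fraction": make_field([[1.0, 0.4], [1.0, 1.0]], lat, lon,
                                        "lf"),
        })
        m = apply_domain_filters(b)
        assert not bool(m[0, 0])   # MAP 80 < 100
        assert not bool(m[0, 1])   # land 0.4 < 0.5
        assert bool(m[1, 0])


class TestGlobalRegression:
    def test_noiseless_exact_recovery(self):
        map_v, mat_v, agb = synthetic_cells(200, noise=0.0, seed=1)
        fit = toy_model(map_v, mat_v, agb).fit()
        assert fit.a == pytest.approx(0.02, abs=1e-10)
        assert fit.b == pytest.approx(-0.3, abs=1e-8)
        assert fit.intercept == pytest.approx(10.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_cell_normal_equations_oracle(self):
        """Coefficients match the closed-form solution of X'X beta = X'y
        computed independently."""
        map_v = np.array([500.0, 1500.0, 2500.0, 800.0])
        mat_v = np.array([28.0, 25.0, 23.0, 27.0])
        agb = np.array([12.0, 40.0, 75.0, 30.0])
        X = np.column_stack([np.ones(4), map_v, mat_v])
        beta = np.linalg.solve(X.T @ X, X.T @ agb)
        fit = AGBClimateModel(agb, map_v, mat_v)._ols(np.ones(4, bool))
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.a == pytest.approx(beta[1], rel=1e-9)
        assert fit.b == pytest.approx(beta[2], rel=1e-9)

    def test_default_bundle_recovers_linear_regime(self, bundle, default_cfg):
        m = AGBClimateModel.from_bundle(bundle,
                                        max_map=default_cfg.saturation_map)
        fit = m.fit()
        assert abs(fit.a * 100 - 3.4) < 2 * fit.se_a * 100
        assert abs(fit.b - (-0.32)) < 2 * fit.se_b

    def test_residuals_orthogonal_to_regressors(self, bundle):
        m = AGBClimateModel.from_bundle(bundle)
        fit = m.fit()
        resid = m.agb - (fit.intercept + fit.a * m.map + fit.b * m.mat)
        assert abs(resid @ m.map) / (np.linalg.norm(resid)
                                     * np.linalg.norm(m.map)) < 1e-8
        assert abs(resid @ m.mat) / (np.linalg.norm(resid)
                                     * np.linalg.norm(m.mat)) < 1e-8

    def test_relative_sensitivity_identity(self, bundle):
        fit = AGBClimateModel.from_bundle(bundle).fit()
        assert fit.delta_map == pytest.approx(1e4 * fit.a / fit.mean_agb)
        assert fit.delta_mat == pytest.approx(100 * fit.b / fit.mean_agb)

    def test_extra_covariate_never_reduces_r2(self, bundle):
        """Nesting property: augmenting the design with an extra covariate
        cannot lower R2 on data generated without it."""
        import statsmodels.api as sm
        m = AGBClimateModel.from_bundle(bundle)
        rng = np.random.default_rng(0)
        X2 = sm.add_constant(np.column_stack([m.map, m.mat]))
        X3 = np.column_stack([X2, rng.normal(size=m.n_cells)])
        r2_base = sm.OLS(m.agb, X2).fit().rsquared
        r2_aug = sm.OLS(m.agb, X3).fit().rsquared
        assert r2_aug >= r2_base - 1e-12

    def test_too_few_cells_rejected(self):
        map_v, mat_v, agb = synthetic_cells(10)
        with pytest.raises(ValueError, match="30 cells"):
            toy_model(map_v, mat_v, agb).fit()


class TestMovingWindow:
    def test_homogeneous_data_gives_flat_curve(self):
        map_v, mat_v, agb = synthetic_cells(4000, noise=1.0, seed=2)
        curve = toy_model(map_v, mat_v, agb).fit_moving_window()
        sig = curve.table[curve.table["significant"]]
        assert len(sig) > 10
        assert sig["a"].std() < 0.05 * abs(sig["a"].mean())

    def test_window_spanning_range_equals_global_fit(self, bundle):
        m = AGBClimateModel.from_bundle(bundle)
        fit = m.fit()
        curve = m.fit_moving_window(levels=[1500.0], half_width=1e7)
        row = curve.table.iloc[0]
        assert row["a"] == pytest.approx(fit.a, rel=1e-12)
        assert row["b"] == pytest.approx(fit.b, rel=1e-12)
        assert row["n_cells"] == fit.n_cells

    def test_saturating_bundle_loses_significance_when_wet(self, default_curve):
        t = default_curve.table
        assert not t[t["level"] >= 2500]["significant"].any()
        assert t[t["level"] <= 2000]["significant"].all()

    def test_piecewise_slope_peak_located(self):
        """With the rainfall slope doubled on [1500, 2000] mm, the curve
        maximum falls inside that band."""
        rng = np.random.default_rng(3)
        map_v = rng.uniform(100, 3100, 6000)
        mat_v = rng.normal(25, 2, 6000)
        a = 0.02
        agb = (10.0 + a * map_v - 0.3 * mat_v
               + a * (np.clip(map_v, 1500, 2000) - 1500.0)
               + rng.normal(0, 2, 6000))
        curve = toy_model(map_v, mat_v, agb).fit_moving_window()
        t = curve.table
        peak = t.loc[t["a"].idxmax(), "level"]
        assert 1500 <= peak <= 2000

    def test_small_windows_flagged_not_significant(self):
        map_v, mat_v, agb = synthetic_cells(60, noise=0.5, seed=4,
                                            map_range=(1000.0, 1200.0))
        curve = toy_model(map_v, mat_v, agb).fit_moving_window()
        far = curve.table[curve.table["level"] >= 2600]
        assert not far["significant"].any()


class TestCurveCsvRoundTrip:
    def test_round_trip(self, tmp_path, default_curve):
        p = tmp_path / "curve.csv"
        default_curve.to_csv(p)
        from defocarb import SensitivityCurve
        back = SensitivityCurve.from_csv(p)
        assert np.allclose(back.table["a"], default_curve.table["a"],
                           equal_nan=True)
        assert (back.table["significant"]
                == default_curve.table["significant"]).all()


class TestDerivedCovariates:
    def month_da(self, vals):
        return xr.DataArray(np.asarray(vals, float).reshape(12, 1, 1),
                            dims=("month", "lat", "lon"),
                            coords={"month": np.arange(1, 13),
                                    "lat": [0.0], "lon": [0.0]})

    def test_flat_seasonality(self):
        cov = derived_covariates(self.month_da([100.0] * 12),
                                 self.month_da([25.0] * 12))
        assert cov["Pamp"].item() == 0.0
        assert cov["PRD"].item() == 300.0
        assert cov["Tamp"].item() == 0.0
        assert cov["MAXT"].item() == 25.0

    def test_dry_quarter_brute_force(self):
        p = [0.0, 0.0, 0.0] + [200.0] * 9
        cov = derived_covariates(self.month_da(p), self.month_da([25.0] * 12))
        brute = min(sum(np.roll(p, -k)[:3]) for k in range(12))
        assert cov["PRD"].item() == brute == 0.0

    def test_temperature_amplitude(self):
        t = list(range(20, 32))
        cov = derived_covariates(self.month_da([100.0] * 12), self.month_da(t))
        assert cov["Tamp"].item() == 11.0
        assert cov["MAXT"].item() == 31.0

    def test_missing_month_rejected(self):
        p = self.month_da([100.0] * 12)
        with pytest.raises(ValueError, match="12 monthly"):
            derived_covariates(p.isel(month=slice(0, 11)), p)


class TestBelsleyDiagnostics:
    def test_orthogonal_columns_all_indices_one(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        d = collinearity_diagnostics(X)
        assert np.allclose(d["condition_indices"], 1.0)
        assert not d["collinear_sets"]

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        d = collinearity_diagnostics(np.column_stack([x, x]))
        assert d["condition_indices"].max() > 30
        assert d["collinear_sets"]
        assert d["collinear_sets"][0]["columns"] == [0, 1]

    def test_indices_match_independent_svd(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        y = 0.99 * x + np.sqrt(1 - 0.99 ** 2) * rng.normal(size=200)
        X = np.column_stack([x, y])
        d = collinearity_diagnostics(X)
        s = np.linalg.svd(X / np.linalg.norm(X, axis=0), compute_uv=False)
        assert np.allclose(sorted(d["condition_indices"]), sorted(s[0] / s))

    def test_variance_proportions_sum_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        d = collinearity_diagnostics(X)
        assert np.allclose(d["variance_proportions"].sum(axis=0), 1.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            collinearity_diagnostics(np.column_stack([np.zeros(5),
                                                      np.ones(5)]))
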
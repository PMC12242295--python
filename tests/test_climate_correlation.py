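"""Seasonal/depth averaging, point-correlation maps, EMC re-tests, OLS."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import scleropipe.climate_correlation as cc
from scleropipe.spectral import SurrogateSpec

from conftest import ar1_series


def monthly_field(values, depth=None, lat=(59.0,), lon=(0.0,),
                  start="1970-01-01", periods=None):
    periods = periods or values.shape[0]
    time = pd.date_range(start, periods=periods, freq="MS")
    coords = {"time": time, "lat": list(lat), "lon": list(lon)}
    dims = ["time", "lat", "lon"]
    if depth is not None:
        coords["depth"] = list(depth)
        dims = ["time", "depth", "lat", "lon"]
    return xr.DataArray(values, coords=coords, dims=dims, name="temperature")


class TestSeasonalMean:
    def test_constant_field(self):
        v = np.full((120, 1, 1), 4.5)
        ann = cc.seasonal_mean(monthly_field(v), cc.SeasonSpec(months=(6, 7, 8)))
        np.testing.assert_allclose(ann.to_numpy(), 4.5)

    def test_djf_cross_year_assignment(self):
        time = pd.date_range("1970-01-01", periods=360, freq="MS")
        v = time.month.to_numpy(float)[:, None, None] * np.ones((1, 1, 1))
        ann = cc.seasonal_mean(
            monthly_field(v, periods=360),
            cc.SeasonSpec(months=cc.SEASONS["DJF"]),
        )
        # December belongs to the January year: (12 + 1 + 2) / 3 = 5
        np.testing.assert_allclose(ann.to_numpy(), 5.0)
        assert int(ann["year"].min()) == 1971  # 1970 lacks Dec 1969

    def test_equal_thickness_depth_average(self):
        v = np.zeros((24, 2, 1, 1))
        v[:, 0], v[:, 1] = 2.0, 4.0
        ann = cc.seasonal_mean(
            monthly_field(v, depth=(5.0, 15.0)),
            cc.SeasonSpec(months=(7,), depth_range=(0, 20)),
        )
        np.testing.assert_allclose(ann.to_numpy(), 3.0)

    def test_single_level_selection(self):
        v = np.zeros((24, 3, 1, 1))
        v[:, 0], v[:, 1], v[:, 2] = 1.0, 2.0, 3.0
        ann = cc.seasonal_mean(
            monthly_field(v, depth=(5.0, 35.0, 100.0)),
            cc.SeasonSpec(months=(7,), depth_range=(35, 35)),
        )
        np.testing.assert_allclose(ann.to_numpy(), 2.0)

    def test_empty_depth_intersection_names_levels(self):
        v = np.zeros((24, 2, 1, 1))
        fld = monthly_field(v, depth=(5.0, 15.0))
        with pytest.raises(ValueError, match="levels"):
            cc.seasonal_mean(
                fld, cc.SeasonSpec(months=(7,), depth_range=(500, 600))
            )

    def test_commutes_with_spatial_subsetting(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((48, 2, 3))
        fld = monthly_field(v, lat=(58.0, 59.0), lon=(0.0, 1.0, 2.0))
        spec = cc.SeasonSpec(months=(6, 7, 8))
        whole = cc.seasonal_mean(fld, spec).sel(lat=59.0, lon=1.0)
        part = cc.seasonal_mean(fld.sel(lat=[59.0], lon=[1.0]), spec)
        np.testing.assert_allclose(whole.to_numpy().ravel(),
                                   part.to_numpy().ravel())


class TestPointCorrelationMap:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.years = np.arange(1970, 2019)
        self.chron = pd.Series(
            ar1_series(self.rng, self.years.size, phi=0.3), index=self.years
        )

    def annual_field(self, values):
        return xr.DataArray(
            values,
            coords={"year": self.years, "lat": np.arange(values.shape[1], dtype=float),
                    "lon": np.arange(values.shape[2], dtype=float)},
            dims=("year", "lat", "lon"),
        )

    def test_identical_cell_perfect_correlation(self):
        v = self.rng.standard_normal((self.years.size, 2, 2))
        v[:, 0, 0] = self.chron.to_numpy()
        cmap = cc.point_correlation_map(self.chron, self.annual_field(v))
        assert float(cmap["r"][0, 0]) == pytest.approx(1.0)
        assert float(cmap["p"][0, 0]) < 1e-20

    def test_embedded_signal_cell_is_argmax(self):
        v = self.rng.standard_normal((self.years.size, 4, 5))
        v[:, 2, 3] = self.chron.to_numpy() + 0.7 * self.rng.standard_normal(
            self.years.size
        )
        cmap = cc.point_correlation_map(self.chron, self.annual_field(v))
        am = np.unravel_index(np.nanargmax(np.abs(cmap["r"].to_numpy())),
                              cmap["r"].shape)
        assert am == (2, 3)

    def test_independent_field_false_positive_rate(self):
        hits = total = 0
        for _ in range(8):
            v = self.rng.standard_normal((self.years.size, 6, 6))
            cmap = cc.point_correlation_map(self.chron, self.annual_field(v))
            hits += int((cmap["p"].to_numpy() < 0.05).sum())
            total += cmap["p"].size
        assert 0.02 <= hits / total <= 0.09

    def test_invariance_to_affine_rescaling(self):
        v = self.rng.standard_normal((self.years.size, 2, 2))
        f1 = self.annual_field(v)
        f2 = self.annual_field(3.0 * v + 7.0)
        c1 = cc.point_correlation_map(self.chron, f1)
        c2 = cc.point_correlation_map(2.0 * self.chron + 1.0, f2)
        np.testing.assert_allclose(c1["r"].to_numpy(), c2["r"].to_numpy(),
                                   atol=1e-12)

    def test_period_restriction(self):
        v = self.rng.standard_normal((self.years.size, 1, 1))
        cmap = cc.point_correlation_map(
            self.chron, self.annual_field(v), period=(1990, 2010)
        )
        assert float(cmap["n"][0, 0]) == 21

    def test_insufficient_coverage_errors(self):
        v = self.rng.standard_normal((self.years.size, 1, 1))
        short = self.chron.iloc[:5]
        with pytest.raises(ValueError):
            cc.point_correlation_map(short, self.annual_field(v))


class TestEmcCellTest:
    def test_autocorrelated_null_saved_by_emc(self):
        """Strongly autocorrelated but independent series: the regression
        p-value over-rejects, and the EMC re-test disagrees with it more
        often than the nominal rate would allow."""
        rng = np.random.default_rng(2)
        years = np.arange(1950, 2020)
        n_trials, reg_hits, emc_saves = 60, 0, 0
        for i in range(n_trials):
            x = pd.Series(ar1_series(rng, years.size, phi=0.9), index=years)
            y = pd.Series(ar1_series(rng, years.size, phi=0.9), index=years)
            from scipy import stats as sst

            p_reg = sst.pearsonr(x, y)[1]
            if p_reg < 0.05:
                reg_hits += 1
                _, p_emc = cc.emc_cell_test(
                    x, y, SurrogateSpec(n_surrogates=300, seed=i)
                )
                emc_saves += p_emc > 0.05
        assert reg_hits / n_trials > 0.10  # naive test over-rejects
        assert emc_saves / max(reg_hits, 1) > 0.5  # EMC mostly disagrees

    def test_true_signal_passes_both(self):
        rng = np.random.default_rng(5)
        years = np.arange(1950, 2020)
        x = pd.Series(ar1_series(rng, years.size, phi=0.5), index=years)
        y = x + 0.5 * rng.standard_normal(years.size)
        r, p = cc.emc_cell_test(x, y, SurrogateSpec(n_surrogates=500, seed=9))
        assert r > 0.5 and p < 0.05


class TestMultipleRegression:
    def test_exact_predictor(self):
        years = np.arange(1970, 2019)
        rng = np.random.default_rng(1)
        x = pd.Series(rng.standard_normal(years.size), index=years)
        res = cc.multiple_regression(2 * x + 3, {"x": x})
        assert res.r_squared == pytest.approx(1.0)
        assert res.adj_r_squared == pytest.approx(1.0)

    def test_adjusted_r2_formula(self):
        years = np.arange(1970, 2019)  # n = 49
        rng = np.random.default_rng(2)
        y = pd.Series(rng.standard_normal(49), index=years)
        preds = {
            f"p{i}": pd.Series(rng.standard_normal(49), index=years)
            for i in range(4)
        }
        res = cc.multiple_regression(y, preds)
        manual = 1 - (1 - res.r_squared) * (49 - 1) / (49 - 4 - 1)
        assert res.adj_r_squared == pytest.approx(manual, abs=1e-12)
        assert res.adj_r_squared <= res.r_squared

    def test_collinearity_warns_with_vif(self):
        years = np.arange(1970, 2030)
        rng = np.random.default_rng(3)
        a = pd.Series(rng.standard_normal(60), index=years)
        b = a * 1.0001 + 1e-6 * rng.standard_normal(60)
        y = pd.Series(rng.standard_normal(60), index=years)
        with pytest.warns(UserWarning, match="collinear"):
            res = cc.multiple_regression(y, {"a": a, "b": b})
        assert res.vif is not None and (res.vif > 10).all()

    def test_too_few_cases_rejected(self):
        years = np.arange(2000, 2006)
        y = pd.Series(np.arange(6.0), index=years)
        preds = {f"p{i}": y * (i + 1) for i in range(3)}
        with pytest.raises(ValueError, match="complete cases"):
            cc.multiple_regression(y, preds)


class TestNetcdfIo:
    def test_round_trip_scipy_engine(self, tmp_path):
        v = np.random.default_rng(0).standard_normal((24, 2, 2, 2))
        fld = monthly_field(v, depth=(5.0, 15.0), lat=(58.0, 59.0),
                            lon=(0.0, 1.0))
        p = tmp_path / "f.nc"
        fld.to_dataset(name="temperature").to_netcdf(p, engine="scipy")
        back = cc.open_field(p, "temperature")
        np.testing.assert_allclose(back.to_numpy(), fld.to_numpy())
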
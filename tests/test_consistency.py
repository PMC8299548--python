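"""Temporal/spatial consistency: metric series, maps, climatology, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecvagree import (ClassificationConfig, GriddedStack, RegionSpec,
                      ScenarioConfig, compare_products, generate,
                      monthly_climatology, seasonal_mann_kendall,
                      spatial_agreement, temporal_agreement, zonal_mean)
from ecvagree.consistency import _kendall_s, classify_stacks, temporal_tables
from ecvagree.metrics import tabulate_codes


def make_stack(values, uncertainties, n_years=None, cell=0.01, var="lai",
               times=None):
    values = np.asarray(values, dtype=float)
    t, ny, nx = values.shape
    if times is None:
        times = pd.date_range("2015-01-01", periods=t, freq="10D")
    return GriddedStack(values=values, uncertainties=np.asarray(uncertainties, float),
                        times=times, lat=-10 + cell * np.arange(ny),
                        lon=20 + cell * np.arange(nx), cell_size=cell, variable=var)


class TestTemporalAgreement:
    def test_zero_noise_linked_region_has_constant_unit_oa(self, linked_noisefree, full_region):
        lai, fapar, lc, _ = linked_noisefree
        series = temporal_agreement(lai, fapar, full_region(lai))
        assert np.allclose(series["OA"].values, 1.0)
        assert np.allclose(series["processed_fraction"].values, 1.0)

    def test_sign_flip_fraction_recovered_per_step(self):
        """With all changes significant and a fraction p of FAPAR
        increments sign-flipped, the mean non-coherent fraction
        (n13+n31)/N matches p within binomial error."""
        p = 0.1
        sc = ScenarioConfig(seed=5, ny=32, nx=32, n_years=1, p_noncoherent=p,
                            noise_scale=0.0, uncertainty_scale=0.0)
        lai, fapar, lc, truth = generate(sc)
        lai = lai.time_slice("2010-05-01", "2010-08-21")
        fapar = fapar.time_slice("2010-05-01", "2010-08-21")
        region = RegionSpec("all", np.ones(lai.shape[1:], bool))
        series = temporal_agreement(lai, fapar, region)
        rate = 1 - series["OA"]  # off-diagonal here is purely n13+n31
        n_total = int(series["n"].sum())
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(rate.mean() - p) < 3 * se + 1e-3

    def test_single_pixel_region_matches_spatial_map(self, noisy_default):
        lai, fapar, lc, _ = noisy_default
        member = np.zeros(lai.shape[1:], bool)
        member[3, 4] = True
        series = temporal_agreement(lai, fapar, RegionSpec("px", member))
        counts = temporal_tables(lai, fapar, RegionSpec("px", member)).sum(axis=0)
        mp = spatial_agreement(lai, fapar)
        pooled_oa = np.trace(counts) / counts.sum()
        assert float(mp["OA"].values[3, 4]) == pytest.approx(pooled_oa)
        assert int(series["n"].sum()) == counts.sum()

    def test_empty_region_rejected(self, noisy_default):
        lai, *_ = noisy_default
        with pytest.raises(ValueError):
            RegionSpec("empty", np.zeros(lai.shape[1:], bool))

    def test_time_sum_of_regional_tables_equals_pooled_tabulation(self, noisy_default, full_region):
        """Aggregation consistency: per-step tables summed over time equal
        one tabulation of all (pixel, step) cases."""
        lai, fapar, lc, _ = noisy_default
        tables = temporal_tables(lai, fapar, full_region(lai))
        li, fi = classify_stacks(lai, fapar)
        pooled = tabulate_codes(li, fi)
        assert np.array_equal(tables.sum(axis=0), pooled.counts)


class TestSpatialAgreement:
    def test_constant_series_gives_unit_oa_everywhere(self):
        v = np.ones((8, 4, 4))
        stack_a = make_stack(v, 0.1 * np.ones_like(v))
        stack_b = make_stack(0.4 * v, 0.05 * np.ones_like(v), var="fapar")
        mp = spatial_agreement(stack_a, stack_b)
        assert np.allclose(mp["OA"].values, 1.0)  # all cases in n22

    def test_deterministic_coherent_seasonality_perfect_sensitivities(self, linked_noisefree):
        lai, fapar, lc, _ = linked_noisefree
        mp = spatial_agreement(lai, fapar)
        assert np.allclose(mp["OA"].values, 1.0)
        si = mp["Si"].values
        sd = mp["Sd"].values
        assert np.allclose(si[np.isfinite(si)], 1.0)
        assert np.allclose(sd[np.isfinite(sd)], 1.0)

    def test_map_mean_oa_consistent_with_temporal_mean(self, full_region):
        """For a stationary homogeneous process the spatial-map mean OA
        and the time-mean of the temporal OA series estimate the same
        quantity (both are ratios over the same case population)."""
        sc = ScenarioConfig(seed=31, ny=12, nx=12, n_years=3)
        lai, fapar, lc, _ = generate(sc)
        mp = spatial_agreement(lai, fapar)
        series = temporal_agreement(lai, fapar, full_region(lai))
        assert abs(np.nanmean(mp["OA"].values) - series["OA"].mean()) < 0.05


class TestClimatology:
    def test_flat_series_flat_profile(self):
        idx = pd.date_range("2015-01-01", periods=72, freq="10D")
        df = pd.DataFrame({"OA": np.full(72, 0.8)}, index=idx)
        clim = monthly_climatology(df)
        assert np.allclose(clim[("OA", "mean")].dropna(), 0.8)
        assert np.allclose(clim[("OA", "std")].dropna(), 0.0)

    def test_injected_winter_drop_located(self):
        idx = pd.date_range("2015-01-01", periods=108, freq="10D")
        oa = np.where(np.isin(idx.month, (12, 1, 2)), 0.4, 0.9)
        clim = monthly_climatology(pd.DataFrame({"OA": oa}, index=idx))
        means = clim[("OA", "mean")]
        assert set(means.nsmallest(3).index) == {12, 1, 2}

    def test_single_year_equals_that_year_with_zero_dispersion(self):
        idx = pd.date_range("2015-01-01", "2015-12-31", freq="10D")
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"OA": rng.uniform(0.5, 1.0, len(idx))}, index=idx)
        clim = monthly_climatology(df)
        expect = df.groupby(df.index.month).mean()["OA"]
        assert np.allclose(clim[("OA", "mean")], expect)
        assert np.allclose(clim[("OA", "std")].dropna(), 0.0)

    def test_short_record_rejected(self):
        idx = pd.date_range("2015-01-01", periods=10, freq="10D")
        with pytest.raises(ValueError):
            monthly_climatology(pd.DataFrame({"OA": np.ones(10)}, index=idx))


class TestSeasonalMannKendall:
    def test_strictly_increasing_series_detected(self):
        idx = pd.date_range("2014-01-01", periods=108, freq="10D")
        r = seasonal_mann_kendall(pd.Series(np.arange(108.0), index=idx))
        assert r.trend_sign == 1
        assert r.p_value < 1e-3

    def test_constant_series_no_trend(self):
        idx = pd.date_range("2014-01-01", periods=108, freq="10D")
        r = seasonal_mann_kendall(pd.Series(np.ones(108), index=idx))
        assert r.score == 0.0
        assert r.trend_sign == 0

    def test_seasonal_cycle_without_trend_not_flagged(self):
        idx = pd.date_range("2014-01-01", periods=144, freq="10D")
        cyc = np.sin(2 * np.pi * idx.dayofyear / 365)
        r = seasonal_mann_kendall(pd.Series(cyc, index=idx))
        assert r.trend_sign == 0

    def test_type_one_error_close_to_alpha(self):
        """White-noise rejection rate stays near the nominal 5% level."""
        rng = np.random.default_rng(99)
        idx = pd.date_range("2014-01-01", periods=108, freq="10D")
        rejections = sum(
            seasonal_mann_kendall(
                pd.Series(rng.standard_normal(108), index=idx)).trend_sign != 0
            for _ in range(400))
        rate = rejections / 400
        assert abs(rate - 0.05) < 0.03

    def test_trend_with_seasonality_power(self):
        """Linear trend of 2 sigma over the record under a seasonal cycle
        is detected in well over 90% of replicates."""
        rng = np.random.default_rng(7)
        idx = pd.date_range("2014-01-01", periods=108, freq="10D")
        cyc = np.sin(2 * np.pi * idx.dayofyear / 365)
        hits = 0
        for _ in range(200):
            y = cyc + np.linspace(0, 2.0, 108) + rng.standard_normal(108)
            if seasonal_mann_kendall(pd.Series(y, index=idx)).trend_sign == 1:
                hits += 1
        assert hits / 200 > 0.9

    def test_per_season_s_matches_scipy_kendalltau(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        s, var = _kendall_s(x)
        tau = stats.kendalltau(np.arange(30), x)
        assert s == pytest.approx(tau.statistic * (30 * 29 / 2))

    def test_short_record_rejected(self):
        idx = pd.date_range("2014-01-01", periods=36, freq="10D")
        with pytest.raises(ValueError):
            seasonal_mann_kendall(pd.Series(np.arange(36.0), index=idx))


class TestCompareProducts:
    def _maps(self, shift=0.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        import xarray as xr
        a = rng.normal(0.8, 0.05, (n, n))
        b = rng.normal(0.8 + shift, 0.05, (n, n))
        coords = {"lat": np.arange(n, dtype=float), "lon": np.arange(n, dtype=float)}
        return (xr.Dataset({"OA": (("lat", "lon"), a)}, coords=coords),
                xr.Dataset({"OA": (("lat", "lon"), b)}, coords=coords))

    def test_identical_maps(self):
        a, _ = self._maps()
        region = RegionSpec("all", np.ones((20, 20), bool))
        r = compare_products(a, a, region)
        assert r.ks_d == 0.0 and r.welch_t == 0.0

    def test_mean_shift_detected(self):
        a, b = self._maps(shift=0.1, seed=1, n=23)
        region = RegionSpec("all", np.ones((23, 23), bool))
        r = compare_products(a, b, region)
        assert r.welch_p < 1e-3 and r.ks_p < 1e-3

    def test_same_distribution_p_uniformity(self):
        """Under the null the Welch p-values are approximately uniform."""
        ps = []
        for s in range(200):
            a, b = self._maps(shift=0.0, seed=s, n=10)
            region = RegionSpec("all", np.ones((10, 10), bool))
            ps.append(compare_products(a, b, region).welch_p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_pixels_rejected(self):
        a, b = self._maps()
        member = np.zeros((20, 20), bool)
        member[0, 0] = True
        with pytest.raises(ValueError):
            compare_products(a, b, RegionSpec("one", member))


class TestZonalMean:
    def test_uniform_field(self):
        field = np.full((10, 4), 0.7)
        z = zonal_mean(field, lat=np.linspace(0, 0.9, 10), band_width=0.5)
        assert np.allclose(z.values, 0.7)

    def test_two_band_construction(self):
        lat = np.array([0.1, 0.2, 1.1, 1.2])
        field = np.array([[0.2], [0.2], [0.8], [0.8]])
        z = zonal_mean(field, lat=lat, band_width=1.0)
        assert z[0.0] == pytest.approx(0.2)
        assert z[1.0] == pytest.approx(0.8)

    def test_all_invalid_band_missing(self):
        lat = np.array([0.1, 1.1])
        field = np.array([[np.nan], [0.5]])
        z = zonal_mean(field, lat=lat, band_width=1.0)
        assert np.isnan(z[0.0]) and z[1.0] == 0.5
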
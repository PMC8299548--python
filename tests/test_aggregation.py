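"""Inverse-variance aggregation, majority resampling, multiscale metrics."""

import numpy as np
import pandas as pd
import pytest

from ecvagree import (AggregationSpec, GriddedStack, ScenarioConfig,
                      aggregate_uncertainty, generate, landcover_majority,
                      multiscale_agreement, weighted_aggregate)


def stack_from(values, uncerts, cell=0.01):
    values = np.asarray(values, float)
    t, ny, nx = values.shape
    return GriddedStack(values=values, uncertainties=np.asarray(uncerts, float),
                        times=pd.date_range("2012-01-01", periods=t, freq="10D"),
                        lat=cell * np.arange(ny), lon=cell * np.arange(nx),
                        cell_size=cell)


class TestWeightedAggregate:
    def test_equal_uncertainties_reduce_to_block_mean(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 3, (4, 6, 6))
        s = stack_from(v, np.full_like(v, 0.2))
        coarse = weighted_aggregate(s, AggregationSpec(0.03))
        expect = v.reshape(4, 2, 3, 2, 3).mean(axis=(2, 4))
        assert np.allclose(coarse.values, expect, atol=1e-12)

    def test_worked_two_pixel_cell(self):
        v = np.zeros((1, 1, 2))
        v[0, 0] = [0.2, 0.4]
        u = np.zeros((1, 1, 2))
        u[0, 0] = [0.1, 0.2]
        # pad to a 2x2 cell with invalid pixels
        values = np.full((1, 2, 2), np.nan)
        uncerts = np.full((1, 2, 2), np.nan)
        values[0, 0], uncerts[0, 0] = v[0, 0], u[0, 0]
        s = stack_from(values, uncerts)
        spec = AggregationSpec(0.02, min_valid_fraction=0.5)
        coarse = weighted_aggregate(s, spec)
        assert coarse.values[0, 0, 0] == pytest.approx((100 * 0.2 + 25 * 0.4) / 125)
        assert coarse.uncertainties[0, 0, 0] == pytest.approx(1 / np.sqrt(125))

    def test_single_valid_pixel_passes_through(self):
        values = np.full((1, 2, 2), np.nan)
        uncerts = np.full((1, 2, 2), np.nan)
        values[0, 1, 1] = 0.7
        uncerts[0, 1, 1] = 0.15
        s = stack_from(values, uncerts)
        coarse = weighted_aggregate(s, AggregationSpec(0.02, min_valid_fraction=0.25))
        assert coarse.values[0, 0, 0] == pytest.approx(0.7)
        assert coarse.uncertainties[0, 0, 0] == pytest.approx(0.15)

    def test_min_valid_fraction_invalidates_sparse_cells(self):
        values = np.full((1, 2, 2), np.nan)
        uncerts = np.full((1, 2, 2), np.nan)
        values[0, 0, 0] = 0.5
        uncerts[0, 0, 0] = 0.1
        s = stack_from(values, uncerts)
        coarse = weighted_aggregate(s, AggregationSpec(0.02, min_valid_fraction=0.5))
        assert not coarse.mask[0, 0, 0]

    def test_weighted_mean_bounded_by_contributors(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 5, (3, 8, 8))
        u = rng.uniform(0.01, 0.5, v.shape)
        s = stack_from(v, u)
        coarse = weighted_aggregate(s, AggregationSpec(0.04))
        blocks = v.reshape(3, 2, 4, 2, 4)
        lo = blocks.min(axis=(2, 4))
        hi = blocks.max(axis=(2, 4))
        assert np.all(coarse.values >= lo - 1e-12)
        assert np.all(coarse.values <= hi + 1e-12)

    def test_zero_uncertainty_floored_not_infinite(self):
        v = np.full((1, 2, 2), 1.0)
        u = np.zeros((1, 2, 2))
        s = stack_from(v, u)
        coarse = weighted_aggregate(s, AggregationSpec(0.02, eps=1e-6))
        assert np.isfinite(coarse.values[0, 0, 0])
        assert coarse.uncertainties[0, 0, 0] == pytest.approx(1e-6 / 2)

    def test_non_nesting_target_rejected(self):
        s = stack_from(np.ones((1, 6, 6)), np.ones((1, 6, 6)))
        with pytest.raises(ValueError):
            weighted_aggregate(s, AggregationSpec(0.025))


class TestAggregateUncertainty:
    def test_equal_uncertainty_closed_form(self):
        """n pixels of equal uncertainty delta give sigma = delta/sqrt(n)."""
        for f, delta in ((2, 0.3), (4, 0.12)):
            v = np.ones((1, f, f))
            s = stack_from(v, np.full_like(v, delta))
            sigma = aggregate_uncertainty(s, AggregationSpec(0.01 * f))
            assert sigma[0, 0, 0] == pytest.approx(delta / np.sqrt(f * f))

    def test_sigma_below_smallest_contributor(self):
        rng = np.random.default_rng(8)
        u = rng.uniform(0.05, 0.4, (2, 4, 4))
        s = stack_from(np.ones_like(u), u)
        sigma = aggregate_uncertainty(s, AggregationSpec(0.04))
        assert np.all(sigma <= u.reshape(2, 1, 4, 1, 4).min(axis=(2, 4)) + 1e-12)

    def test_sigma_strictly_decreases_with_added_pixels(self):
        base = np.full((1, 2, 2), 0.2)
        v = np.ones((1, 2, 2))
        full = stack_from(v, base)
        partial_vals = v.copy()
        partial_vals[0, 1, 1] = np.nan
        partial = stack_from(partial_vals, base)
        spec = AggregationSpec(0.02, min_valid_fraction=0.25)
        assert (aggregate_uncertainty(full, spec)[0, 0, 0]
                < aggregate_uncertainty(partial, spec)[0, 0, 0])


class TestLandcoverMajority:
    def test_uniform_block(self):
        lc = np.full((4, 4), 3, dtype=np.int16)
        out = landcover_majority(lc, AggregationSpec(0.02), 0.01)
        assert np.array_equal(out, np.full((2, 2), 3))

    def test_three_vs_one(self):
        lc = np.array([[1, 1], [1, 4]], dtype=np.int16)
        out = landcover_majority(lc, AggregationSpec(0.02), 0.01)
        assert out[0, 0] == 1

    def test_tie_breaks_to_smallest_code(self):
        lc = np.array([[4, 4], [2, 2]], dtype=np.int16)
        out = landcover_majority(lc, AggregationSpec(0.02), 0.01)
        assert out[0, 0] == 2

    def test_all_invalid_cell_comes_out_invalid(self):
        lc = np.zeros((2, 2), dtype=np.int16)
        out = landcover_majority(lc, AggregationSpec(0.02), 0.01)
        assert out[0, 0] == 0


class TestMultiscaleAgreement:
    def test_zero_noise_linked_products_perfect_at_every_resolution(self, linked_noisefree):
        lai, fapar, lc, _ = linked_noisefree
        specs = [AggregationSpec(0.02), AggregationSpec(0.04), AggregationSpec(0.08)]
        out = multiscale_agreement(lai, fapar, lc, specs)
        assert np.allclose(out["OA"].values, 1.0)
        assert set(out.index.get_level_values("cell_size")) == {0.02, 0.04, 0.08}

    def test_independent_noise_oa_improves_with_aggregation(self):
        """Averaging down independent pixel noise raises the chance both
        aggregated ECVs classify a step identically, so OA grows with the
        aggregation factor."""
        sc = ScenarioConfig(seed=41, ny=32, nx=32, n_years=2)
        lai, fapar, lc, _ = generate(sc)
        specs = [AggregationSpec(0.01), AggregationSpec(0.04), AggregationSpec(0.16)]
        out = multiscale_agreement(lai, fapar, lc, specs)
        oa = out.xs("all", level="stratum")["OA"]
        assert oa[0.16] > oa[0.01]

    def test_miscalibrated_stratum_loses_sensitivity_with_resolution(self):
        """Understated uncertainties on one stratum: after aggregation
        the propagated uncertainties shrink further while residual noise
        stays correlated with none, so the growing-season sensitivity of
        the miscalibrated stratum degrades relative to its fine-scale
        value rather than improving like the calibrated ones."""
        sc = ScenarioConfig(seed=43, ny=32, nx=32, n_years=2)
        lai, fapar, lc, _ = generate(sc)
        # overstate noise (x4) relative to stated uncertainty on stratum 2
        bad = lc == 2
        rng = np.random.default_rng(7)
        fapar.values[:, bad] += 3 * fapar.uncertainties[:, bad] * \
            rng.standard_normal(fapar.values[:, bad].shape)
        np.clip(fapar.values, 0, 1, out=fapar.values)
        specs = [AggregationSpec(0.01), AggregationSpec(0.08)]
        out = multiscale_agreement(lai, fapar, lc, specs,
                                   class_names={1: "c1", 2: "c2", 3: "c3", 4: "c4"})
        gain_bad = out.loc[(0.08, "c2"), "OA"] - out.loc[(0.01, "c2"), "OA"]
        gain_good = out.loc[(0.08, "c3"), "OA"] - out.loc[(0.01, "c3"), "OA"]
        assert out.loc[(0.08, "c2"), "OA"] < out.loc[(0.08, "c3"), "OA"]
        assert gain_bad < gain_good + 0.05
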
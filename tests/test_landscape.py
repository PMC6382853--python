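"""Synthetic landscape generation: gradients, noise, sampling, spread."""

import numpy as np
import pytest

from invasdm.geo import haversine_km
from invasdm.landscape import (LandscapeSpec, SpreadConfig, TrueSuitability,
                               VariableSpec, make_climate_rasters,
                               make_future_rasters, sample_occurrences,
                               simulate_spread)
from invasdm.raster import RasterStack


def spec_1var(**kw):
    var = VariableSpec("temp", direction="north", gradient=1.0, noise_amp=0.0)
    defaults = dict(n_rows=10, n_cols=10, variables=[var], seed=1)
    defaults.update(kw)
    return LandscapeSpec(**defaults)


def uniform_stack(n=20):
    return RasterStack(["temp"], np.zeros((1, n, n)), -100.0, -90.0, 30.0, 40.0)


class TestClimateRasters:
    def test_noise_free_gradient_is_column_constant_with_unit_row_steps(self):
        stack = make_climate_rasters(spec_1var())
        g = stack.band("temp")
        assert np.allclose(g, g[:, [0]])                   # column-constant
        assert np.allclose(np.diff(g[:, 0]), -1.0)         # +1 per cell northward

    def test_same_seed_reproduces_identical_rasters(self):
        var = VariableSpec("temp", gradient=0.5, noise_amp=1.0, noise_length=3)
        s = LandscapeSpec(n_rows=12, n_cols=12, variables=[var], seed=5)
        a = make_climate_rasters(s)
        b = make_climate_rasters(s)
        assert np.array_equal(a.values, b.values)

    def test_noise_field_is_spatially_correlated(self):
        var = VariableSpec("temp", gradient=0.0, noise_amp=1.0, noise_length=5)
        s = LandscapeSpec(n_rows=80, n_cols=80, variables=[var], seed=2)
        g = make_climate_rasters(s).band("temp")
        g = g - g.mean()

        def lag_corr(lag):
            a, b = g[:, :-lag].ravel(), g[:, lag:].ravel()
            return np.corrcoef(a, b)[0, 1]

        assert lag_corr(1) > lag_corr(10)
        assert lag_corr(1) > 0.5

    def test_duplicate_variable_names_rejected(self):
        vars_ = [VariableSpec("temp"), VariableSpec("temp")]
        with pytest.raises(ValueError, match="unique"):
            LandscapeSpec(variables=vars_)

    def test_unknown_direction_rejected(self):
        s = spec_1var(variables=[VariableSpec("t", direction="sideways")])
        with pytest.raises(ValueError, match="direction"):
            make_climate_rasters(s)


class TestSampleOccurrences:
    def test_zero_suitability_region_receives_no_points(self):
        stack = uniform_stack()
        suit = np.ones(stack.shape)
        suit[:, 10:] = 0.0                                  # right half barren
        occ = sample_occurrences(suit, stack, n=500, seed=3)
        _, cols = stack.lonlat_to_rowcol(occ.lon, occ.lat)
        assert (cols < 10).all()

    def test_uniform_suitability_fills_quadrants_evenly(self):
        stack = uniform_stack()
        occ = sample_occurrences(np.ones(stack.shape), stack, n=10_000, seed=4)
        rows, cols = stack.lonlat_to_rowcol(occ.lon, occ.lat)
        n, p = 10_000, 0.25
        se = np.sqrt(n * p * (1 - p))
        for q in [(rows < 10) & (cols < 10), (rows < 10) & (cols >= 10),
                  (rows >= 10) & (cols < 10), (rows >= 10) & (cols >= 10)]:
            assert abs(q.sum() - n * p) < 3 * se

    def test_dominant_bias_cell_captures_nearly_all_points(self):
        stack = uniform_stack()
        bias = np.full(stack.shape, 1e-5)
        bias[5, 5] = 1.0                                    # >99.6% of the weight
        occ = sample_occurrences(np.ones(stack.shape), stack, n=2000,
                                 bias=bias, seed=5)
        rows, cols = stack.lonlat_to_rowcol(occ.lon, occ.lat)
        assert np.mean((rows == 5) & (cols == 5)) > 0.99

    def test_cell_counts_follow_multinomial_law(self):
        from scipy.stats import chisquare
        stack = uniform_stack(8)
        rng = np.random.default_rng(6)
        suit = rng.uniform(0.2, 1.0, stack.shape)
        bias = rng.uniform(0.5, 1.5, stack.shape)
        n = 50_000
        occ = sample_occurrences(suit, stack, n=n, bias=bias, seed=6)
        rows, cols = stack.lonlat_to_rowcol(occ.lon, occ.lat)
        counts = np.zeros(stack.shape)
        np.add.at(counts, (rows, cols), 1)
        w = suit * bias
        res = chisquare(counts.ravel(), n * (w / w.sum()).ravel())
        assert res.pvalue > 0.01

    def test_all_zero_weights_rejected(self):
        stack = uniform_stack()
        with pytest.raises(ValueError, match="zero"):
            sample_occurrences(np.zeros(stack.shape), stack, n=10, seed=0)


class TestSimulateSpread:
    def kit(self, n=40):
        stack = RasterStack(["t"], np.zeros((1, n, n)), -100.0, -90.0, 30.0, 40.0)
        suit = np.ones(stack.shape)
        return stack, suit

    def test_wave_front_speed_bounded_by_truncated_kernel(self):
        stack, suit = self.kit()
        cfg = SpreadConfig(mode="wave", n_years=8, local_kernel_sd=20.0, seed=1)
        occ = simulate_spread(suit, stack, cfg, [(20, 20)])
        lon0, lat0 = stack.rowcol_to_lonlat(np.array([20]), np.array([20]))
        d = haversine_km(occ.lon, occ.lat, lon0[0], lat0[0])
        years = occ.year - cfg.start_year
        # per-hop bound: 3 SD plus one cell diagonal of rounding slack
        cell_diag = haversine_km(0, 34.875, stack.cell_width_deg,
                                 34.875 + stack.cell_height_deg)
        assert np.all(d <= years * (3 * cfg.local_kernel_sd + cell_diag) + cell_diag)

    def test_stratified_jumps_outrun_the_wave(self):
        stack, suit = self.kit(60)
        wave = SpreadConfig(mode="wave", n_years=10, local_kernel_sd=15.0, seed=2)
        strat = SpreadConfig(mode="stratified", n_years=10, local_kernel_sd=15.0,
                             jump_rate=0.2, jump_kernel_sd=400.0, seed=2)
        lon0, lat0 = stack.rowcol_to_lonlat(np.array([30]), np.array([30]))

        def max_dist(cfg):
            occ = simulate_spread(suit, stack, cfg, [(30, 30)])
            return haversine_km(occ.lon, occ.lat, lon0[0], lat0[0]).max()

        assert max_dist(strat) > max_dist(wave)

    def test_zero_jump_rate_reduces_stratified_to_wave(self):
        stack, suit = self.kit()
        wave = SpreadConfig(mode="wave", n_years=6, seed=3)
        strat0 = SpreadConfig(mode="stratified", n_years=6, jump_rate=0.0, seed=3)
        a = simulate_spread(suit, stack, wave, [(20, 20)])
        b = simulate_spread(suit, stack, strat0, [(20, 20)])
        assert a.records[["longitude", "latitude", "year"]].equals(
            b.records[["longitude", "latitude", "year"]])

    def test_founder_on_zero_suitability_rejected(self):
        stack, suit = self.kit()
        suit[0, 0] = 0.0
        cfg = SpreadConfig(n_years=2, seed=0)
        with pytest.raises(ValueError, match="suitability"):
            simulate_spread(suit, stack, cfg, [(0, 0)])

    def test_wave_mode_forces_zero_jump_rate(self):
        cfg = SpreadConfig(mode="wave", jump_rate=0.5)
        assert cfg.jump_rate == 0.0


class TestFutureRasters:
    def test_offset_applied_exactly_and_only_to_listed_variable(self, study):
        stack = study["stack"]
        fut = make_future_rasters(stack, {"temperature": 2.0})
        assert np.allclose(fut.band("temperature"),
                           stack.band("temperature") + 2.0, equal_nan=True)
        assert np.array_equal(fut.band("moisture"), stack.band("moisture"),
                              equal_nan=True)

    def test_empty_deltas_is_identity(self, study):
        fut = make_future_rasters(study["stack"], {})
        assert np.array_equal(fut.values, study["stack"].values, equal_nan=True)

    def test_offsets_compose_additively(self, study):
        twice = make_future_rasters(
            make_future_rasters(study["stack"], {"temperature": 1.0}),
            {"temperature": 1.0})
        once = make_future_rasters(study["stack"], {"temperature": 2.0})
        assert np.allclose(twice.values, once.values, equal_nan=True)

    def test_unknown_variable_rejected(self, study):
        with pytest.raises(KeyError):
            make_future_rasters(study["stack"], {"humidity": 1.0})
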
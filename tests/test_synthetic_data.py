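import numpy as np
import pytest
from scipy.stats import chisquare

from nichecast import GridSpec
from nichecast import synthetic_data as synth
from nichecast.data_io import TEMPERATURE_VARIABLES, VARIABLES
from nichecast.errors import ConfigError, DataError, GridError


class TestGenerateEnvStack:
    def test_seeded_reproducibility(self, grid):
        a = synth.generate_env_stack(grid, seed=5)
        b = synth.generate_env_stack(grid, seed=5)
        for name in VARIABLES:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_zero_noise_gives_deterministic_gradients(self, grid):
        st = synth.generate_env_stack(grid, seed=5, noise_sd=0.0)
        _, lat = grid.lon_lat_mesh()
        np.testing.assert_allclose(
            st.layers["temperature_mean"], 30.0 - 0.5 * (lat - 30.0)
        )
        np.testing.assert_allclose(
            st.layers["temperature_ltmax"] - st.layers["temperature_ltmin"], 12.0
        )

    def test_all_nine_variables_present(self, stack):
        assert set(stack.variable_names) == set(VARIABLES)

    def test_ltmin_below_mean_below_ltmax(self, stack):
        m = stack.mask
        assert np.all(
            stack.layers["temperature_ltmin"][m] < stack.layers["temperature_mean"][m]
        )
        assert np.all(
            stack.layers["temperature_mean"][m] < stack.layers["temperature_ltmax"][m]
        )

    def test_temperature_decreases_with_latitude_in_expectation(self, grid):
        st = synth.generate_env_stack(grid, seed=3)
        row_means = st.layers["temperature_mean"].mean(axis=1)
        slope = np.polyfit(grid.lats(), row_means, 1)[0]
        assert slope < -0.3

    def test_invalid_grid_rejected(self):
        with pytest.raises(GridError):
            GridSpec(0, 0, 0.05, -3, 10)

    def test_negative_noise_sd_rejected(self, grid):
        with pytest.raises(ConfigError):
            synth.generate_env_stack(grid, seed=1, noise_sd=-1.0)


class TestScenarios:
    def test_zero_offsets_identity(self, stack):
        spec = synth.ScenarioSpec("SSP1-1.9", "2030s", offsets={})
        out = synth.apply_scenario(stack, spec)
        for name in VARIABLES:
            np.testing.assert_array_equal(out.layers[name], stack.layers[name])

    def test_additive_offset_exact(self, stack):
        spec = synth.ScenarioSpec(
            "SSP2-4.5", "2060s", offsets={v: 3.0 for v in TEMPERATURE_VARIABLES}
        )
        out = synth.apply_scenario(stack, spec)
        m = stack.mask
        for v in TEMPERATURE_VARIABLES:
            np.testing.assert_allclose(out.layers[v][m] - stack.layers[v][m], 3.0)

    def test_severity_ordering_at_equal_period(self, stack):
        hot = synth.apply_scenario(stack, synth.default_scenario("SSP5-8.5", "2090s"))
        cool = synth.apply_scenario(stack, synth.default_scenario("SSP1-1.9", "2090s"))
        m = stack.mask
        assert np.all(
            hot.layers["temperature_mean"][m] >= cool.layers["temperature_mean"][m]
        )

    def test_period_monotonicity_within_scenario(self, stack):
        for scen in synth.SCENARIO_NAMES:
            offsets = [
                synth.default_scenario(scen, p).offsets["temperature_mean"]
                for p in synth.PERIODS
            ]
            assert offsets == sorted(offsets)

    def test_unknown_names_rejected(self):
        with pytest.raises(ConfigError):
            synth.default_scenario("RCP8.5", "2030s")
        with pytest.raises(ConfigError):
            synth.ScenarioSpec("SSP1-1.9", "2150s")

    def test_mask_unchanged(self, masked_stack):
        out = synth.apply_scenario(
            masked_stack, synth.default_scenario("SSP5-8.5", "2090s")
        )
        np.testing.assert_array_equal(out.mask, masked_stack.mask)


class TestBathymetryMask:
    def test_depth_rules(self, grid):
        turbid = (124.0, 33.4, 132.0, 34.0)
        depth, mask = synth.generate_bathymetry_and_mask(grid, seed=8, turbid_region=turbid)
        lon, lat = grid.lon_lat_mesh()
        in_turbid = (lat >= 33.4) & (lat <= 34.0)
        # deeper than 20 m -> masked everywhere
        assert not mask[depth > 20.0].any()
        # 5-20 m inside the turbid region -> masked; outside -> valid
        mid = (depth > 5.0) & (depth <= 20.0)
        assert not mask[mid & in_turbid].any()
        assert mask[mid & ~in_turbid].all()
        # shallow cells valid everywhere
        assert mask[depth <= 5.0].all()

    def test_seeded_determinism(self, grid):
        d1, m1 = synth.generate_bathymetry_and_mask(grid, seed=4)
        d2, m2 = synth.generate_bathymetry_and_mask(grid, seed=4)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(m1, m2)


class TestSampleOccurrences:
    def test_zero_suitability_cells_never_sampled(self, masked_stack):
        surf = synth.default_surface()
        suit = surf.evaluate(masked_stack)
        occ = synth.sample_occurrences(surf, masked_stack, n=500, seed=2)
        row, col = masked_stack.grid.cell_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy()
        )
        assert np.all(suit[row, col] > 0)
        assert masked_stack.mask[row, col].all()

    def test_same_seed_identical(self, masked_stack):
        surf = synth.default_surface()
        a = synth.sample_occurrences(surf, masked_stack, n=50, seed=9)
        b = synth.sample_occurrences(surf, masked_stack, n=50, seed=9)
        assert a.records.equals(b.records)

    def test_uniform_suitability_multinomial(self, grid):
        # constant truth => cell counts consistent with uniform multinomial
        st = synth.generate_env_stack(grid, seed=1)
        surf = synth.TrueSuitabilitySurface(
            driver_variables=(), intercept=0.0, linear={}, quadratic={}
        )
        occ = synth.sample_occurrences(surf, st, n=2000, seed=4)
        row, col = grid.cell_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy()
        )
        counts = np.zeros(grid.shape)
        np.add.at(counts, (row, col), 1)
        p = chisquare(counts.ravel()).pvalue
        assert p > 0.01

    def test_both_eras_represented(self, masked_stack):
        surf = synth.default_surface()
        occ = synth.sample_occurrences(surf, masked_stack, n=30, seed=11)
        assert set(occ.records["era"]) == {"past", "present"}

    def test_degenerate_surface_raises(self, stack):
        surf = synth.TrueSuitabilitySurface(
            driver_variables=(), intercept=-1e9, linear={}, quadratic={}
        )
        with pytest.raises(DataError):
            synth.sample_occurrences(surf, stack, n=10, seed=1)

    def test_empirical_frequencies_track_suitability(self, masked_stack):
        # Kolmogorov-style convergence check at n = 10^4
        surf = synth.default_surface()
        suit = surf.evaluate(masked_stack)
        occ = synth.sample_occurrences(surf, masked_stack, n=10_000, seed=21)
        row, col = masked_stack.grid.cell_of(
            occ.records["lon"].to_numpy(), occ.records["lat"].to_numpy()
        )
        counts = np.zeros(masked_stack.grid.shape)
        np.add.at(counts, (row, col), 1)
        m = masked_stack.mask
        expected = suit[m] / np.nansum(suit[m])
        observed = counts[m] / 10_000
        # sup-norm of the cumulative difference over the cell enumeration
        ks = np.abs(np.cumsum(observed - expected)).max()
        assert ks < 0.02


class TestSuitabilitySurface:
    def test_values_in_unit_interval(self, masked_stack):
        suit = synth.default_surface().evaluate(masked_stack)
        valid = suit[masked_stack.mask]
        assert np.all((valid >= 0) & (valid <= 1))

    def test_depends_only_on_drivers(self, masked_stack):
        surf = synth.default_surface()
        perturbed = masked_stack.with_layers(
            {
                k: (v + 5.0 if k not in surf.driver_variables else v)
                for k, v in masked_stack.layers.items()
            }
        )
        np.testing.assert_array_equal(
            surf.evaluate(masked_stack)[masked_stack.mask],
            surf.evaluate(perturbed)[masked_stack.mask],
        )

    def test_velocity_response_saturates_at_cap(self, masked_stack):
        surf = synth.default_surface(velocity_cap=0.7)
        bumped = masked_stack.with_layers(
            {
                k: (np.maximum(v, 0.9) if k == "velocity_mean" else v)
                for k, v in masked_stack.layers.items()
            }
        )
        more = masked_stack.with_layers(
            {
                k: (np.maximum(v, 1.5) if k == "velocity_mean" else v)
                for k, v in masked_stack.layers.items()
            }
        )
        np.testing.assert_array_equal(
            surf.evaluate(bumped)[masked_stack.mask],
            surf.evaluate(more)[masked_stack.mask],
        )


class TestMpaMask:
    def test_coverage_within_tolerance(self, masked_stack):
        grid = masked_stack.grid
        mask = synth.generate_mpa_mask(
            grid, seed=1, coverage_fraction=0.3, valid_mask=masked_stack.mask
        )
        frac = mask[masked_stack.mask].mean()
        assert 0.24 <= frac <= 0.36

    def test_seeded_determinism(self, grid):
        a = synth.generate_mpa_mask(grid, seed=2, coverage_fraction=0.2)
        b = synth.generate_mpa_mask(grid, seed=2, coverage_fraction=0.2)
        np.testing.assert_array_equal(a, b)

    def test_values_binary(self, grid):
        mask = synth.generate_mpa_mask(grid, seed=3, coverage_fraction=0.4)
        assert set(np.unique(mask)) <= {0, 1}

    def test_bad_coverage_rejected(self, grid):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ConfigError):
                synth.generate_mpa_mask(grid, seed=1, coverage_fraction=bad)

    def test_polygons_rasterize_consistently(self, grid):
        from nichecast.data_io import rasterize_polygons

        mask, polys = synth.generate_mpa_mask(
            grid, seed=5, coverage_fraction=0.2, return_polygons=True
        )
        assert np.array_equal(rasterize_polygons(polys, grid), mask)
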
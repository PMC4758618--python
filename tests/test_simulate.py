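"""Synthetic stack generator: rendering exactness, camera model, scenarios."""

import math

import numpy as np
import pytest

from kinquant import (ArmSpec, ConfigError, GenotypeScenario, OpticsModel,
                      VoxelGrid, apply_noise, get_scenario, render_focus,
                      scenario_library, simulate_arm, simulate_field)
from oracles import gaussian_quadrature_voxels


class TestRenderFocus:
    def test_zero_photons_leaves_grid_unchanged(self):
        grid = VoxelGrid(np.full((9, 32, 32), 7.0))
        before = grid.values.copy()
        render_focus(grid, (4, 16, 16), 0.0, 0.12, 0.35)
        np.testing.assert_array_equal(grid.values, before)

    @pytest.mark.parametrize("center,photons,sigma_xy,sigma_z", [
        ((8, 24, 24), 5000.0, 0.12, 0.35),
        ((8.4, 23.7, 24.2), 1234.5, 0.2, 0.5),
        ((6, 20, 28), 10.0, 0.12, 0.35),
    ])
    def test_mass_conservation_far_from_edges(self, center, photons, sigma_xy, sigma_z):
        """A focus >= 5 sigma from every edge deposits its full photon count."""
        grid = VoxelGrid(np.zeros((17, 48, 48)))
        before = grid.values.sum()
        render_focus(grid, center, photons, sigma_xy, sigma_z)
        added = grid.values.sum() - before
        assert added == pytest.approx(photons, rel=1e-3)

    def test_matches_fine_grid_quadrature(self):
        """Voxel-integrated rendering equals oversampled midpoint quadrature
        on a 7x7x5-voxel grid with sigma_xy = 1 px and sigma_z = 1 slice."""
        dx = dz = 1.0  # voxel units: sigma expressed directly in voxels
        grid = VoxelGrid(np.zeros((5, 7, 7)), dx=dx, dy=dx, dz=dz)
        photons = 1000.0
        center = (2.0, 3.0, 3.0)
        render_focus(grid, center, photons, sigma_xy=1.0, sigma_z=1.0)
        expected = gaussian_quadrature_voxels((5, 7, 7), center, photons,
                                              sigma_z_vox=1.0, sigma_xy_vox=1.0,
                                              oversample=256)
        np.testing.assert_allclose(grid.values, expected, rtol=1e-4, atol=1e-9)

    def test_invalid_parameters_raise(self):
        grid = VoxelGrid(np.zeros((9, 32, 32)))
        with pytest.raises(ConfigError):
            render_focus(grid, (4, 16, 16), -1.0, 0.12, 0.35)
        with pytest.raises(ConfigError):
            render_focus(grid, (4, 16, 16), 100.0, 0.0, 0.35)
        with pytest.raises(ConfigError):
            render_focus(grid, (4, 16, 160), 100.0, 0.12, 0.35)


class TestApplyNoise:
    def test_noise_disabled_is_rounding_only(self):
        optics = OpticsModel(photon_noise=False, read_noise_sd=0.0)
        grid = VoxelGrid(np.full((4, 32, 32), 41.4))
        noisy = apply_noise(grid, optics, seed=0)
        assert noisy.quantized
        np.testing.assert_array_equal(noisy.values, np.full((4, 32, 32), 41, np.uint16))

    def test_mean_of_draws_is_unbiased(self):
        optics = OpticsModel(photon_noise=True, read_noise_sd=2.0)
        v = 80.0
        grid = VoxelGrid(np.full((2, 32, 32), v))
        draws = [apply_noise(grid, optics, seed=s).values.mean() for s in range(1000)]
        n = 1000 * grid.values.size
        se = math.sqrt((v + optics.read_noise_sd ** 2) / n)
        assert np.mean(draws) == pytest.approx(v, abs=3 * se)

    def test_variance_is_poisson_plus_read_noise(self):
        """Monte-Carlo variance at level v approximates v + read_noise^2."""
        optics = OpticsModel(photon_noise=True, read_noise_sd=3.0)
        v = 120.0
        grid = VoxelGrid(np.full((10, 10, 10), v))
        samples = np.concatenate([
            apply_noise(grid, optics, seed=s).values.astype(float).ravel()
            for s in range(10)
        ])  # 10^4 draws
        expected = v + optics.read_noise_sd ** 2
        assert samples.var(ddof=1) == pytest.approx(expected, rel=0.06)

    def test_refuses_quantized_input(self):
        grid = VoxelGrid(np.full((2, 32, 32), 5, dtype=np.uint16))
        with pytest.raises(ConfigError):
            apply_noise(grid, OpticsModel(), seed=0)

    def test_clips_at_bit_depth_ceiling(self):
        grid = VoxelGrid(np.full((1, 32, 32), 70000.0))
        noisy = apply_noise(grid, OpticsModel(photon_noise=False, read_noise_sd=0.0), 0)
        assert noisy.values.max() == 2 ** 16 - 1


class TestSimulateField:
    def test_same_seed_bit_identical(self):
        scen = get_scenario("fig2a_psh1del")
        a = simulate_field(scen, seed=11, n_foci=20)
        b = simulate_field(scen, seed=11, n_foci=20)
        for label in a:
            np.testing.assert_array_equal(a[label][0]["GFP"].values,
                                          b[label][0]["GFP"].values)
            assert a[label][1].equals(b[label][1])

    def test_different_seed_differs(self):
        scen = get_scenario("fig2a_psh1del")
        a = simulate_field(scen, seed=11, n_foci=20)
        b = simulate_field(scen, seed=12, n_foci=20)
        assert not np.array_equal(a["wild_type"][0]["GFP"].values,
                                  b["wild_type"][0]["GFP"].values)

    def test_degenerate_population_all_foci_identical(self, quiet_optics):
        scen = GenotypeScenario(
            name="degenerate",
            arms=(ArmSpec(label="wt", intensity_fold=1.0, cv=0.0),))
        _, truth = simulate_arm(scen, "wt", quiet_optics, seed=0, n_foci=12)
        assert truth["photons"].nunique() == 1
        assert truth["sigma_xy_um"].nunique() == 1

    def test_planted_brightness_matches_lognormal_mean(self):
        """Sample mean of planted photons over >= 500 foci agrees with the
        configured lognormal mean within 3 standard errors."""
        scen = get_scenario("fig2a_psh1del")
        n = 600
        _, truth = simulate_arm(scen, "psh1del", seed=21, n_foci=n)
        arm = scen.arms[1]
        mean = scen.baseline_photons * arm.intensity_fold
        se = mean * arm.cv / math.sqrt(n)
        assert truth["photons"].mean() == pytest.approx(mean, abs=3 * se)

    def test_grid_large_enough_for_default_rois(self):
        channels, truth = simulate_arm(get_scenario("wt_reference"), "wild_type",
                                       seed=0, n_foci=4)
        grid = channels["GFP"]
        assert grid.nz >= 7 and min(grid.shape[1:]) >= 32
        # detectability: every planted center >= 3 voxels from every edge
        dims = np.array(grid.shape)
        pos = truth[["z", "y", "x"]].to_numpy()
        assert (pos >= 3).all() and (pos <= dims - 4).all()


class TestScenarioLibrary:
    def test_fig2a_preset_effect_sizes(self):
        scen = get_scenario("fig2a_psh1del")
        assert scen.intensity_fold == pytest.approx(1.83)
        assert scen.cv == pytest.approx(0.25)
        assert scen.arms[1].cv == pytest.approx(0.57 / 1.83)

    def test_wt_reference_is_unit_fold(self):
        scen = get_scenario("wt_reference")
        assert all(arm.intensity_fold == 1.0 and arm.fwhm_fold == 1.0
                   for arm in scen.arms)

    def test_dualtag_fractions_are_half_half(self):
        scen = get_scenario("fig1b_dualtag")
        dual = [a for a in scen.arms if a.label == "dualtag"][0]
        assert dual.channels["YFP"] == pytest.approx(0.5)
        assert dual.channels["CFP"] == pytest.approx(0.5)

    def test_every_preset_documents_its_source(self):
        for scen in scenario_library().values():
            assert scen.source

    def test_unknown_preset_raises(self):
        with pytest.raises(ConfigError, match="unknown scenario"):
            get_scenario("fig99_nonexistent")
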
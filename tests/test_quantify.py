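"""Dual-ROI quantitation: geometry, invariances, recovery, dual-tag."""

import math

import numpy as np
import pytest

from conftest import make_focus_grid
from kinquant import (DegenerateReferenceError, RoiGeometry, RoiOutOfBoundsError,
                      RunConfig, VoxelGrid, build_roi, dual_tag_contributions,
                      measure_focus, normalize_population,
                      roi_volume, run_scenario)

VOX = (0.205, 0.205, 0.4)


def default_roi(grid=None):
    grid = grid or VoxelGrid(np.zeros((17, 48, 48)))
    return build_roi((8, 24, 24), grid), grid


class TestRoiGeometry:
    def test_kinetochore_box_volume_is_printed_value(self):
        roi, grid = default_roi()
        kin, _ = roi_volume(roi, *VOX)
        assert roi.n_kin == 81
        assert round(kin, 2) == 1.36
        assert kin == pytest.approx(81 * 0.205 * 0.205 * 0.4, abs=1e-12)

    def test_background_volume_within_0p1pct_of_printed(self):
        roi, grid = default_roi()
        _, bg = roi_volume(roi, *VOX)
        assert abs(bg - 23.51) / 23.51 < 1e-3

    def test_single_voxel_volume(self):
        assert 0.205 * 0.205 * 0.4 == pytest.approx(0.016810, abs=5e-7)

    def test_volume_equals_independent_recount(self):
        roi, _ = default_roi()
        kin, bg = roi_volume(roi, *VOX)
        vv = VOX[0] * VOX[1] * VOX[2]
        assert kin == pytest.approx(len({tuple(v) for v in roi.kin_voxels}) * vv)
        assert bg == pytest.approx(len({tuple(v) for v in roi.bg_voxels}) * vv)

    def test_sets_disjoint_and_gap_respected(self):
        roi, _ = default_roi()
        kin = {tuple(v) for v in roi.kin_voxels}
        bg = {tuple(v) for v in roi.bg_voxels}
        assert not kin & bg
        # every shell voxel lies outside the box dilated by the 2-voxel gap
        cz, cy, cx = roi.center
        for z, y, x in bg:
            assert (abs(z - cz) > 4 + 2 or abs(y - cy) > 1 + 2
                    or abs(x - cx) > 1 + 2)

    def test_shell_is_nearest_voxels_by_anisotropic_distance(self):
        """Independent recomputation of shell membership by explicit sort."""
        roi, _ = default_roi()
        cz, cy, cx = roi.center
        dz_, dy_, dx_ = 0.4, 0.205, 0.205
        cand = []
        for z in range(17):
            for y in range(48):
                for x in range(48):
                    oz, oy, ox = z - cz, y - cy, x - cx
                    if abs(oz) <= 6 and abs(oy) <= 3 and abs(ox) <= 3:
                        continue  # inside gap-dilated box
                    d = math.sqrt((oz * dz_) ** 2 + (oy * dy_) ** 2 + (ox * dx_) ** 2)
                    cand.append((d, oz, oy, ox, (z, y, x)))
        cand.sort()
        expected = {c[4] for c in cand[:1399]}
        assert {tuple(v) for v in roi.bg_voxels} == expected

    def test_degenerate_gap_zero_equal_volume_shell(self):
        geometry = RoiGeometry(box_dims=(3, 3, 3), gap=0,
                               bg_volume_um3=27 * 0.205 * 0.205 * 0.4)
        grid = VoxelGrid(np.zeros((17, 48, 48)))
        roi = build_roi((8, 24, 24), grid, geometry)
        assert roi.n_kin == roi.n_bg == 27
        assert not ({tuple(v) for v in roi.kin_voxels}
                    & {tuple(v) for v in roi.bg_voxels})

    def test_out_of_bounds_roi_names_the_focus(self):
        grid = VoxelGrid(np.zeros((17, 48, 48)))
        with pytest.raises(RoiOutOfBoundsError, match="spot_007"):
            build_roi((8, 2, 24), grid, focus_id="spot_007")


class TestMeasureFocus:
    def test_uniform_grid_gives_zero_corrected(self):
        grid = VoxelGrid(np.full((17, 48, 48), 314.0))
        roi = build_roi((8, 24, 24), grid)
        assert measure_focus(grid, roi).corrected == 0.0

    def test_offset_invariance(self):
        grid = make_focus_grid(background=50.0)
        roi = build_roi((8, 24, 24), grid)
        base = measure_focus(grid, roi).corrected
        shifted = VoxelGrid(grid.values + 123.0)
        after = measure_focus(shifted, build_roi((8, 24, 24), shifted)).corrected
        assert after == pytest.approx(base, rel=1e-9)

    def test_scale_equivariance(self):
        grid = make_focus_grid(background=50.0)
        roi = build_roi((8, 24, 24), grid)
        base = measure_focus(grid, roi).corrected
        scaled = VoxelGrid(grid.values * 3.5)
        after = measure_focus(scaled, build_roi((8, 24, 24), scaled)).corrected
        assert after == pytest.approx(3.5 * base, rel=1e-12)

    def test_matches_direct_summation_oracle(self):
        """corrected equals sum(kin)/81 - sum(bg)/1399 computed by explicit
        per-voxel summation."""
        grid = make_focus_grid(background=20.0)
        roi = build_roi((8, 24, 24), grid)
        m = measure_focus(grid, roi)
        kin_sum = sum(grid.values[z, y, x] for z, y, x in roi.kin_voxels)
        bg_sum = sum(grid.values[z, y, x] for z, y, x in roi.bg_voxels)
        assert m.corrected == pytest.approx(kin_sum / 81 - bg_sum / 1399, rel=1e-12)

    def test_negative_corrected_preserved(self):
        values = np.full((17, 48, 48), 100.0)
        values[8, 24, 24] = 0.0  # dim center over bright surroundings
        grid = VoxelGrid(values)
        roi = build_roi((8, 24, 24), grid)
        assert measure_focus(grid, roi).corrected < 0


class TestNormalization:
    def test_reference_normalized_to_itself_has_unit_mean(self):
        rng = np.random.default_rng(0)
        ref = rng.lognormal(5, 0.3, 200)
        normed = normalize_population(ref, ref)
        assert normed.mean() == pytest.approx(1.0, abs=1e-12)

    def test_linearity_under_doubling(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(100, 10, 50)
        vals = rng.normal(150, 10, 50)
        n1 = normalize_population(vals, ref)
        n2 = normalize_population(2 * vals, ref)
        np.testing.assert_allclose(n2, 2 * n1, rtol=1e-12)

    def test_degenerate_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            normalize_population([1.0], [])
        with pytest.raises(DegenerateReferenceError):
            normalize_population([1.0], [1.0, -1.0])

    def test_fig2a_pipeline_recovers_planted_fold(self):
        """Full detect+quantify on the Fig 2A-style scenario recovers the
        planted 1.83 intensity fold within 5%."""
        res = run_scenario(RunConfig(scenario="fig2a_psh1del", seed=2, n_foci=80))
        assert res.normalized_mean("psh1del") == pytest.approx(1.83, rel=0.05)
        assert res.normalized_mean("wild_type") == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gap", [4, 6])
    def test_gap_distance_robustness(self, gap):
        """Moving the background shell further from the focus changes the
        recovered control-normalized mean by < 2%."""
        base = run_scenario(RunConfig(scenario="fig2c_psh1del", seed=3,
                                      n_foci=60)).normalized_mean("psh1del")
        moved = run_scenario(RunConfig(scenario="fig2c_psh1del", seed=3, n_foci=60,
                                       roi=RoiGeometry(gap=gap))
                             ).normalized_mean("psh1del")
        assert abs(moved - base) / base < 0.02


class TestDualTag:
    def test_single_tag_strain_against_own_reference(self):
        rng = np.random.default_rng(2)
        yfp = rng.normal(100, 5, 80)      # expressed channel
        cfp = rng.normal(0, 1, 80)        # dark channel
        res = dual_tag_contributions(yfp, cfp, rng.normal(100, 5, 80),
                                     rng.normal(100, 5, 80))
        assert res.mean_yfp == pytest.approx(1.0, abs=0.05)
        assert res.mean_cfp == pytest.approx(0.0, abs=0.05)
        assert res.mean_total == pytest.approx(1.0, abs=0.07)

    def test_equal_competition_scenario(self):
        """Simulated 50/50 dual-tag competition: each channel contributes
        0.4-0.6 of its haploid reference and the total is ~1."""
        res = run_scenario(RunConfig(scenario="fig1b_dualtag", seed=4, n_foci=100))
        d = res.dualtag
        assert 0.4 <= d.mean_yfp <= 0.6
        assert 0.4 <= d.mean_cfp <= 0.6
        assert d.mean_total == pytest.approx(1.0, abs=0.08)

    def test_unequal_fractions_recovered(self):
        """Planted 0.7/0.3 channel split recovered within 5%."""
        from kinquant import ArmSpec, GenotypeScenario
        scen = GenotypeScenario(
            name="dualtag_70_30", kind="dualtag",
            arms=(ArmSpec(label="haploid_yfp", channels={"YFP": 1.0}, cv=0.2),
                  ArmSpec(label="haploid_cfp", channels={"CFP": 1.0}, cv=0.2),
                  ArmSpec(label="dualtag", channels={"YFP": 0.7, "CFP": 0.3},
                          cv=0.2)))
        res = run_scenario(RunConfig(scenario=scen, seed=5, n_foci=100))
        assert res.dualtag.mean_yfp == pytest.approx(0.7, rel=0.05)
        assert res.dualtag.mean_cfp == pytest.approx(0.3, rel=0.05)
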
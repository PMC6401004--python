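"""Synthetic scene generators and their ground-truth payloads."""

import math

import numpy as np
import pytest

from gpqpi import scenes
from gpqpi.quantify import DryMassMap, drymass_to_phase
from gpqpi.scenes import (
    cell_phantom,
    cell_phantom_series,
    coherence_length_um,
    gp_lens_scene,
    grid_coords,
    make_spectrum,
    mirror_scene,
    scene_from_descriptor,
    slm_scene,
)


class TestSpectrum:
    def test_single_sample_is_monochromatic(self):
        s = make_spectrum(600, 50, 1)
        assert s.wavelengths_nm.tolist() == [600.0]
        assert s.weights.tolist() == [1.0]

    def test_symmetric_and_normalized(self):
        s = make_spectrum(600, 50, 21)
        assert s.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(s.weights, s.weights[::-1])
        assert s.center_nm == pytest.approx(600.0)

    def test_coherence_length_of_the_600_50_band(self):
        assert coherence_length_um(600, 50) == pytest.approx(7.2)

    def test_rejects_nonpositive_center(self):
        with pytest.raises(ValueError):
            make_spectrum(-600, 50, 5)


class TestMirrorScene:
    def test_zero_displacement_zero_retardance(self, mono600):
        sc = mirror_scene((32, 32), 0.5, 0.0)
        assert np.all(sc.retardance(600.0) == 0.0)

    def test_150nm_gives_pi_at_600nm(self):
        sc = mirror_scene((8, 8), 0.5, 150.0)
        assert np.all(sc.retardance(600.0) == pytest.approx(math.pi))

    def test_300nm_gives_two_pi(self):
        sc = mirror_scene((8, 8), 0.5, 300.0)
        assert np.all(sc.retardance(600.0) == pytest.approx(2 * math.pi))

    def test_retardance_linear_in_displacement(self):
        r1 = mirror_scene((4, 4), 0.5, 100.0).retardance(600.0)[0, 0]
        r3 = mirror_scene((4, 4), 0.5, 300.0).retardance(600.0)[0, 0]
        assert r3 == pytest.approx(3 * r1, rel=1e-12)

    def test_out_of_range_displacement_rejected(self):
        with pytest.raises(ValueError):
            mirror_scene((8, 8), 0.5, 1500.0)


class TestSLMScene:
    def test_all_zero_matrix_is_background_only(self):
        sc = slm_scene((64, 64), 0.5, 4.0, np.zeros((4, 4)))
        assert np.all(sc.retardance(600.0) == 0.0)

    def test_5x5_block_at_pi_covers_exactly_25_pixels(self):
        matrix = np.pad(np.full((5, 5), math.pi), 1)  # 7x7 panel
        sc = slm_scene((256, 256), 0.5, 10.0, matrix)
        ret = sc.retardance(600.0)
        n_grid_px_per_slm_px = (10.0 / 0.5) ** 2
        assert np.isclose(ret, math.pi).sum() == 25 * n_grid_px_per_slm_px
        assert set(np.unique(ret)) == {0.0, math.pi}

    def test_ground_truth_carries_programmed_values(self):
        matrix = np.zeros((4, 4))
        matrix[1, 1], matrix[1, 2] = 3.09, 2.85
        sc = slm_scene((128, 128), 0.5, 10.0, matrix)
        assert sc.ground_truth["phase_matrix"][1, 1] == 3.09
        assert sc.ground_truth["phase_matrix"][1, 2] == 2.85
        mask = scenes.slm_pixel_mask(sc, 1, 1)
        assert np.all(sc.retardance(600.0)[mask] == 3.09)

    def test_wavelength_independent(self):
        sc = slm_scene((32, 32), 0.5, 4.0, np.full((2, 2), 1.0))
        assert np.array_equal(sc.retardance(550.0), sc.retardance(650.0))

    def test_pixel_smaller_than_pitch_rejected(self):
        with pytest.raises(ValueError):
            slm_scene((32, 32), 0.5, 0.25, np.zeros((2, 2)))


class TestGPLensScene:
    def test_on_axis_phase_zero(self):
        sc = gp_lens_scene((65, 65), 1.0, 100.0, 600.0)
        phi = sc.ground_truth["single_pass_phase"]
        assert phi[32, 32] == pytest.approx(0.0)

    def test_hand_evaluated_phase_at_quarter_millimetre(self):
        # phi = -pi r^2/(lambda f) = -pi (250 um)^2 / (0.6 um * 1e5 um)
        sc = gp_lens_scene((501, 501), 1.0, 100.0, 600.0)
        phi = sc.ground_truth["single_pass_phase"]
        x, _ = grid_coords((501, 501), 1.0)
        col = np.argmin(np.abs(x[0] - 250.0))
        expected = -math.pi * 250.0**2 / (0.6 * 1e5)
        assert phi[250, col] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-3.2725, abs=1e-4)

    def test_retardance_is_twice_single_pass(self):
        sc = gp_lens_scene((64, 64), 1.0)
        assert np.allclose(
            sc.retardance(600.0), 2 * sc.ground_truth["single_pass_phase"]
        )

    def test_rotational_symmetry(self):
        sc = gp_lens_scene((128, 128), 1.0)
        ret = sc.retardance(600.0)
        assert np.allclose(ret, ret[::-1, ::-1], atol=1e-12)
        assert np.allclose(ret, ret.T, atol=1e-12)

    def test_zero_focal_length_rejected(self):
        with pytest.raises(ValueError):
            gp_lens_scene((32, 32), 1.0, focal_length_mm=0.0)


class TestCellPhantom:
    def test_mass_conservation_by_construction(self):
        sc = cell_phantom((256, 256), 0.5, 1, (200.0, 200.0), seed=3)
        total = sc.ground_truth["density_pg_um2"].sum() * 0.5**2
        assert total == pytest.approx(200.0, rel=1e-3)

    def test_deterministic_given_seed(self):
        a = cell_phantom((256, 256), 0.5, 2, seed=11)
        b = cell_phantom((256, 256), 0.5, 2, seed=11)
        assert np.array_equal(a.opd_s_nm, b.opd_s_nm)

    def test_phase_density_consistent_with_davies_relation(self):
        sc = cell_phantom((256, 256), 0.5, 2, seed=5)
        density = DryMassMap(sc.ground_truth["density_pg_um2"], 0.5)
        recomputed = drymass_to_phase(density, 600.0)
        assert np.allclose(
            recomputed.phase, sc.retardance(600.0), atol=1e-9
        )

    def test_generation_error_when_cells_cannot_fit(self):
        with pytest.raises(RuntimeError):
            cell_phantom((32, 32), 0.5, 20, seed=0)

    def test_series_grows_area_and_conserves_mass(self):
        frames = cell_phantom_series(
            (256, 256), 0.5, 2, 4, area_growth_per_frame=0.05, seed=7
        )
        t0 = frames[0].ground_truth["cell_table"]
        t3 = frames[3].ground_truth["cell_table"]
        assert np.all(t3["area_um2"].values > t0["area_um2"].values)
        assert np.allclose(
            t3["total_mass_pg"], t0["total_mass_pg"], rtol=5e-3
        )
        assert np.all(
            t3["mean_density_pg_um2"].values < t0["mean_density_pg_um2"].values
        )


class TestSceneInvariants:
    @pytest.mark.parametrize(
        "scene",
        [
            mirror_scene((32, 32), 0.5, 137.0),
            slm_scene((32, 32), 0.5, 4.0, np.full((2, 2), 1.3)),
            gp_lens_scene((32, 32), 1.0),
            cell_phantom((128, 128), 0.5, 1, seed=1),
        ],
        ids=["mirror", "slm", "lens", "cells"],
    )
    def test_no_nan_and_retardance_definition(self, scene):
        for lam in (575.0, 600.0, 625.0):
            ret = scene.retardance(lam)
            assert np.all(np.isfinite(ret))
            assert np.allclose(
                ret, scene.sample_phase(lam) - scene.reference_phase(lam)
            )

    def test_descriptor_round_trip(self):
        for sc in (
            mirror_scene((16, 16), 0.5, 42.0),
            slm_scene((64, 64), 0.5, 4.0, np.full((3, 3), 0.5)),
            gp_lens_scene((32, 32), 1.0, 50.0, 550.0),
            cell_phantom((256, 256), 0.5, 2, seed=9),
        ):
            rebuilt = scene_from_descriptor(sc.descriptor)
            assert np.array_equal(
                rebuilt.retardance(600.0), sc.retardance(600.0)
            )
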
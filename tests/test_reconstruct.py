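"""Sideband demodulation, background compensation and unwrapping."""

import math

import numpy as np
import pytest

from gpqpi.hologram import form_hologram
from gpqpi.reconstruct import (
    ComplexField,
    PhaseMap,
    border_mask,
    demodulate,
    lowpass_denoise,
    residue_count,
    subtract_background,
    unwrap,
    wrapped_phase,
)
from gpqpi.scenes import (
    gp_lens_scene,
    grid_coords,
    make_spectrum,
    mirror_scene,
    slm_scene,
)


def _circular_mean(phases):
    return float(np.angle(np.exp(1j * phases).mean()))


class TestDemodulate:
    def test_flat_scene_recovers_constant_phase(self, flat_scene, mono600):
        holo = form_hologram(flat_scene, mono600)
        pm = wrapped_phase(demodulate(holo))
        interior = pm.phase[border_mask(pm.shape)]
        assert interior.std() < 1e-3

    def test_mirror_half_wave_recovers_pi(self, mono600):
        holo = form_hologram(mirror_scene((256, 256), 0.5, 150.0), mono600)
        pm = wrapped_phase(demodulate(holo))
        interior = pm.phase[border_mask(pm.shape)]
        # pi is the wrap point; measure distance on the circle
        dist = np.abs(np.angle(np.exp(1j * (interior - math.pi))))
        assert dist.max() < 1e-3

    def test_lens_wrapped_phase_matches_ground_truth(self, mono600):
        scene = gp_lens_scene((256, 256), 500 / 256, 100.0, 600.0)
        holo = form_hologram(scene, mono600)
        pm = wrapped_phase(demodulate(holo))
        truth = 2.0 * scene.ground_truth["single_pass_phase"]
        m = border_mask(pm.shape)
        err = np.angle(np.exp(1j * (pm.phase - truth)))[m]
        err -= np.median(err)
        assert np.abs(err).max() < 1e-2

    def test_linear_in_hologram_intensity(self, flat_scene, mono600):
        h1 = form_hologram(flat_scene, mono600)
        h2 = form_hologram(mirror_scene(flat_scene.shape, 0.5, 100.0), mono600)
        f1 = demodulate(h1).data
        f2 = demodulate(h2).data
        import copy

        h_sum = copy.deepcopy(h1)
        h_sum.intensity = h1.intensity + h2.intensity
        assert np.allclose(demodulate(h_sum).data, f1 + f2, atol=1e-10)

    def test_phase_independent_of_global_intensity_scale(self, mono600):
        scene = gp_lens_scene((128, 128), 2.0, 100.0)
        holo = form_hologram(scene, mono600)
        pm1 = wrapped_phase(demodulate(holo))
        holo.intensity = holo.intensity * 37.5
        pm2 = wrapped_phase(demodulate(holo))
        m = border_mask(pm1.shape)
        assert np.allclose(pm1.phase[m], pm2.phase[m], atol=1e-9)

    def test_sideband_dc_overlap_rejected(self, flat_scene, mono600):
        holo = form_hologram(flat_scene, mono600, carrier=(0.125, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            demodulate(holo, bandwidth=0.1)


class TestWrappedPhase:
    def test_constant_phase_field(self):
        f = ComplexField(np.full((8, 8), np.exp(0.3j)), 0.5)
        assert np.allclose(wrapped_phase(f).phase, 0.3)

    def test_wrap_convention_half_open_interval(self):
        f = ComplexField(np.full((4, 4), np.exp(1j * (math.pi + 0.1))), 0.5)
        assert np.allclose(wrapped_phase(f).phase, -math.pi + 0.1)
        f_at_pi = ComplexField(np.full((4, 4), -1.0 + 0j), 0.5)
        assert np.all(wrapped_phase(f_at_pi).phase == math.pi)

    def test_zero_amplitude_pixel_flagged(self):
        data = np.ones((4, 4), dtype=complex)
        data[2, 2] = 0.0
        pm = wrapped_phase(ComplexField(data, 0.5))
        assert pm.phase[2, 2] == 0.0
        assert pm.quality[2, 2] == 0.0
        assert pm.quality[0, 0] > 0.0


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self, flat_scene, mono600):
        pm = wrapped_phase(demodulate(form_hologram(flat_scene, mono600)))
        out = subtract_background(pm, pm)
        assert np.allclose(out.phase, 0.0)

    def test_tilt_removed_by_first_order_polynomial(self):
        x, y = grid_coords((64, 64), 0.5)
        pm = PhaseMap(0.01 * x + 0.02 * y + 0.3, False, 0.5)
        out = subtract_background(pm, 1)
        assert out.phase.std() < 1e-6

    def test_slm_block_survives_reference_subtraction(self, mono600):
        from gpqpi.scenes import slm_pixel_mask

        matrix = np.zeros((3, 3))
        matrix[1, 1] = 1.5
        scene = slm_scene((256, 256), 0.5, 16.0, matrix)
        bg_scene = slm_scene((256, 256), 0.5, 16.0, np.zeros((3, 3)))
        # imaging pixel plateaus needs a band resolving the pixel size
        carrier = (0.25, 0.0)
        holo = form_hologram(scene, mono600, carrier=carrier)
        holo_bg = form_hologram(bg_scene, mono600, carrier=carrier)
        pm = wrapped_phase(demodulate(holo, bandwidth=0.125))
        pm_bg = wrapped_phase(demodulate(holo_bg, bandwidth=0.125))
        diff = subtract_background(pm, pm_bg)
        center = slm_pixel_mask(scene, 1, 1, shrink=0.25)
        m = border_mask(pm.shape)
        assert _circular_mean(diff.phase[center & m]) == pytest.approx(
            1.5, abs=0.02
        )
        inside = scene.retardance(600.0) == 1.5
        far_outside = (~inside) & m & (np.abs(scene.retardance(600.0)) == 0.0)
        assert abs(np.median(diff.phase[far_outside])) < 0.02

    def test_grid_mismatch_rejected(self):
        a = PhaseMap(np.zeros((8, 8)), True, 0.5)
        b = PhaseMap(np.zeros((16, 16)), True, 0.5)
        with pytest.raises(ValueError):
            subtract_background(a, b)


class TestUnwrap:
    def test_smooth_map_unchanged_up_to_constant(self):
        x, _ = grid_coords((64, 64), 0.5)
        pm = PhaseMap(0.01 * x, True, 0.5)  # no wraps present
        out = unwrap(pm)
        d = out.phase - pm.phase
        assert np.allclose(d, d.flat[0], atol=1e-9)

    def test_quadratic_lens_retardance_spanning_many_wraps(self):
        scene = gp_lens_scene((256, 256), 500 / 256, 100.0, 600.0)
        truth = 2.0 * scene.ground_truth["single_pass_phase"]
        pm = PhaseMap(np.angle(np.exp(1j * truth)), True, 500 / 256)
        out = unwrap(pm)
        d = out.phase - truth
        assert np.abs(d - np.median(d)).max() < 1e-2
        assert out.meta["residues"] == 0

    def test_one_dimensional_ramp_against_numpy_oracle(self):
        # 10 pi ramp along x, wrapped; compare to np.unwrap row by row
        x, _ = grid_coords((16, 128), 1.0)
        true = 10 * math.pi * (x - x.min()) / (x.max() - x.min())
        pm = PhaseMap(np.angle(np.exp(1j * true)), True, 1.0)
        out = unwrap(pm)
        oracle = np.unwrap(pm.phase, axis=1)
        d = out.phase - oracle
        assert np.allclose(d, d.flat[0], atol=1e-9)

    def test_residue_count_detects_vortex(self):
        x, y = grid_coords((32, 32), 1.0)
        vortex = np.angle((x + 1j * y))
        assert residue_count(vortex) >= 1
        smooth = np.angle(np.exp(1j * 0.05 * x))
        assert residue_count(smooth) == 0


class TestLowpassDenoise:
    def test_exact_on_quadratic_profiles(self, rng):
        x, y = grid_coords((128, 128), 1.0)
        quad = 1e-3 * (x**2 + 0.5 * y**2) + 0.01 * x
        pm = PhaseMap(quad, False, 1.0)
        out = lowpass_denoise(pm, sigma_um=8.0)
        assert np.abs(out.phase - quad).max() < 1e-9

    def test_suppresses_white_noise(self, rng):
        noise = rng.normal(0, 0.1, (128, 128))
        pm = PhaseMap(noise, False, 1.0)
        out = lowpass_denoise(pm, sigma_um=8.0)
        assert out.phase.std() < 0.2 * noise.std()


class TestEndToEndRoundTrip:
    @pytest.mark.parametrize("dz_nm", [40.0, 150.0, 260.0])
    def test_mirror_heights_recovered(self, dz_nm, broadband):
        scene = mirror_scene((256, 256), 0.5, dz_nm)
        holo = form_hologram(scene, broadband)
        pm = wrapped_phase(demodulate(holo))
        m = border_mask(pm.shape)
        expected = np.angle(np.exp(1j * 4 * math.pi * dz_nm / 600.0))
        measured = _circular_mean(pm.phase[m])
        assert abs(
            np.angle(np.exp(1j * (measured - expected)))
        ) < 2e-2

    def test_lens_retardance_recovered(self, mono600):
        scene = gp_lens_scene((256, 256), 500 / 256, 100.0, 600.0)
        holo = form_hologram(scene, mono600)
        out = unwrap(wrapped_phase(demodulate(holo)))
        truth = 2.0 * scene.ground_truth["single_pass_phase"]
        m = border_mask(out.shape)
        d = (out.phase - truth)[m]
        assert np.abs(d - np.median(d)).max() < 2e-2
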
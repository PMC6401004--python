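"""Lens characterization: focal fit, Fresnel number, diffraction propagation.

The closed-form Fresnel axial intensity is validated against a direct
Fresnel quadrature (the slow oracle) before the FFT propagator is compared
with it, keeping the two numerical routes independent.
"""

import math

import numpy as np
import pytest

from gpqpi.lensmap import (
    analytic_axial_intensity,
    axial_intensity,
    characterize,
    direct_fresnel_on_axis,
    fit_focal_length,
    fresnel_number,
    propagate,
    single_pass_phase,
)
from gpqpi.reconstruct import PhaseMap
from gpqpi.scenes import gp_lens_scene, grid_coords


def _lens_phase(grid=256, field_um=600.0, f_mm=100.0):
    pitch = field_um / grid
    scene = gp_lens_scene((grid, grid), pitch, f_mm, 600.0)
    return PhaseMap(scene.ground_truth["single_pass_phase"], False, pitch)


class TestSinglePassPhase:
    def test_halves_retardance(self):
        pm = PhaseMap(np.full((8, 8), 3.0), False, 1.0)
        assert np.allclose(single_pass_phase(pm).phase, 1.5)

    def test_rejects_wrapped(self):
        with pytest.raises(ValueError):
            single_pass_phase(PhaseMap(np.zeros((4, 4)), True, 1.0))


class TestFitFocalLength:
    def test_exact_quadratic_recovered(self):
        phi = _lens_phase()
        f, rms = fit_focal_length(phi, 600.0)
        assert f == pytest.approx(-100.0, rel=1e-3) or f == pytest.approx(
            100.0, rel=1e-3
        )
        assert abs(abs(f) - 100.0) / 100.0 < 1e-3
        assert rms < 1e-6

    def test_doubling_phase_halves_focal_length(self):
        phi = _lens_phase()
        f1, _ = fit_focal_length(phi, 600.0)
        phi2 = PhaseMap(2 * phi.phase, False, phi.pitch_um)
        f2, _ = fit_focal_length(phi2, 600.0)
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)

    def test_flat_phase_fails(self):
        with pytest.raises(ValueError):
            fit_focal_length(PhaseMap(np.zeros((32, 32)), False, 1.0), 600.0)

    def test_robust_to_noise_at_instrument_level(self, rng):
        phi = _lens_phase()
        noisy = PhaseMap(
            phi.phase + rng.normal(0, 0.031, phi.shape), False, phi.pitch_um
        )
        f, _ = fit_focal_length(noisy, 600.0)
        assert abs(f) == pytest.approx(100.0, rel=0.01)


class TestFresnelNumber:
    def test_quarter_millimetre_aperture_rounds_to_one(self):
        nf = fresnel_number(0.25, 600.0, 100.0)
        assert nf == pytest.approx(1.0417, abs=1e-3)
        assert round(nf) == 1

    def test_quadratic_in_aperture(self):
        assert fresnel_number(0.5, 600.0, 100.0) == pytest.approx(
            4 * fresnel_number(0.25, 600.0, 100.0)
        )

    def test_inverse_in_focal_length(self):
        assert fresnel_number(0.25, 600.0, 200.0) == pytest.approx(0.52, abs=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fresnel_number(-0.25, 600.0, 100.0)


class TestAnalyticAxialIntensity:
    def test_unity_at_paraxial_focus(self):
        assert analytic_axial_intensity(
            np.array([100.0]), 0.25, 100.0, 600.0
        )[0] == pytest.approx(1.0)

    def test_zeros_at_predicted_positions(self):
        # sin(u/2)=0 at 1/z - 1/f = 2 m lambda / a^2
        a_um, lam_um, f_um = 250.0, 0.6, 1e5
        for m in (1, 2):
            z_um = 1.0 / (1.0 / f_um + 2 * m * lam_um / a_um**2)
            val = analytic_axial_intensity(
                np.array([z_um * 1e-3]), 0.25, 100.0, 600.0
            )[0]
            assert val < 1e-20

    def test_validated_against_direct_fresnel_quadrature(self):
        # oracle requirement: closed form vs brute-force integral
        phi = _lens_phase(grid=192)
        z = np.arange(35.0, 300.0, 5.0)
        u = direct_fresnel_on_axis(phi, 600.0, z, aperture_radius_mm=0.25)
        num = np.abs(u) ** 2
        num /= num.max()
        ana = analytic_axial_intensity(z, 0.25, 100.0, 600.0)
        ana /= ana.max()
        assert np.abs(num - ana).max() < 0.01


class TestPropagate:
    def test_far_field_of_flat_aperture_matches_direct_integral(self):
        # 64^2 oracle grid: flat circular aperture, compare on-axis values
        grid = 64
        pitch = 600.0 / grid
        phi = PhaseMap(np.zeros((grid, grid)), False, pitch)
        z = np.array([150.0, 250.0, 400.0])
        vol = propagate(phi, 600.0, z, aperture_radius_mm=0.25, pad_factor=4)
        num = vol[:, grid // 2, grid // 2] ** 2
        oracle = np.abs(
            direct_fresnel_on_axis(phi, 600.0, z, aperture_radius_mm=0.25)
        ) ** 2
        assert np.allclose(num / num.max(), oracle / oracle.max(), rtol=0.01,
                           atol=0.01)

    def test_energy_conserved_before_band_limit(self):
        phi = _lens_phase(grid=128)
        vol = propagate(phi, 600.0, np.array([2.0, 5.0]),
                        aperture_radius_mm=0.25, pad_factor=2, crop=False)
        x, y = grid_coords(phi.shape, phi.pitch_um)
        e0 = np.sum((x**2 + y**2 <= 250.0**2).astype(float))
        for plane in vol:
            assert np.sum(plane**2) == pytest.approx(e0, rel=0.01)

    def test_rejects_nonpositive_distance(self):
        phi = _lens_phase(grid=64)
        with pytest.raises(ValueError):
            propagate(phi, 600.0, np.array([-1.0]))


@pytest.fixture(scope="module")
def profiles():
    phi = _lens_phase(grid=192)
    z = np.arange(30.0, 300.0 + 1e-9, 2.0)
    vol = propagate(phi, 600.0, z, aperture_radius_mm=0.25)
    num = axial_intensity(vol)
    ana = analytic_axial_intensity(z, 0.25, 100.0, 600.0)
    return z, num, ana / ana.max()


class TestAxialProfileLowFresnelNumber:
    def test_peak_shifted_toward_lens(self, profiles):
        z, num, ana = profiles
        assert z[np.argmax(num)] < 100.0
        assert z[np.argmax(ana)] < 100.0

    def test_maxima_coincide_within_one_step(self, profiles):
        z, num, ana = profiles
        assert abs(z[np.argmax(num)] - z[np.argmax(ana)]) <= 2.0

    def test_first_zero_coincides_within_one_step(self, profiles):
        z, num, ana = profiles
        near = z < 60.0
        assert abs(
            z[near][np.argmin(num[near])] - z[near][np.argmin(ana[near])]
        ) <= 2.0

    def test_profiles_strongly_correlated(self, profiles):
        _, num, ana = profiles
        assert np.corrcoef(num, ana)[0, 1] > 0.99

    def test_asymmetry_about_the_paraxial_focus(self, profiles):
        z, num, _ = profiles
        for delta in (10.0, 20.0):
            before = num[np.argmin(np.abs(z - (100.0 - delta)))]
            after = num[np.argmin(np.abs(z - (100.0 + delta)))]
            assert before > after


class TestCharacterize:
    def test_full_report_from_ideal_retardance(self):
        scene = gp_lens_scene((192, 192), 600.0 / 192, 100.0, 600.0)
        ret = PhaseMap(2 * scene.ground_truth["single_pass_phase"], False,
                       600.0 / 192)
        char = characterize(ret, 600.0, 0.25,
                            z_mm=np.arange(40.0, 200.0, 2.0))
        assert abs(char.focal_length_mm) == pytest.approx(100.0, rel=0.01)
        assert round(char.fresnel_number) == 1
        assert char.axial_intensity.max() == pytest.approx(1.0)

    def test_single_plane_axial_intensity_is_unity(self):
        vol = np.ones((1, 16, 16))
        assert axial_intensity(vol).tolist() == [1.0]
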
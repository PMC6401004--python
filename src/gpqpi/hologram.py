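"""Achromatic off-axis hologram formation under broadband illumination.

The detector intensity is an incoherent sum of two-beam interference
patterns, one per spectral line, all sharing the same carrier frequency
(the defining property of the geometric-phase 4G design: the fringe period
does not depend on wavelength).  For spectral weights w_λ,

    I(x, y) = Σ_λ w_λ [ |s_λ|² + |r_λ|²
              + 2|s_λ||r_λ| cos(2π ν_c·(x, y) + Φ_s − Φ_r + 2π·OPD/λ) ]

which is the fully incoherent, ideal-point-imaging limit of the partially
coherent model; an optional Gaussian PSF blur approximates finite NA.

Noise models: per-frame piston drift (a spatially uniform height-equivalent
phase fluctuation, the dominant instability of a common-path setup),
additive Gaussian read noise, and Poisson shot noise at a stated photon
budget.  All randomness is driven by a single seed, so holograms are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from gpqpi.scenes import SceneSpec, Spectrum, grid_coords

__all__ = [
    "NoiseSpec",
    "Hologram",
    "form_hologram",
    "fringe_contrast",
    "fringe_period_per_line",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and instability settings for hologram formation.

    Parameters
    ----------
    piston_sigma_nm : float
        Std of the per-frame piston drift in height-equivalent nm
        (double-pass: phase contribution 4π·p/λ).
    read_noise_frac : float
        Std of additive Gaussian read noise as a fraction of the spatial
        mean of the noiseless intensity.
    photon_budget : float or None
        Mean photon count per pixel; Poisson shot noise is applied at this
        scaling.  ``None`` disables shot noise.
    psf_sigma_um : float
        Gaussian PSF blur width applied to the noiseless intensity
        (approximation to finite-NA imaging); 0 disables.
    pedestal_frac : float
        Constant stray-light pedestal added before the noise, as a fraction
        of the mean intensity.  Keeps strong injected noise inside the
        detector's nonnegative range (otherwise zero-clipping at fringe
        troughs rectifies the noise into a phase bias); it carries no
        spatial structure and is rejected by the DC filter downstream.
    """

    piston_sigma_nm: float = 0.0
    read_noise_frac: float = 0.0
    photon_budget: float | None = None
    psf_sigma_um: float = 0.0
    pedestal_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_budget is not None and self.photon_budget < 0:
            raise ValueError("photon budget must be nonnegative")
        if self.piston_sigma_nm < 0 or self.read_noise_frac < 0:
            raise ValueError("noise amplitudes must be nonnegative")


@dataclass
class Hologram:
    """Recorded off-axis intensity pattern plus acquisition metadata."""

    intensity: np.ndarray
    pitch_um: float
    carrier: tuple[float, float]  # cycles/µm, (νx, νy), wavelength independent
    spectrum: Spectrum
    frame_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be nonnegative")
        nu = math.hypot(*self.carrier)
        if nu >= 1.0 / (2.0 * self.pitch_um):
            raise ValueError(
                f"carrier {nu:.4f} cycles/um at or beyond Nyquist "
                f"{1.0 / (2.0 * self.pitch_um):.4f}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def form_hologram(
    scene: SceneSpec,
    spectrum: Spectrum,
    carrier: tuple[float, float] = (0.125, 0.0),
    opd_offset_um: float = 0.0,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    frame_index: int = 0,
) -> Hologram:
    """Form one achromatic off-axis hologram of a scene.

    ``opd_offset_um`` models the inter-arm optical-path compensator as a
    scalar path offset, adding 2π·OPD/λ per spectral line — the knob that
    exposes coherence gating for broadband spectra.
    """
    nu = math.hypot(*carrier)
    if nu >= 1.0 / (2.0 * scene.pitch_um):
        raise ValueError(
            f"carrier {nu:.4f} cycles/um aliases at pitch {scene.pitch_um} um"
        )
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    piston_nm = 0.0
    if noise.piston_sigma_nm > 0:
        piston_nm = float(rng.normal(0.0, noise.piston_sigma_nm))

    x, y = grid_coords(scene.shape, scene.pitch_um)
    carrier_phase = 2.0 * math.pi * (carrier[0] * x + carrier[1] * y)
    a_s = scene.sample_amplitude()
    a_r = scene.reference_amplitude()
    background = a_s**2 + a_r**2
    cross = 2.0 * a_s * a_r

    intensity = np.zeros(scene.shape, dtype=float)
    for lam_nm, w in zip(spectrum.wavelengths_nm, spectrum.weights):
        delta = scene.retardance(lam_nm)
        phase = (
            carrier_phase
            + delta
            + 2.0 * math.pi * opd_offset_um * 1e3 / lam_nm
            + 4.0 * math.pi * piston_nm / lam_nm
        )
        intensity += w * (background + cross * np.cos(phase))

    if noise.psf_sigma_um > 0:
        intensity = ndimage.gaussian_filter(
            intensity, noise.psf_sigma_um / scene.pitch_um
        )

    base_mean = float(intensity.mean())  # read noise references this,
    # so the injected amplitude stays linear in read_noise_frac
    if noise.pedestal_frac > 0:
        intensity = intensity + noise.pedestal_frac * base_mean
    mean_i = float(intensity.mean())
    if noise.photon_budget:
        scale = noise.photon_budget / mean_i if mean_i > 0 else 1.0
        intensity = rng.poisson(intensity * scale).astype(float) / scale
    if noise.read_noise_frac > 0:
        intensity = intensity + rng.normal(
            0.0, noise.read_noise_frac * base_mean, size=intensity.shape
        )
    np.clip(intensity, 0.0, None, out=intensity)

    return Hologram(
        intensity=intensity,
        pitch_um=scene.pitch_um,
        carrier=tuple(carrier),
        spectrum=spectrum,
        frame_index=frame_index,
        meta={
            "opd_offset_um": opd_offset_um,
            "piston_nm": piston_nm,
            "noise": {
                "piston_sigma_nm": noise.piston_sigma_nm,
                "read_noise_frac": noise.read_noise_frac,
                "photon_budget": noise.photon_budget,
                "psf_sigma_um": noise.psf_sigma_um,
                "pedestal_frac": noise.pedestal_frac,
            },
            "seed": seed,
            "scene": scene.descriptor,
        },
    )


def fringe_contrast(
    hologram: Hologram,
    window: tuple[slice, slice] | None = None,
) -> float:
    """Michelson contrast of the carrier fringe in a window.

    Fits the local two-beam model I = c₀ + c₁cos(2πν·r) + c₂sin(2πν·r)
    by least squares at the known carrier and returns
    (I_max − I_min)/(I_max + I_min) = √(c₁²+c₂²)/c₀ of the fitted sinusoid.
    Exact for noiseless two-beam fringes regardless of window size; the
    window must still span at least 3 fringe periods for a stable fit.
    """
    win = window or (slice(None), slice(None))
    patch = hologram.intensity[win]
    x, y = grid_coords(hologram.shape, hologram.pitch_um)
    xs, ys = x[win], y[win]
    nu = math.hypot(*hologram.carrier)
    if nu == 0:
        raise ValueError("hologram has no carrier")
    extent = math.hypot(
        xs.max() - xs.min(), ys.max() - ys.min()
    )
    if extent * nu < 3.0:
        raise ValueError(
            f"window spans {extent * nu:.2f} fringe periods; need >= 3"
        )
    arg = 2.0 * math.pi * (hologram.carrier[0] * xs + hologram.carrier[1] * ys)
    design = np.stack(
        [np.ones(arg.size), np.cos(arg).ravel(), np.sin(arg).ravel()], axis=1
    )
    coef, *_ = np.linalg.lstsq(design, patch.ravel(), rcond=None)
    c0, c1, c2 = coef
    if c0 <= 0:
        return 0.0
    return float(min(math.hypot(c1, c2) / c0, 1.0))


def fringe_period_per_line(
    scene: SceneSpec,
    spectrum: Spectrum,
    carrier: tuple[float, float] = (0.125, 0.0),
) -> list[tuple[float, float]]:
    """Measured fringe period of each spectral line's own hologram.

    Forms a monochromatic hologram per line and locates the dominant
    off-DC peak of its 2-D power spectrum.  Because the carrier is
    achromatic by design, all periods coincide with 1/|ν_c| within one FFT
    bin — a regression guard on the achromaticity of the model.
    """
    if len(spectrum) < 2:
        raise ValueError("need at least two spectral lines")
    out = []
    for lam_nm in spectrum.wavelengths_nm:
        mono = Spectrum(np.array([lam_nm]), np.array([1.0]))
        holo = form_hologram(scene, mono, carrier=carrier)
        spec = np.fft.fft2(holo.intensity - holo.intensity.mean())
        fy = np.fft.fftfreq(holo.shape[0], d=holo.pitch_um)
        fx = np.fft.fftfreq(holo.shape[1], d=holo.pitch_um)
        power = np.abs(spec) ** 2
        iy, ix = np.unravel_index(np.argmax(power), power.shape)
        freq = math.hypot(fx[ix], fy[iy])
        out.append((float(lam_nm), 1.0 / freq if freq > 0 else math.inf))
    return out
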
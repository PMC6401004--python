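"""Single-shot retardance restoration from an off-axis hologram.

The carrier fringe shifts the interference cross-term to a sideband in the
spatial-frequency plane.  Demodulation multiplies the hologram by the
conjugate carrier wave and applies a circular low-pass filter at baseband —
algebraically the same as selecting the +1 sideband and shifting it to the
origin, but exact also for carriers that do not fall on an FFT bin.  The
argument of the resulting complex field is the wrapped retardance estimate;
background compensation and 2-D unwrapping complete the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.signal.windows import tukey
from skimage.restoration import unwrap_phase as _unwrap_2d

from gpqpi.hologram import Hologram
from gpqpi.scenes import grid_coords

__all__ = [
    "ComplexField",
    "PhaseMap",
    "demodulate",
    "wrapped_phase",
    "subtract_background",
    "unwrap",
    "residue_count",
    "border_mask",
    "reconstruct_retardance",
]

#: Apodized margin (pixels) excluded from quantitative comparisons.
BORDER_PX = 16

#: Apodization taper length per edge (pixels).  A real window never biases
#: the phase where it is positive; a wide taper only trades edge amplitude
#: for strongly suppressed spectral leakage of the conjugate sideband.
TAPER_PX = 32


@dataclass
class ComplexField:
    """Complex amplitude on the object-space grid."""

    data: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("complex field contains non-finite values")


@dataclass
class PhaseMap:
    """Phase grid in radians with wrap state and provenance metadata."""

    phase: np.ndarray
    wrapped: bool
    pitch_um: float
    quality: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


def border_mask(shape: tuple[int, int], border: int = BORDER_PX) -> np.ndarray:
    """Boolean mask that is True in the interior, False on the border."""
    m = np.zeros(shape, dtype=bool)
    m[border:-border or None, border:-border or None] = True
    return m


def demodulate(
    hologram: Hologram,
    carrier: tuple[float, float] | None = None,
    bandwidth: float | None = None,
    apodize: bool = True,
    remove_dc: bool = True,
) -> ComplexField:
    """Extract the baseband complex field from the +1 carrier sideband.

    Parameters
    ----------
    carrier : (νx, νy) in cycles/µm, optional
        Defaults to the carrier recorded in the hologram metadata.
    bandwidth : float, optional
        Radius of the circular pass band, cycles/µm.  Default: half the
        carrier magnitude (the largest band that still separates the
        sideband from the DC term of comparable width).
    remove_dc : bool
        Subtract a Gaussian low-pass estimate of the zero-order
        (non-interference) intensity before demodulation.  Without this the
        apodization window spreads the strong DC term into the pass band,
        leaving a phase ripple floor on otherwise noiseless holograms.

    Raises
    ------
    ValueError
        If the pass band would overlap the DC term (bandwidth > |ν_c|/2).
    """
    carrier = carrier if carrier is not None else hologram.carrier
    nu = math.hypot(*carrier)
    if nu == 0:
        raise ValueError("zero carrier frequency: no sideband to demodulate")
    if bandwidth is None:
        bandwidth = nu / 2.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if bandwidth > nu / 2.0 * (1.0 + 1e-9):
        raise ValueError(
            "sideband/DC overlap: pass-band radius "
            f"{bandwidth:.4f} cycles/um exceeds half the carrier offset "
            f"{nu / 2.0:.4f} cycles/um"
        )

    intensity = hologram.intensity
    if remove_dc:
        # the smoothing kernel estimates the zero-order term: it must be
        # opaque at the carrier (attenuation exp(-2 pi^2 sigma^2 f_c^2),
        # ~1e-12 at sigma = 1.2/f_c) while passing slow DC variations
        f_c_px = nu * hologram.pitch_um
        sigma_px = 1.2 / f_c_px
        intensity = intensity - ndimage.gaussian_filter(intensity, sigma_px)
    ny, nx = intensity.shape
    x, y = grid_coords(intensity.shape, hologram.pitch_um)
    demod = intensity * np.exp(
        -2.0j * math.pi * (carrier[0] * x + carrier[1] * y)
    )
    if apodize:
        win = np.outer(
            tukey(ny, min(1.0, 2.0 * TAPER_PX / ny)),
            tukey(nx, min(1.0, 2.0 * TAPER_PX / nx)),
        )
        demod = demod * win

    spec = np.fft.fft2(demod)
    fy = np.fft.fftfreq(ny, d=hologram.pitch_um)
    fx = np.fft.fftfreq(nx, d=hologram.pitch_um)
    fxx, fyy = np.meshgrid(fx, fy)
    mask = fxx**2 + fyy**2 <= bandwidth**2
    field = np.fft.ifft2(spec * mask)
    return ComplexField(data=field, pitch_um=hologram.pitch_um)


def wrapped_phase(field: ComplexField) -> PhaseMap:
    """Element-wise argument in (−π, π] with a low-quality mask.

    Zero-amplitude pixels carry no phase information; they are assigned
    phase 0 and flagged in the quality map (quality = |field|, exactly 0
    where degenerate).
    """
    amp = np.abs(field.data)
    phase = np.angle(field.data)
    phase = np.where(amp == 0.0, 0.0, phase)
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (−π, π] contract
    phase = np.where(phase == -math.pi, math.pi, phase)
    return PhaseMap(
        phase=phase, wrapped=True, pitch_um=field.pitch_um, quality=amp
    )


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * a))


def _poly_design(shape: tuple[int, int], pitch_um: float, order: int) -> np.ndarray:
    x, y = grid_coords(shape, pitch_um)
    xn = x / np.abs(x).max() if np.abs(x).max() > 0 else x
    yn = y / np.abs(y).max() if np.abs(y).max() > 0 else y
    cols = [
        (xn**i * yn**j).ravel()
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.stack(cols, axis=1)


def subtract_background(
    phase: PhaseMap, reference: "PhaseMap | int" = 1
) -> PhaseMap:
    """Remove the background phase.

    ``reference`` is either a stored background :class:`PhaseMap` (e.g. the
    non-addressed SLM reconstruction), subtracted with wrapped arithmetic
    when either operand is wrapped, or an integer polynomial order: a
    least-squares 2-D polynomial fit (default order 1 — piston + tilt) is
    removed from the map.  The polynomial fit is made robust by iterative
    sigma-clipping so that compact foreground objects (cells, programmed
    regions) do not drag the background estimate — otherwise the fitted
    piston absorbs part of the object signal itself.
    """
    if isinstance(reference, PhaseMap):
        if reference.shape != phase.shape:
            raise ValueError(
                f"grid mismatch: {phase.shape} vs {reference.shape}"
            )
        diff = phase.phase - reference.phase
        if phase.wrapped or reference.wrapped:
            return PhaseMap(
                phase=_wrap(diff), wrapped=True, pitch_um=phase.pitch_um,
                quality=phase.quality,
                meta={**phase.meta, "background": "reference"},
            )
        return PhaseMap(
            phase=diff, wrapped=False, pitch_um=phase.pitch_um,
            quality=phase.quality, meta={**phase.meta, "background": "reference"},
        )
    order = int(reference)
    design = _poly_design(phase.shape, phase.pitch_um, order)
    target = phase.phase.ravel()
    keep = np.ones(target.size, dtype=bool)
    for _ in range(5):
        coef, *_ = np.linalg.lstsq(design[keep], target[keep], rcond=None)
        resid = target - design @ coef
        center = np.median(resid[keep])
        # MAD-based scale so foreground objects cannot inflate the clip
        mad = np.median(np.abs(resid[keep] - center))
        if mad == 0:
            break
        keep = np.abs(resid - center) < 2.0 * 1.4826 * mad
    fitted = (design @ coef).reshape(phase.shape)
    out = phase.phase - fitted
    return PhaseMap(
        phase=_wrap(out) if phase.wrapped else out,
        wrapped=phase.wrapped,
        pitch_um=phase.pitch_um,
        quality=phase.quality,
        meta={**phase.meta, "background": f"poly:{order}"},
    )


def residue_count(wrapped: np.ndarray) -> int:
    """Number of phase residues (non-closing 2×2 plaquette loops)."""
    dx = _wrap(np.diff(wrapped, axis=1))
    dy = _wrap(np.diff(wrapped, axis=0))
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return int(np.sum(np.abs(loop) > math.pi))


def unwrap(phase: PhaseMap) -> PhaseMap:
    """2-D phase unwrapping (reliability-sorted region growing).

    Exact (up to one global 2π offset) for noiseless smooth inputs whose
    true per-pixel gradients stay below π; degrades gracefully on noisy
    maps.  The residue count of the wrapped input is reported in the
    metadata as a quality diagnostic.
    """
    if not phase.wrapped:
        return PhaseMap(
            phase=phase.phase.copy(), wrapped=False, pitch_um=phase.pitch_um,
            quality=phase.quality, meta=dict(phase.meta),
        )
    n_res = residue_count(phase.phase)
    out = np.asarray(_unwrap_2d(phase.phase), dtype=float)
    return PhaseMap(
        phase=out, wrapped=False, pitch_um=phase.pitch_um,
        quality=phase.quality, meta={**phase.meta, "residues": n_res},
    )


def lowpass_denoise(
    phase: PhaseMap, sigma_um: float, detrend_order: int = 2
) -> PhaseMap:
    """Denoise an unwrapped map by detrended Gaussian smoothing.

    A 2-D polynomial of ``detrend_order`` is fitted and removed, the
    residual is Gaussian-smoothed with width ``sigma_um``, and the trend is
    added back.  Unlike direct smoothing this is exactly unbiased on
    polynomial profiles up to the detrend order (e.g. the parabolic phase
    of a lens), including at the grid borders; genuine features larger
    than a few ``sigma_um`` pass attenuation-free.
    """
    if phase.wrapped:
        raise ValueError("denoising operates on unwrapped maps")
    design = _poly_design(phase.shape, phase.pitch_um, detrend_order)
    coef, *_ = np.linalg.lstsq(design, phase.phase.ravel(), rcond=None)
    trend = (design @ coef).reshape(phase.shape)
    resid = phase.phase - trend
    smooth = ndimage.gaussian_filter(resid, sigma_um / phase.pitch_um)
    return PhaseMap(
        phase=trend + smooth,
        wrapped=False,
        pitch_um=phase.pitch_um,
        quality=phase.quality,
        meta={**phase.meta, "denoise_sigma_um": sigma_um,
              "denoise_detrend_order": detrend_order},
    )


def reconstruct_retardance(
    hologram: Hologram,
    carrier: tuple[float, float] | None = None,
    bandwidth: float | None = None,
    background: "PhaseMap | int | None" = None,
    do_unwrap: bool = False,
) -> PhaseMap:
    """Convenience pipeline: demodulate → wrapped phase → [background] → [unwrap]."""
    pm = wrapped_phase(demodulate(hologram, carrier, bandwidth))
    if do_unwrap:
        pm = unwrap(pm)
    if background is not None:
        pm = subtract_background(pm, background)
    return pm
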
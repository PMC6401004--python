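"""Jones calculus in the circular basis for polarization-coded interferometry.

All operators act on the column vector ``(e_L, e_R)`` of left- and
right-handed circular amplitudes.  The handedness convention is fixed once
for the whole package: the LHCP unit vector is ``(x̂ + i ŷ)/√2`` seen from
the receiver, so a field ``E = (E_x, E_y)`` decomposes as

    e_L = (E_x − i E_y)/√2,    e_R = (E_x + i E_y)/√2.

The geometric-phase grating is the key element: a half-wave-like anisotropic
structure whose local fast-axis orientation ``φ(x, y)`` rotates in space.
It swaps handedness and imprints the geometric (Pancharatnam–Berry) phase
``±2φ``, with opposite sign for the two circular inputs — the mechanism that
deflects LHCP and RHCP into opposite diffraction orders and makes the fringe
carrier achromatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JonesVector",
    "JonesOperator",
    "LIN_TO_CIRC",
    "gpg_operator",
    "waveplate_operator",
    "analyzer_operator",
    "mirror_operator",
    "grating_deflection",
    "from_linear",
]

#: Basis-change matrix mapping linear amplitudes (E_x, E_y) to circular
#: amplitudes (e_L, e_R) under the package convention.
LIN_TO_CIRC = np.array(
    [[1.0, -1.0j], [1.0, 1.0j]], dtype=complex
) / math.sqrt(2.0)

_CIRC_TO_LIN = LIN_TO_CIRC.conj().T  # unitary inverse


@dataclass(frozen=True)
class JonesVector:
    """Polarization state as circular-basis amplitudes.

    Parameters
    ----------
    e_L, e_R : complex
        Left-/right-handed circular amplitudes. A global phase factor leaves
        every observable (intensity, degree of circularity) unchanged.
    """

    e_L: complex
    e_R: complex

    @property
    def intensity(self) -> float:
        """Total intensity ``|e_L|² + |e_R|²``."""
        return abs(self.e_L) ** 2 + abs(self.e_R) ** 2

    def as_array(self) -> np.ndarray:
        return np.array([self.e_L, self.e_R], dtype=complex)


@dataclass(frozen=True)
class JonesOperator:
    """2×2 complex operator acting on ``(e_L, e_R)``.

    Lossless elements (gratings, waveplates, mirrors) are unitary; a
    polarizer is an idempotent rank-1 projector.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=complex)
        if m.shape != (2, 2):
            raise ValueError(f"Jones operator must be 2x2, got {m.shape}")
        object.__setattr__(self, "m", m)

    def __call__(self, v: JonesVector) -> JonesVector:
        out = self.m @ v.as_array()
        return JonesVector(out[0], out[1])

    def __matmul__(self, other: "JonesOperator") -> "JonesOperator":
        return JonesOperator(self.m @ other.m)

    def is_unitary(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.m.conj().T @ self.m, np.eye(2), atol=atol)
        )

    def is_projector(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.m @ self.m, self.m, atol=atol))


def from_linear(e_x: complex, e_y: complex) -> JonesVector:
    """Build a :class:`JonesVector` from linear-basis amplitudes."""
    e_l, e_r = LIN_TO_CIRC @ np.array([e_x, e_y], dtype=complex)
    return JonesVector(e_l, e_r)


def gpg_operator(phi: float) -> JonesOperator:
    """Geometric-phase grating at local anisotropy-axis orientation ``phi``.

    Acts as an ideal half-wave structure: handedness is swapped and the
    geometric phase ``±2·phi`` is imprinted with opposite signs on the two
    circular components.  An LHCP input emerges RHCP with phase ``+2·phi``;
    an RHCP input emerges LHCP with phase ``−2·phi``.

    Parameters
    ----------
    phi : float
        Local orientation of the anisotropy axis, radians. Must be finite.
    """
    if not np.isfinite(phi):
        raise ValueError(f"anisotropy-axis orientation must be finite, got {phi}")
    # column j = image of basis state j: L -> e^{+2iφ} R, R -> e^{-2iφ} L
    return JonesOperator(
        np.array(
            [
                [0.0, np.exp(-2.0j * phi)],
                [np.exp(+2.0j * phi), 0.0],
            ],
            dtype=complex,
        )
    )


def waveplate_operator(retardance: float, azimuth: float) -> JonesOperator:
    """Linear retarder of given retardance with fast axis at ``azimuth``.

    Constructed in the linear basis as R(θ)·diag(e^{−iδ/2}, e^{+iδ/2})·R(−θ)
    and conjugated into the circular basis.  A quarter-wave plate
    (δ = π/2) at 45° maps horizontal/vertical linear light to pure circular
    states, which is how the interferometer's orthogonal linear sample and
    reference polarizations are converted to LHCP/RHCP.
    """
    c, s = math.cos(azimuth), math.sin(azimuth)
    rot = np.array([[c, -s], [s, c]], dtype=complex)
    ret = np.array(
        [
            [np.exp(-0.5j * retardance), 0.0],
            [0.0, np.exp(+0.5j * retardance)],
        ],
        dtype=complex,
    )
    lin = rot @ ret @ rot.T
    return JonesOperator(LIN_TO_CIRC @ lin @ _CIRC_TO_LIN)


def analyzer_operator(angle: float) -> JonesOperator:
    """Linear polarizer (analyzer) transmitting the direction ``angle``.

    Projects both circular components onto one linear state so that the
    polarization-coded sample and reference waves can interfere.  For equal
    circular amplitudes with relative phase δ the transmitted intensity is
    ∝ (1 + cos(δ + c)) where the offset c depends only on the analyzer
    angle.
    """
    c, s = math.cos(angle), math.sin(angle)
    proj_lin = np.array([[c * c, c * s], [c * s, s * s]], dtype=complex)
    return JonesOperator(LIN_TO_CIRC @ proj_lin @ _CIRC_TO_LIN)


def mirror_operator() -> JonesOperator:
    """Ideal metallic mirror: handedness swap, no added phase.

    Real mirror phase shifts are common to both arms and absorbed into the
    background phase.
    """
    return JonesOperator(np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex))


def grating_deflection(
    period_phase_um: float, wavelength_um: float
) -> tuple[float, float]:
    """First-order deflection of the geometric-phase grating.

    Parameters
    ----------
    period_phase_um : float
        Spatial period of one full 2π ramp of the *geometric phase*, µm.
        (For a grating whose anisotropy axis rotates by 2π over Λ_axis the
        phase 2φ ramps twice as fast; pass the phase period explicitly.)
    wavelength_um : float
        Vacuum wavelength, µm; must satisfy 0 < λ < Λ.

    Returns
    -------
    (order_angle_deg, mutual_angle_deg)
        Deflection angle of one first order, and the mutual angle between
        the +1st and −1st orders (twice the former).
    """
    if not (wavelength_um > 0 and period_phase_um > 0):
        raise ValueError("period and wavelength must be positive")
    if wavelength_um >= period_phase_um:
        raise ValueError(
            f"no propagating first order: wavelength {wavelength_um} um >= "
            f"phase period {period_phase_um} um"
        )
    order = math.degrees(math.asin(wavelength_um / period_phase_um))
    return order, 2.0 * order
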
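"""Synthetic scene generators with ground truth.

A :class:`SceneSpec` describes the two polarization-coded arms of the
interferometer as per-wavelength phase functions on a common object-space
grid.  Phase is split into an *achromatic* part (geometric phase, programmed
liquid-crystal retardance) and an *optical-path* part expressed in
nanometres (mirror topography, cellular dry mass), whose phase contribution
scales as 2π·OPD/λ.  This split is what produces coherence gating for
broadband light while geometric-phase elements stay wavelength independent.

Coordinate convention: pixel centers, origin at the grid center, x to the
right along columns, y downward along rows, 0-based indices.

Generators
----------
``mirror_scene``      piezo-displaced plane mirror (height metrology)
``slm_scene``         per-pixel programmed retardance of an SLM display
``gp_lens_scene``     polarization-directed (geometric-phase) flat lens
``cell_phantom``      Gaussian-blob live-cell dry-mass phantoms
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Spectrum",
    "SceneSpec",
    "CELLTABLE_COLUMNS",
    "make_spectrum",
    "mirror_scene",
    "slm_scene",
    "gp_lens_scene",
    "cell_phantom",
    "cell_phantom_series",
    "grid_coords",
    "scene_from_descriptor",
    "DAVIES_ALPHA_UM3_PER_PG",
]

#: Specific refractive increment of cellular dry matter (Davies relation),
#: µm³/pg.  Conventional value; exposed so callers can override.
DAVIES_ALPHA_UM3_PER_PG = 0.18

CELLTABLE_COLUMNS = [
    "frame",
    "label",
    "area_um2",
    "mean_density_pg_um2",
    "total_mass_pg",
]


@dataclass(frozen=True)
class Spectrum:
    """Sampled broadband source: wavelengths (nm) with normalized weights."""

    wavelengths_nm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.shape != p.shape:
            raise ValueError("wavelengths and weights must be matching 1-D arrays")
        if np.any(p < 0):
            raise ValueError("spectral weights must be nonnegative")
        if w.size > 1 and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("spectral weights must sum to 1")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "weights", p)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def center_nm(self) -> float:
        return float(np.sum(self.wavelengths_nm * self.weights))

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "weights": self.weights.tolist(),
        }


def make_spectrum(center_nm: float, fwhm_nm: float, n_samples: int) -> Spectrum:
    """Gaussian spectral band sampled at equally spaced wavelengths.

    Samples span ±2σ around the center (σ = FWHM/2√(2 ln 2)); weights follow
    the Gaussian line shape and are renormalized to sum to one.
    ``n_samples=1`` (or zero bandwidth) yields a monochromatic line.

    The coherence length of the band is λ_c = center²/FWHM — 7.2 µm for the
    600/50 nm band used throughout.
    """
    if center_nm <= 0:
        raise ValueError(f"central wavelength must be positive, got {center_nm}")
    if fwhm_nm < 0:
        raise ValueError("bandwidth must be nonnegative")
    if n_samples < 1:
        raise ValueError("need at least one spectral sample")
    if n_samples == 1 or fwhm_nm == 0:
        return Spectrum(np.array([center_nm]), np.array([1.0]))
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lam = np.linspace(center_nm - 2 * sigma, center_nm + 2 * sigma, n_samples)
    w = np.exp(-0.5 * ((lam - center_nm) / sigma) ** 2)
    w = w / w.sum()
    return Spectrum(lam, w)


def coherence_length_um(center_nm: float, fwhm_nm: float) -> float:
    """Coherence length λ²/Δλ in µm."""
    return center_nm**2 / fwhm_nm * 1e-3


def grid_coords(shape: tuple[int, int], pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Object-space coordinate grids (x, y) in µm, origin at grid center."""
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch_um
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch_um
    return np.meshgrid(x, y)


@dataclass
class SceneSpec:
    """Per-polarization phase description of one simulated scene.

    The sample/reference arm phase at wavelength λ (nm) is

        Φ(x, y; λ) = phase_const(x, y) + 2π · opd_nm(x, y)/λ

    so achromatic (geometric/programmed) contributions live in
    ``phase_*_const`` and physical optical-path contributions in
    ``opd_*_nm``.  ``ground_truth`` carries whatever the generator knows
    about the scene (height, programmed phase, lens phase, CellTable).
    """

    shape: tuple[int, int]
    pitch_um: float
    phase_s_const: np.ndarray | float = 0.0
    phase_r_const: np.ndarray | float = 0.0
    opd_s_nm: np.ndarray | float = 0.0
    opd_r_nm: np.ndarray | float = 0.0
    amp_s: np.ndarray | float = 1.0
    amp_r: np.ndarray | float = 1.0
    ground_truth: dict[str, Any] = field(default_factory=dict)
    descriptor: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("phase_s_const", "phase_r_const", "opd_s_nm", "opd_r_nm"):
            val = getattr(self, name)
            if np.ndim(val) and np.asarray(val).shape != tuple(self.shape):
                raise ValueError(f"{name} shape mismatch with scene grid")
            if not np.all(np.isfinite(val)):
                raise ValueError(f"{name} contains non-finite values")

    def _phase(self, const, opd, lam_nm: float) -> np.ndarray:
        out = np.broadcast_to(np.asarray(const, dtype=float), self.shape).copy()
        opd = np.asarray(opd, dtype=float)
        if np.any(opd != 0):
            out += 2.0 * math.pi * np.broadcast_to(opd, self.shape) / lam_nm
        return out

    def sample_phase(self, lam_nm: float) -> np.ndarray:
        return self._phase(self.phase_s_const, self.opd_s_nm, lam_nm)

    def reference_phase(self, lam_nm: float) -> np.ndarray:
        return self._phase(self.phase_r_const, self.opd_r_nm, lam_nm)

    def retardance(self, lam_nm: float) -> np.ndarray:
        """Φ_s − Φ_r at the given wavelength — the restorable quantity."""
        return self.sample_phase(lam_nm) - self.reference_phase(lam_nm)

    def sample_amplitude(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.amp_s, dtype=float), self.shape)

    def reference_amplitude(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.amp_r, dtype=float), self.shape)


def mirror_scene(
    shape: tuple[int, int], pitch_um: float, dz_nm: float
) -> SceneSpec:
    """Plane mirror displaced by ``dz_nm`` along the optical axis.

    Reflection geometry: the light passes the displacement twice, so the
    sample-arm phase is 4π·dz/λ, uniform over the field.  The calibrated
    piezo range is ±1 µm.
    """
    if abs(dz_nm) > 1000.0:
        raise ValueError(
            f"displacement {dz_nm} nm outside the calibrated +-1000 nm range"
        )
    return SceneSpec(
        shape=tuple(shape),
        pitch_um=float(pitch_um),
        opd_s_nm=2.0 * dz_nm if dz_nm else 0.0,
        ground_truth={"height_nm": float(dz_nm)},
        descriptor={"kind": "mirror", "shape": list(shape), "pitch_um": pitch_um,
                    "dz_nm": dz_nm},
    )


def slm_scene(
    shape: tuple[int, int],
    pitch_um: float,
    pixel_size_um: float,
    phase_matrix: np.ndarray,
    crosstalk_sigma_um: float = 0.0,
) -> SceneSpec:
    """Spatial light modulator with per-pixel programmed phase.

    The SLM pixel grid is centered on the field; each grid pixel inherits
    the programmed phase of the SLM pixel it falls in (piecewise constant),
    optionally blurred by a Gaussian of width ``crosstalk_sigma_um`` to
    emulate inter-pixel crosstalk.  The programmed retardance is treated as
    wavelength independent over the illumination band.  The reference arm is
    unmodulated.
    """
    phase_matrix = np.atleast_2d(np.asarray(phase_matrix, dtype=float))
    if not np.all(np.isfinite(phase_matrix)):
        raise ValueError("phase_matrix contains non-finite values")
    if pixel_size_um < pitch_um:
        raise ValueError(
            f"SLM pixel ({pixel_size_um} um) smaller than grid pitch ({pitch_um} um)"
        )
    x, y = grid_coords(shape, pitch_um)
    n_py, n_px = phase_matrix.shape
    # SLM panel centered on the field; indices of the SLM pixel under each
    # grid point, -1 outside the panel
    ix = np.floor(x / pixel_size_um + n_px / 2.0).astype(int)
    iy = np.floor(y / pixel_size_um + n_py / 2.0).astype(int)
    inside = (ix >= 0) & (ix < n_px) & (iy >= 0) & (iy < n_py)
    phase = np.zeros(tuple(shape), dtype=float)
    phase[inside] = phase_matrix[iy[inside], ix[inside]]
    if crosstalk_sigma_um > 0:
        phase = ndimage.gaussian_filter(phase, crosstalk_sigma_um / pitch_um)
    return SceneSpec(
        shape=tuple(shape),
        pitch_um=float(pitch_um),
        phase_s_const=phase,
        ground_truth={
            "phase_matrix": phase_matrix,
            "pixel_size_um": float(pixel_size_um),
        },
        descriptor={
            "kind": "slm",
            "shape": list(shape),
            "pitch_um": pitch_um,
            "pixel_size_um": pixel_size_um,
            "phase_matrix": phase_matrix.tolist(),
            "crosstalk_sigma_um": crosstalk_sigma_um,
        },
    )


def slm_pixel_mask(
    scene: SceneSpec, row: int, col: int, shrink: float = 0.0
) -> np.ndarray:
    """Boolean mask of the grid pixels belonging to SLM pixel (row, col).

    ``shrink`` trims the mask to the central (1−2·shrink) fraction of the
    pixel in each direction, useful for excluding edge transition zones.
    """
    gt = scene.ground_truth
    pm = gt["phase_matrix"]
    size = gt["pixel_size_um"]
    n_py, n_px = pm.shape
    x, y = grid_coords(scene.shape, scene.pitch_um)
    x0 = (col - n_px / 2.0) * size
    y0 = (row - n_py / 2.0) * size
    m = shrink * size
    return (
        (x >= x0 + m)
        & (x < x0 + size - m)
        & (y >= y0 + m)
        & (y < y0 + size - m)
    )


def gp_lens_scene(
    shape: tuple[int, int],
    pitch_um: float,
    focal_length_mm: float = 100.0,
    design_wavelength_nm: float = 600.0,
    aperture_halfwidth_mm: float | None = None,
) -> SceneSpec:
    """Polarization-directed flat lens encoded in geometric phase.

    The single-pass geometric phase is the parabolic profile
    φ(x, y) = −π r²/(λ₀ f).  The two circular components acquire conjugate
    phases, so the sample arm carries +φ and the reference arm −φ and the
    restorable retardance is 2φ.  Being geometric, the phase is wavelength
    independent.  ``aperture_halfwidth_mm`` limits the phase to a centered
    square aperture; by default the whole field is the aperture.
    """
    if focal_length_mm == 0:
        raise ValueError("focal length must be nonzero")
    x, y = grid_coords(shape, pitch_um)
    lam_um = design_wavelength_nm * 1e-3
    f_um = focal_length_mm * 1e3
    phi = -math.pi * (x**2 + y**2) / (lam_um * f_um)
    if aperture_halfwidth_mm is not None:
        a_um = aperture_halfwidth_mm * 1e3
        phi = np.where((np.abs(x) <= a_um) & (np.abs(y) <= a_um), phi, 0.0)
    return SceneSpec(
        shape=tuple(shape),
        pitch_um=float(pitch_um),
        phase_s_const=+phi,
        phase_r_const=-phi,
        ground_truth={
            "single_pass_phase": phi,
            "focal_length_mm": float(focal_length_mm),
            "design_wavelength_nm": float(design_wavelength_nm),
        },
        descriptor={
            "kind": "gp_lens",
            "shape": list(shape),
            "pitch_um": pitch_um,
            "focal_length_mm": focal_length_mm,
            "design_wavelength_nm": design_wavelength_nm,
            "aperture_halfwidth_mm": aperture_halfwidth_mm,
        },
    )


def _place_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int],
    pitch_um: float,
    n_cells: int,
    sigma_range_um: tuple[float, float],
    edge_margin_um: float = 8.0,
    max_tries: int = 4000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping blob centers; (x, y, sigma) in µm.

    Cells keep 3σ plus ``edge_margin_um`` clear of the field edge so their
    mass stays inside the analyzable region of downstream reconstructions.
    """
    ny, nx = shape
    half_x = nx * pitch_um / 2.0
    half_y = ny * pitch_um / 2.0
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in "
                f"{max_tries} tries; enlarge the field or reduce n_cells"
            )
        tries += 1
        sigma = rng.uniform(*sigma_range_um)
        margin = 3.0 * sigma + edge_margin_um
        if 2 * margin >= 2 * half_x or 2 * margin >= 2 * half_y:
            continue
        cx = rng.uniform(-half_x + margin, half_x - margin)
        cy = rng.uniform(-half_y + margin, half_y - margin)
        if all(
            math.hypot(cx - px, cy - py) > 3.0 * (sigma + ps)
            for px, py, ps in placed
        ):
            placed.append((cx, cy, sigma))
    return placed


def _phantom_scene(
    shape: tuple[int, int],
    pitch_um: float,
    blobs: list[tuple[float, float, float, float]],
    frame: int,
    alpha_um3_per_pg: float,
    passes: int,
    descriptor: dict[str, Any],
) -> SceneSpec:
    """Assemble density/phase maps and ground-truth table from blob params."""
    x, y = grid_coords(shape, pitch_um)
    density = np.zeros(tuple(shape), dtype=float)
    rows = []
    for label, (cx, cy, sigma, mass) in enumerate(blobs, start=1):
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        blob = mass / (2.0 * math.pi * sigma**2) * np.exp(-0.5 * r2 / sigma**2)
        density += blob
        mask = blob > 0.05 * blob.max()
        area = mask.sum() * pitch_um**2
        rows.append(
            {
                "frame": frame,
                "label": label,
                "area_um2": area,
                "mean_density_pg_um2": float(blob[mask].mean()),
                "total_mass_pg": float(blob.sum() * pitch_um**2),
            }
        )
    # Davies relation: OPD = alpha * passes * surface density
    opd_nm = 1e3 * alpha_um3_per_pg * passes * density
    table = pd.DataFrame(rows, columns=CELLTABLE_COLUMNS)
    return SceneSpec(
        shape=tuple(shape),
        pitch_um=float(pitch_um),
        opd_s_nm=opd_nm,
        ground_truth={
            "density_pg_um2": density,
            "cell_table": table,
            "alpha_um3_per_pg": alpha_um3_per_pg,
            "passes": passes,
            "blobs": blobs,
        },
        descriptor=descriptor,
    )


def cell_phantom(
    shape: tuple[int, int],
    pitch_um: float,
    n_cells: int,
    total_mass_range_pg: tuple[float, float] = (150.0, 400.0),
    seed: int | None = None,
    sigma_range_um: tuple[float, float] = (6.0, 9.0),
    alpha_um3_per_pg: float = DAVIES_ALPHA_UM3_PER_PG,
    passes: int = 2,
    edge_margin_um: float = 8.0,
) -> SceneSpec:
    """Live-cell phantom: non-overlapping Gaussian dry-mass blobs.

    Each cell is a 2-D Gaussian surface-density profile of known integrated
    dry mass (pg); the sample-arm OPD follows the Davies relation
    OPD = α·passes·ρ, with the double-pass reflective geometry by default.
    Ground truth includes the density map and a per-cell table.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    centers = _place_blobs(rng, shape, pitch_um, n_cells, sigma_range_um,
                           edge_margin_um)
    masses = rng.uniform(*total_mass_range_pg, size=n_cells)
    blobs = [(cx, cy, s, m) for (cx, cy, s), m in zip(centers, masses)]
    descriptor = {
        "kind": "cell_phantom",
        "shape": list(shape),
        "pitch_um": pitch_um,
        "n_cells": n_cells,
        "total_mass_range_pg": list(total_mass_range_pg),
        "seed": seed,
        "sigma_range_um": list(sigma_range_um),
        "alpha_um3_per_pg": alpha_um3_per_pg,
        "passes": passes,
        "edge_margin_um": edge_margin_um,
    }
    return _phantom_scene(
        shape, pitch_um, blobs, 0, alpha_um3_per_pg, passes, descriptor
    )


def cell_phantom_series(
    shape: tuple[int, int],
    pitch_um: float,
    n_cells: int,
    n_frames: int,
    area_growth_per_frame: float = 0.0,
    total_mass_range_pg: tuple[float, float] = (150.0, 400.0),
    seed: int | None = None,
    sigma_range_um: tuple[float, float] = (6.0, 9.0),
    alpha_um3_per_pg: float = DAVIES_ALPHA_UM3_PER_PG,
    passes: int = 2,
    edge_margin_um: float = 8.0,
) -> list[SceneSpec]:
    """Time-lapse phantom: cells spread while conserving dry mass.

    Per frame the blob area grows by ``area_growth_per_frame`` (fractional),
    i.e. σ² scales by (1+g)ᵗ with the integrated mass held fixed — area up,
    mean density down, emulating spreading cells.
    """
    base = cell_phantom(
        shape, pitch_um, n_cells, total_mass_range_pg, seed,
        sigma_range_um, alpha_um3_per_pg, passes, edge_margin_um,
    )
    blobs0 = base.ground_truth["blobs"]
    frames = []
    for t in range(n_frames):
        scale = (1.0 + area_growth_per_frame) ** (t / 2.0)  # sigma ~ sqrt(area)
        blobs = [(cx, cy, s * scale, m) for cx, cy, s, m in blobs0]
        desc = dict(base.descriptor, kind="cell_phantom_series", frame=t,
                    n_frames=n_frames, area_growth_per_frame=area_growth_per_frame)
        frames.append(
            _phantom_scene(shape, pitch_um, blobs, t, alpha_um3_per_pg,
                           passes, desc)
        )
    return frames


def scene_from_descriptor(descriptor: dict[str, Any]) -> SceneSpec:
    """Rebuild a scene bit-for-bit from its JSON descriptor."""
    d = dict(descriptor)
    kind = d.pop("kind")
    d["shape"] = tuple(d["shape"])
    if kind == "mirror":
        return mirror_scene(d["shape"], d["pitch_um"], d["dz_nm"])
    if kind == "slm":
        return slm_scene(
            d["shape"], d["pitch_um"], d["pixel_size_um"],
            np.asarray(d["phase_matrix"]), d.get("crosstalk_sigma_um", 0.0),
        )
    if kind == "gp_lens":
        return gp_lens_scene(
            d["shape"], d["pitch_um"], d["focal_length_mm"],
            d["design_wavelength_nm"], d.get("aperture_halfwidth_mm"),
        )
    if kind == "cell_phantom":
        return cell_phantom(
            d["shape"], d["pitch_um"], d["n_cells"],
            tuple(d["total_mass_range_pg"]), d["seed"],
            tuple(d["sigma_range_um"]), d["alpha_um3_per_pg"], d["passes"],
            d.get("edge_margin_um", 8.0),
        )
    raise ValueError(f"unknown scene kind {kind!r}")
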
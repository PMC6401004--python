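"""Physical quantification of restored phase and precision protocols.

Conversions
-----------
Height (reflective double pass):      δz = λ·Φ/(4π)
Dry-mass surface density (Davies):    ρ  = λ·Φ/(2π·α·passes)

with α the specific refractive increment of cellular dry matter
(default 0.18 µm³/pg) and ``passes`` the number of times light traverses
the specimen (2 in the reflective geometry).

Precision protocols
-------------------
``temporal_stability``  σ_T: std over time of ROI-mean height in small
    (diffraction-spot sized) regions of interest, averaged over a lattice
    of ROIs.
``spatial_noise``       σ_Z: spatial std of height in blank square areas
    (default nine 20×20 µm² ROIs spread over the field).
``accuracy_metrics``    per-step mean error and RMSE of measured versus
    ground-truth displacement across repeated experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gpqpi.reconstruct import PhaseMap
from gpqpi.scenes import DAVIES_ALPHA_UM3_PER_PG

__all__ = [
    "HeightMap",
    "DryMassMap",
    "StabilityReport",
    "AccuracyReport",
    "phase_to_height",
    "phase_to_drymass",
    "drymass_to_phase",
    "temporal_stability",
    "spatial_noise",
    "accuracy_metrics",
    "roi_lattice",
]

#: Default diffraction-spot (Airy) ROI radius: 0.61·λ/NA at 600 nm, NA 0.3.
DIFFRACTION_SPOT_RADIUS_UM = 0.61 * 0.6 / 0.3


@dataclass
class HeightMap:
    """Surface-height grid in nm."""

    height_nm: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.height_nm = np.asarray(self.height_nm, dtype=float)
        if not np.all(np.isfinite(self.height_nm)):
            raise ValueError("height map contains non-finite values")


@dataclass
class DryMassMap:
    """Dry-mass surface-density grid in pg/µm²."""

    density_pg_um2: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.density_pg_um2 = np.asarray(self.density_pg_um2, dtype=float)
        if not np.all(np.isfinite(self.density_pg_um2)):
            raise ValueError("density map contains non-finite values")


@dataclass
class StabilityReport:
    """Per-ROI standard deviations with their summary statistics (nm)."""

    per_roi_nm: np.ndarray
    n_frames: int
    roi_centers_px: list[tuple[int, int]]
    roi_size: str
    mean_nm: float = field(init=False)
    spread_nm: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_roi_nm = np.asarray(self.per_roi_nm, dtype=float)
        if np.any(self.per_roi_nm < 0):
            raise ValueError("standard deviations must be nonnegative")
        self.mean_nm = float(self.per_roi_nm.mean())
        self.spread_nm = float(self.per_roi_nm.std(ddof=0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_roi_nm": self.per_roi_nm.tolist(),
                "mean_nm": self.mean_nm,
                "spread_nm": self.spread_nm,
                "n_frames": self.n_frames,
                "roi_centers_px": self.roi_centers_px,
                "roi_size": self.roi_size,
            },
            indent=2,
        )


@dataclass
class AccuracyReport:
    """Per-step ME and RMSE (nm) of measured vs. ground-truth heights."""

    truth_nm: np.ndarray
    me_nm: np.ndarray
    rmse_nm: np.ndarray
    n_repeats: int

    def __post_init__(self) -> None:
        self.truth_nm = np.asarray(self.truth_nm, dtype=float)
        self.me_nm = np.asarray(self.me_nm, dtype=float)
        self.rmse_nm = np.asarray(self.rmse_nm, dtype=float)
        if np.any(self.rmse_nm + 1e-12 < np.abs(self.me_nm)):
            raise ValueError("RMSE must dominate |ME| at every step")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "truth_nm": self.truth_nm,
                "me_nm": self.me_nm,
                "rmse_nm": self.rmse_nm,
            }
        )


def _require_unwrapped(phase: PhaseMap, what: str) -> None:
    if phase.wrapped:
        raise ValueError(
            f"{what} requires an unwrapped phase map; run reconstruct.unwrap first"
        )


def phase_to_height(phase: PhaseMap, wavelength_nm: float) -> HeightMap:
    """Convert unwrapped phase to surface height, δz = λΦ/(4π)."""
    _require_unwrapped(phase, "height conversion")
    return HeightMap(
        height_nm=wavelength_nm * phase.phase / (4.0 * math.pi),
        pitch_um=phase.pitch_um,
    )


def phase_to_drymass(
    phase: PhaseMap,
    wavelength_nm: float,
    alpha_um3_per_pg: float = DAVIES_ALPHA_UM3_PER_PG,
    passes: int = 2,
) -> DryMassMap:
    """Convert unwrapped phase to dry-mass density via the Davies relation.

    ρ = λ·Φ/(2π·α·passes) in pg/µm² with λ in µm equivalents.
    """
    _require_unwrapped(phase, "dry-mass conversion")
    if alpha_um3_per_pg <= 0:
        raise ValueError("specific refractive increment must be positive")
    if passes not in (1, 2):
        raise ValueError("passes must be 1 (transmission) or 2 (reflection)")
    lam_um = wavelength_nm * 1e-3
    return DryMassMap(
        density_pg_um2=lam_um * phase.phase
        / (2.0 * math.pi * alpha_um3_per_pg * passes),
        pitch_um=phase.pitch_um,
    )


def drymass_to_phase(
    density: DryMassMap,
    wavelength_nm: float,
    alpha_um3_per_pg: float = DAVIES_ALPHA_UM3_PER_PG,
    passes: int = 2,
) -> PhaseMap:
    """Inverse Davies conversion (used by the phantom generator round trip)."""
    lam_um = wavelength_nm * 1e-3
    return PhaseMap(
        phase=2.0 * math.pi * alpha_um3_per_pg * passes
        * density.density_pg_um2 / lam_um,
        wrapped=False,
        pitch_um=density.pitch_um,
    )


def roi_lattice(
    shape: tuple[int, int], n_rois: int, margin_frac: float = 0.2
) -> list[tuple[int, int]]:
    """Centers (row, col) of a near-square ROI lattice with margins."""
    side = int(round(math.sqrt(n_rois)))
    if side * side != n_rois:
        raise ValueError("n_rois must be a perfect square (e.g. 9)")
    ny, nx = shape
    rows = np.linspace(margin_frac * ny, (1 - margin_frac) * ny, side)
    cols = np.linspace(margin_frac * nx, (1 - margin_frac) * nx, side)
    return [(int(round(r)), int(round(c))) for r in rows for c in cols]


def _disk_mask(
    shape: tuple[int, int], center: tuple[int, int], radius_px: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def temporal_stability(
    heights: Sequence[HeightMap],
    n_rois: int = 9,
    roi_radius_um: float = DIFFRACTION_SPOT_RADIUS_UM,
) -> StabilityReport:
    """Temporal stability σ_T from a height-map time series.

    For each circular ROI (diffraction-spot radius by default, on a 3×3
    lattice) the ROI-mean height is tracked over frames; the per-ROI σ is
    the std of that time series, and the report summarizes mean ± spread
    across ROIs.
    """
    if len(heights) < 2:
        raise ValueError("need at least two frames")
    shape = heights[0].height_nm.shape
    pitch = heights[0].pitch_um
    radius_px = roi_radius_um / pitch
    centers = roi_lattice(shape, n_rois)
    for r, c in centers:
        if (
            r - radius_px < 0 or r + radius_px >= shape[0]
            or c - radius_px < 0 or c + radius_px >= shape[1]
        ):
            raise ValueError("ROI extends outside the grid")
    masks = [_disk_mask(shape, ctr, radius_px) for ctr in centers]
    series = np.array(
        [[h.height_nm[m].mean() for m in masks] for h in heights]
    )  # (n_frames, n_rois)
    per_roi = series.std(axis=0, ddof=1)
    return StabilityReport(
        per_roi_nm=per_roi,
        n_frames=len(heights),
        roi_centers_px=centers,
        roi_size=f"disk r={roi_radius_um:g} um",
    )


def spatial_noise(
    height: HeightMap,
    n_rois: int = 9,
    roi_size_um: float = 20.0,
) -> StabilityReport:
    """Spatial background noise σ_Z in blank square areas.

    Default protocol: nine 20×20 µm² ROIs equally distributed over the
    field; per-ROI spatial std of height, summarized as mean ± spread.
    """
    shape = height.height_nm.shape
    half_px = int(round(roi_size_um / height.pitch_um / 2))
    centers = roi_lattice(shape, n_rois)
    per_roi = []
    for r, c in centers:
        if (
            r - half_px < 0 or r + half_px > shape[0]
            or c - half_px < 0 or c + half_px > shape[1]
        ):
            raise ValueError("ROI extends outside the grid")
        patch = height.height_nm[r - half_px : r + half_px, c - half_px : c + half_px]
        per_roi.append(patch.std(ddof=1))
    return StabilityReport(
        per_roi_nm=np.array(per_roi),
        n_frames=1,
        roi_centers_px=centers,
        roi_size=f"square {roi_size_um:g} um",
    )


def accuracy_metrics(
    measured_nm: np.ndarray, truth_nm: Sequence[float]
) -> AccuracyReport:
    """Per-step mean error and RMSE across repeats.

    ``measured_nm`` has shape (n_repeats, n_steps); ``truth_nm`` gives the
    ground-truth displacement of each step.
    """
    measured = np.atleast_2d(np.asarray(measured_nm, dtype=float))
    truth = np.asarray(truth_nm, dtype=float)
    if measured.shape[1] != truth.size:
        raise ValueError(
            f"step count mismatch: {measured.shape[1]} measured vs "
            f"{truth.size} truth values"
        )
    err = measured - truth[None, :]
    return AccuracyReport(
        truth_nm=truth,
        me_nm=err.mean(axis=0),
        rmse_nm=np.sqrt((err**2).mean(axis=0)),
        n_repeats=measured.shape[0],
    )
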
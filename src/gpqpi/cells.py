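"""Cell segmentation, morphometrics and tracking on dry-mass maps.

Cells are delineated on the dry-mass density image by marker-based
watershed: Gaussian smoothing, foreground thresholding (Otsu by default),
markers from h-maxima of the smoothed density, then watershed of the
inverted density restricted to the foreground.  Per-cell area, mean
density and total dry mass are tabulated, and labels are linked across
frames by greedy maximum-overlap matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import relabel_sequential, watershed

from gpqpi.quantify import DryMassMap
from gpqpi.scenes import CELLTABLE_COLUMNS

__all__ = ["LabelImage", "segment", "measure", "track", "Trajectory"]


@dataclass
class LabelImage:
    """Integer label grid: 0 = background, cells are 1..n_labels."""

    labels: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def segment(
    density: DryMassMap,
    smoothing_sigma_um: float = 1.0,
    background_threshold: float | None = None,
    h_depth: float | None = None,
    min_area_um2: float = 20.0,
) -> LabelImage:
    """Marker-based watershed segmentation of a dry-mass density map.

    Parameters
    ----------
    smoothing_sigma_um : float
        Gaussian pre-smoothing width (µm).
    background_threshold : float, optional
        Foreground threshold in pg/µm²; Otsu on the smoothed map when None.
    h_depth : float, optional
        Minimum peak prominence (pg/µm²) for watershed markers; defaults to
        10% of the smoothed map's dynamic range.
    min_area_um2 : float
        Regions smaller than this are dropped (reconstruction ringing and
        debris-sized specks, well below any cell footprint).

    Returns an all-background image (with a warning) when no foreground
    survives the threshold.
    """
    rho = density.density_pg_um2
    if not np.all(np.isfinite(rho)):
        raise ValueError("density map contains non-finite values")
    smooth = ndimage.gaussian_filter(rho, smoothing_sigma_um / density.pitch_um)
    if background_threshold is None:
        if smooth.max() <= smooth.min():
            warnings.warn("flat density map: nothing to segment", stacklevel=2)
            return LabelImage(np.zeros_like(rho, dtype=np.int32), density.pitch_um)
        background_threshold = float(threshold_otsu(smooth))
    foreground = smooth > background_threshold
    if not foreground.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
        return LabelImage(np.zeros_like(rho, dtype=np.int32), density.pitch_um)
    if h_depth is None:
        h_depth = 0.1 * float(smooth.max() - smooth.min())
    peaks = h_maxima(smooth, h_depth)
    markers = cc_label(peaks & foreground, connectivity=1)
    if markers.max() == 0:
        markers = cc_label(foreground, connectivity=1)
    labels = watershed(-smooth, markers=markers, mask=foreground, connectivity=1)
    if min_area_um2 > 0:
        min_px = int(round(min_area_um2 / density.pitch_um**2))
        ids, counts = np.unique(labels, return_counts=True)
        for lab, n in zip(ids, counts):
            if lab != 0 and n < min_px:
                labels[labels == lab] = 0
    labels, *_ = relabel_sequential(labels)
    return LabelImage(labels, density.pitch_um)


def measure(labels: LabelImage, density: DryMassMap) -> pd.DataFrame:
    """Per-cell morphometrics: area (µm²), mean density, total mass (pg).

    area = pixel count × pitch²; total mass = density sum × pitch².
    """
    if labels.labels.shape != density.density_pg_um2.shape:
        raise ValueError("label image and density map grids differ")
    pitch2 = labels.pitch_um**2
    rows = []
    for lab in range(1, labels.n_labels + 1):
        mask = labels.labels == lab
        n = int(mask.sum())
        if n == 0:
            continue
        vals = density.density_pg_um2[mask]
        rows.append(
            {
                "frame": 0,
                "label": lab,
                "area_um2": n * pitch2,
                "mean_density_pg_um2": float(vals.mean()),
                "total_mass_pg": float(vals.sum() * pitch2),
            }
        )
    return pd.DataFrame(rows, columns=CELLTABLE_COLUMNS)


@dataclass
class Trajectory:
    """One tracked cell: frame-resolved labels and morphometrics."""

    trajectory_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    area_um2: list[float] = field(default_factory=list)
    mean_density_pg_um2: list[float] = field(default_factory=list)
    total_mass_pg: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def track(
    label_images: list[LabelImage],
    tables: list[pd.DataFrame],
    min_overlap: float = 0.3,
) -> pd.DataFrame:
    """Greedy maximum-overlap tracking of labels across consecutive frames.

    Two labels in consecutive frames are linked when their pixel overlap
    exceeds ``min_overlap`` of the smaller region; matches are taken
    greedily in decreasing overlap.  Unmatched labels start or terminate
    trajectories; trajectory ids are never reused.

    Returns a long-format table with columns frame, label, trajectory_id,
    area_um2, mean_density_pg_um2, total_mass_pg.
    """
    if len(label_images) < 2:
        raise ValueError("tracking needs at least two frames")
    next_id = 1
    # trajectory id assigned to each label of the current frame
    assignment: dict[int, int] = {}
    records = []
    trajectories: dict[int, Trajectory] = {}

    for frame, (li, tab) in enumerate(zip(label_images, tables)):
        if frame == 0:
            assignment = {}
            for lab in range(1, li.n_labels + 1):
                assignment[lab] = next_id
                trajectories[next_id] = Trajectory(next_id)
                next_id += 1
        else:
            prev = label_images[frame - 1].labels
            cur = li.labels
            overlaps = []
            for lab in range(1, li.n_labels + 1):
                mask = cur == lab
                prev_under = prev[mask]
                for plab in np.unique(prev_under):
                    if plab == 0:
                        continue
                    inter = int(np.sum(prev_under == plab))
                    smaller = min(int(mask.sum()), int(np.sum(prev == plab)))
                    frac = inter / smaller if smaller else 0.0
                    if frac >= min_overlap:
                        overlaps.append((frac, lab, int(plab)))
            overlaps.sort(reverse=True)
            new_assignment: dict[int, int] = {}
            used_prev: set[int] = set()
            for frac, lab, plab in overlaps:
                if lab in new_assignment or plab in used_prev:
                    continue
                if plab in assignment:
                    new_assignment[lab] = assignment[plab]
                    used_prev.add(plab)
            for lab in range(1, li.n_labels + 1):
                if lab not in new_assignment:
                    new_assignment[lab] = next_id
                    trajectories[next_id] = Trajectory(next_id)
                    next_id += 1
            assignment = new_assignment

        by_label = tab.set_index("label") if len(tab) else tab
        for lab, tid in assignment.items():
            if len(tab) == 0 or lab not in by_label.index:
                continue
            row = by_label.loc[lab]
            traj = trajectories[tid]
            traj.frames.append(frame)
            traj.labels.append(lab)
            traj.area_um2.append(float(row["area_um2"]))
            traj.mean_density_pg_um2.append(float(row["mean_density_pg_um2"]))
            traj.total_mass_pg.append(float(row["total_mass_pg"]))
            records.append(
                {
                    "frame": frame,
                    "label": lab,
                    "trajectory_id": tid,
                    "area_um2": float(row["area_um2"]),
                    "mean_density_pg_um2": float(row["mean_density_pg_um2"]),
                    "total_mass_pg": float(row["total_mass_pg"]),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "frame",
            "label",
            "trajectory_id",
            "area_um2",
            "mean_density_pg_um2",
            "total_mass_pg",
        ],
    ).sort_values(["trajectory_id", "frame"], ignore_index=True)
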
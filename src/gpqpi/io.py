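"""File formats: TIFF stacks with JSON sidecars, CSV tables.

Holograms are written as multi-page 16-bit grayscale TIFF with a JSON
sidecar (pixel pitch, carrier vector, spectrum, per-frame metadata and the
quantization scale).  Phase/height/density maps are 32-bit float TIFF with
a sidecar.  Cell tables and trajectories are plain CSV.

The uint16 quantization scale is stored in the sidecar and reused when a
read hologram is re-written, so write → read → write is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from gpqpi.hologram import Hologram
from gpqpi.reconstruct import PhaseMap
from gpqpi.scenes import Spectrum

__all__ = [
    "write_hologram_stack",
    "read_hologram_stack",
    "write_phase_map",
    "read_phase_map",
    "write_float_map",
    "write_cell_table",
    "read_cell_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_hologram_stack(path: str | Path, holograms: Sequence[Hologram]) -> None:
    """Write holograms as a multi-page uint16 TIFF plus JSON sidecar."""
    path = Path(path)
    if not holograms:
        raise ValueError("nothing to write")
    first = holograms[0]
    scale = first.meta.get("tiff_scale")
    if scale is None:
        peak = max(float(h.intensity.max()) for h in holograms)
        scale = 65535.0 / peak if peak > 0 else 1.0
    pages = np.stack(
        [np.round(h.intensity * scale).astype(np.uint16) for h in holograms]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pitch_um": first.pitch_um,
        "carrier": list(first.carrier),
        "spectrum": first.spectrum.to_dict(),
        "tiff_scale": scale,
        "frames": [
            {"frame_index": h.frame_index,
             "meta": {k: v for k, v in h.meta.items() if k != "tiff_scale"}}
            for h in holograms
        ],
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_hologram_stack(path: str | Path) -> list[Hologram]:
    """Read a hologram stack written by :func:`write_hologram_stack`."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = json.loads(_sidecar(path).read_text())
    spec = Spectrum(
        np.asarray(sidecar["spectrum"]["wavelengths_nm"]),
        np.asarray(sidecar["spectrum"]["weights"]),
    )
    scale = sidecar["tiff_scale"]
    out = []
    for page, frame in zip(pages, sidecar["frames"]):
        meta = dict(frame["meta"])
        meta["tiff_scale"] = scale
        out.append(
            Hologram(
                intensity=page.astype(float) / scale,
                pitch_um=sidecar["pitch_um"],
                carrier=tuple(sidecar["carrier"]),
                spectrum=spec,
                frame_index=frame["frame_index"],
                meta=meta,
            )
        )
    return out


def write_phase_map(path: str | Path, phase: PhaseMap) -> None:
    """Write a phase map as 32-bit float TIFF with processing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, phase.phase.astype(np.float32))
    sidecar = {
        "wrapped": phase.wrapped,
        "pitch_um": phase.pitch_um,
        "meta": phase.meta,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, default=_jsonable))


def read_phase_map(path: str | Path) -> PhaseMap:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = json.loads(_sidecar(path).read_text())
    return PhaseMap(
        phase=data,
        wrapped=sidecar["wrapped"],
        pitch_um=sidecar["pitch_um"],
        meta=sidecar.get("meta", {}),
    )


def write_float_map(path: str | Path, data: np.ndarray, **sidecar_fields) -> None:
    """Write any 2-D float map (height, density, ground truth) as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    if sidecar_fields:
        _sidecar(path).write_text(
            json.dumps(sidecar_fields, indent=2, default=_jsonable)
        )


def write_cell_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
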
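"""TIFF-stack and JSON-sidecar I/O for pipeline artifacts.

Physical quantities (density, δ, retrieved maps) are 32-bit float TIFF
stacks; count frames are 16-bit unsigned.  Each stack carries a JSON
sidecar with units and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import tifffile

from .phantoms import DensityPhantom
from .reconstruct import DeltaVolume


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: str | Path, array: np.ndarray, meta: Dict[str, Any],
                dtype: str = "float32") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "uint16":
        data = np.clip(np.round(array), 0, 65535).astype(np.uint16)
    else:
        data = array.astype(np.float32)
    tifffile.imwrite(path, data)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path: str | Path) -> tuple[np.ndarray, Dict[str, Any]]:
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return np.asarray(data), meta


def write_phantom(phantom: DensityPhantom, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "quantity": "mass_density",
        "units": "g cm^-3",
        "voxel_size_mm": phantom.voxel_size_mm,
        "medium_density": phantom.medium_density,
        "z_over_m": phantom.z_over_m,
    }
    if phantom.labels is not None:
        labels_path = path.with_name(path.stem + "_labels.tif")
        tifffile.imwrite(labels_path, phantom.labels.astype(np.uint8))
        meta["labels_file"] = labels_path.name
    write_stack(path, phantom.grid, meta)


def read_phantom(path: str | Path) -> DensityPhantom:
    path = Path(path)
    grid, meta = read_stack(path)
    labels = None
    if "labels_file" in meta:
        labels = tifffile.imread(path.with_name(meta["labels_file"]))
    return DensityPhantom(
        grid.astype(np.float64), meta["voxel_size_mm"], meta["medium_density"],
        meta.get("z_over_m", 0.55), labels,
    )


def write_delta_volume(volume: DeltaVolume, path: str | Path) -> None:
    write_stack(path, volume.grid, {
        "quantity": "delta_contrast", "units": "dimensionless",
        "voxel_size_mm": volume.voxel_size_mm,
        "wavelength_nm": volume.wavelength_nm,
    })


def read_delta_volume(path: str | Path) -> DeltaVolume:
    grid, meta = read_stack(path)
    return DeltaVolume(grid.astype(np.float64), meta["voxel_size_mm"],
                       meta.get("wavelength_nm", 0.0))
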
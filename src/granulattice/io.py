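"""File I/O: MRC volumes (via gemmi's CCP4/MRC2014 support), TIFF images,
CSV point/label tables and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Volume3D


def save_mrc(vol: Volume3D, path) -> None:
    """Write a volume as an MRC2014 map; voxel size goes in the cell header."""
    import gemmi

    nz, ny, nx = vol.data.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data.astype(np.float32)))
    # The numpy array maps onto gemmi's (nu, nv, nw) in C order, so the cell
    # edges follow the array axes (z, y, x); gemmi cells are in Angstrom.
    grid.unit_cell = gemmi.UnitCell(
        nz * vol.voxel_size * 10.0,
        ny * vol.voxel_size * 10.0,
        nx * vol.voxel_size * 10.0,
        90.0, 90.0, 90.0,
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def load_mrc(path) -> Volume3D:
    """Read an MRC/CCP4 map back into a :class:`Volume3D` (origin at 0)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.ascontiguousarray(np.array(m.grid, copy=True))  # (z, y, x)
    voxel_size = m.grid.unit_cell.a / m.grid.nu / 10.0  # Angstrom -> nm
    return Volume3D(data, voxel_size)


def save_tiff(image: np.ndarray, path, pixel_size: float | None = None) -> None:
    meta = {"pixel_size_nm": pixel_size} if pixel_size else None
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32), metadata=meta)


def load_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_points_csv(points: np.ndarray, path, labels=None) -> None:
    """Centres (and optional sector/domain labels) as x_nm, y_nm, z_nm[, sector]."""
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame(points, columns=["x_nm", "y_nm", "z_nm"])
    if labels is not None:
        df["sector"] = np.asarray(labels)
    df.to_csv(path, index=False)


def load_points_csv(path):
    df = pd.read_csv(path)
    points = df[["x_nm", "y_nm", "z_nm"]].to_numpy()
    labels = df["sector"].to_numpy() if "sector" in df.columns else None
    return points, labels


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
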
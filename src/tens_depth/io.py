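"""Plain-text exporters: legacy-VTK structured points, CSV tables, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import VoxelGrid
from .protocol import SDCurve

__all__ = [
    "write_vtk_structured_points",
    "write_nifti",
    "write_sd_csv",
    "read_sd_csv",
    "write_json",
]


def write_vtk_structured_points(
    path: str | Path, grid: VoxelGrid, fields: dict[str, np.ndarray]
) -> Path:
    """ASCII legacy-VTK STRUCTURED_POINTS file with one scalar per field.

    Spacing and origin are written in mm.  Data are emitted in VTK's
    x-fastest order.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "tens-depth field export (units: mm)",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.spacing[0]} {grid.spacing[1]} {grid.spacing[2]}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        if arr.shape != grid.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid {grid.shape}")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i : i + 9]) for i in range(0, len(flat), 9))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_nifti(path: str | Path, grid: VoxelGrid, array: np.ndarray) -> Path:
    """Optional NIfTI export (mm spacing in the affine); needs nibabel."""
    import nibabel as nib

    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return Path(path)


def write_sd_csv(path: str | Path, curve: SDCurve) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"pulse_width_us": curve.pw_us, "threshold_mA": curve.threshold_mA}
    ).to_csv(path, index=False)
    return path


def read_sd_csv(path: str | Path, meta: dict | None = None) -> SDCurve:
    df = pd.read_csv(path)
    return SDCurve(
        pw_us=df["pulse_width_us"].to_numpy(),
        threshold_mA=df["threshold_mA"].to_numpy(),
        meta=meta or {},
    )


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default) + "\n")
    return path
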
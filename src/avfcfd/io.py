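"""File I/O: NIfTI volumes, STL surfaces, legacy-ASCII VTK fields, CSV tables.

NIfTI goes through nibabel and STL through trimesh.  Field and polyline
output uses the legacy ASCII VTK format written directly (a few dozen
lines of plain text) so results open in standard viewers.  A JSON-lines
run log records stage provenance.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np

from .imaging import LumenMask
from .synth import VoxelVolume

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_stl",
    "write_vtk_structured",
    "write_vtk_polyline",
    "RunLog",
    "config_hash",
]


def _affine(spacing_mm: float, origin_mm) -> np.ndarray:
    aff = np.eye(4) * spacing_mm
    aff[3, 3] = 1.0
    aff[:3, 3] = origin_mm
    return aff


def write_nifti(obj: VoxelVolume | LumenMask, path) -> Path:
    path = Path(path)
    if isinstance(obj, LumenMask):
        data = obj.values.astype(np.uint8)
    else:
        data = obj.values.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(obj.spacing_um / 1e3, obj.origin_mm))
    nib.save(img, str(path))
    return path


def read_nifti(path, as_mask: bool = False):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing_mm = float(img.affine[0, 0])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if as_mask:
        return LumenMask(data.astype(bool), spacing_mm * 1e3, origin)
    return VoxelVolume(data.astype(float), spacing_mm * 1e3, origin)


def write_stl(mesh, path) -> Path:
    path = Path(path)
    mesh.export(str(path))
    return path


def write_vtk_structured(path, x_mm, y_mm, fields: dict[str, np.ndarray],
                         title: str = "avfcfd field") -> Path:
    """Legacy ASCII VTK structured grid of a 2-D slice.

    ``x_mm``/``y_mm``: (ni, nj) node coordinates; each field is (ni, nj)
    point data.
    """
    path = Path(path)
    ni, nj = np.asarray(x_mm).shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET STRUCTURED_GRID\n")
        f.write(f"DIMENSIONS {ni} {nj} 1\n")
        f.write(f"POINTS {ni * nj} float\n")
        for j in range(nj):
            for i in range(ni):
                f.write(f"{x_mm[i, j]:.6e} {y_mm[i, j]:.6e} 0.0\n")
        f.write(f"POINT_DATA {ni * nj}\n")
        for name, arr in fields.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for j in range(nj):
                for i in range(ni):
                    f.write(f"{arr[i, j]:.6e}\n")
    return path


def write_vtk_polyline(path, points_mm: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None,
                       title: str = "centerline") -> Path:
    """Legacy ASCII VTK polyline (centerline export)."""
    path = Path(path)
    n = len(points_mm)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        for p in points_mm:
            f.write(f"{p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
        f.write(f"LINES 1 {n + 1}\n")
        f.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")
        if point_data:
            f.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for val in arr:
                    f.write(f"{val:.6e}\n")
    return path


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class RunLog:
    """JSON-lines provenance log: one record per pipeline stage."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, stage: str, **payload):
        entry = {"stage": stage, "wall_time": time.time(), **payload}
        with open(self.path, "a") as f:
            f.write(json.dumps(entry, default=str) + "\n")
        return entry
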
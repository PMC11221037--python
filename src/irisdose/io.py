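"""File formats: MetaImage (MHD) voxel grids and dose maps, a plain
binary + JSON sidecar grid format, columnar phase-space files, and
2-column CSV curves.

MetaImage I/O goes through SimpleITK; arrays are stored (x, y, z) in
memory and transposed to ITK's (z, y, x) on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .geometry import StructureMask, VoxelGrid
from .source import Curve, PhaseSpace
from .transport import DoseGrid

__all__ = [
    "write_image_mhd", "read_image_mhd",
    "write_grid_mhd", "read_grid_mhd",
    "write_mask_mhd", "read_mask_mhd",
    "write_grid_raw", "read_grid_raw",
    "write_dose_mhd",
    "write_phase_space", "read_phase_space",
    "write_curve_csv", "read_curve_csv",
]


def write_image_mhd(array: np.ndarray, grid: VoxelGrid, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(array, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def read_image_mhd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (array in (x, y, z) order, origin, spacing)."""
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, np.array(img.GetOrigin()), np.array(img.GetSpacing())


def write_grid_mhd(grid: VoxelGrid, prefix) -> None:
    """Write a phantom as ``<prefix>_density.mhd`` + ``<prefix>_material.mhd``."""
    prefix = Path(prefix)
    write_image_mhd(grid.density, grid, prefix.with_name(
        prefix.name + "_density.mhd"))
    write_image_mhd(grid.material_id.astype(np.uint8), grid,
                    prefix.with_name(prefix.name + "_material.mhd"))


def read_grid_mhd(prefix) -> VoxelGrid:
    prefix = Path(prefix)
    dens, origin, spacing = read_image_mhd(
        prefix.with_name(prefix.name + "_density.mhd"))
    mat, _, _ = read_image_mhd(
        prefix.with_name(prefix.name + "_material.mhd"))
    return VoxelGrid(origin, spacing, dens, mat.astype(np.int8))


def write_mask_mhd(mask: StructureMask, path) -> None:
    write_image_mhd(mask.mask.astype(np.uint8), mask.grid, path)


def read_mask_mhd(path, grid: VoxelGrid, label: str = "") -> StructureMask:
    arr, _, _ = read_image_mhd(path)
    return StructureMask(grid, arr > 0, label)


def write_grid_raw(grid: VoxelGrid, prefix) -> None:
    """Plain binary + JSON sidecar: ``<prefix>.density.f64`` (C-order
    float64), ``<prefix>.material.u8`` and ``<prefix>.json`` metadata."""
    prefix = Path(prefix)
    grid.density.astype("<f8").tofile(f"{prefix}.density.f64")
    grid.material_id.astype(np.uint8).tofile(f"{prefix}.material.u8")
    meta = {"origin_mm": grid.origin.tolist(),
            "spacing_mm": grid.spacing.tolist(),
            "dims": list(grid.dims),
            "density_dtype": "<f8", "material_dtype": "u1",
            "order": "C", "axis_order": "xyz"}
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def read_grid_raw(prefix) -> VoxelGrid:
    prefix = Path(prefix)
    meta = json.loads(Path(f"{prefix}.json").read_text())
    dims = tuple(meta["dims"])
    dens = np.fromfile(f"{prefix}.density.f64",
                       dtype=meta["density_dtype"]).reshape(dims)
    mat = np.fromfile(f"{prefix}.material.u8",
                      dtype=meta["material_dtype"]).reshape(dims)
    return VoxelGrid(np.array(meta["origin_mm"]),
                     np.array(meta["spacing_mm"]), dens,
                     mat.astype(np.int8))


def write_dose_mhd(dose: DoseGrid, prefix) -> None:
    """Dose + relative-uncertainty MetaImages plus a JSON run manifest."""
    prefix = Path(prefix)
    write_image_mhd(dose.dose, dose.grid,
                    prefix.with_name(prefix.name + "_dose.mhd"))
    write_image_mhd(dose.rel_uncertainty, dose.grid,
                    prefix.with_name(prefix.name + "_uncertainty.mhd"))
    manifest = {"histories": dose.histories, "batches": dose.batches,
                "meta": {k: v for k, v in dose.meta.items()
                         if isinstance(v, (int, float, str))}}
    Path(f"{prefix}_manifest.json").write_text(json.dumps(manifest,
                                                          indent=2))


_PS_COLUMNS = ("energy", "x", "y", "u", "v", "w", "weight")


def write_phase_space(ps: PhaseSpace, prefix) -> None:
    """Columnar float64 binary (energy, x, y, u, v, w, weight) plus a JSON
    header with geometry and provenance."""
    prefix = Path(prefix)
    cols = np.column_stack([ps.energy, ps.position[:, 0], ps.position[:, 1],
                            ps.direction[:, 0], ps.direction[:, 1],
                            ps.direction[:, 2], ps.weight])
    cols.astype("<f8").T.tofile(f"{prefix}.phsp")
    header = {"columns": list(_PS_COLUMNS), "n_particles": len(ps),
              "n_source": ps.n_source, "plane_z_mm": ps.plane_z,
              "collimator_diameter_mm": ps.collimator_diameter,
              "dtype": "<f8", "layout": "columnar",
              "provenance": ps.provenance}
    Path(f"{prefix}.json").write_text(json.dumps(header, indent=2))


def read_phase_space(prefix) -> PhaseSpace:
    prefix = Path(prefix)
    header = json.loads(Path(f"{prefix}.json").read_text())
    n = header["n_particles"]
    cols = np.fromfile(f"{prefix}.phsp", dtype=header["dtype"]).reshape(
        len(_PS_COLUMNS), n)
    return PhaseSpace(
        energy=cols[0], position=cols[1:3].T, direction=cols[3:6].T,
        weight=cols[6], plane_z=header["plane_z_mm"],
        collimator_diameter=header["collimator_diameter_mm"],
        n_source=header["n_source"], provenance=header.get("provenance", {}))


def write_curve_csv(curve: Curve, path, x_name: str = "position_mm",
                    y_name: str = "value") -> None:
    pd.DataFrame({x_name: curve.x, y_name: curve.y}).to_csv(path,
                                                            index=False)


def read_curve_csv(path) -> Curve:
    df = pd.read_csv(path)
    return Curve(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
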
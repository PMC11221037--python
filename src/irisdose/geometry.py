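"""Voxel phantom representation, synthetic phantoms, and ray-path geometry.

Conventions used throughout the package:

* world frame is right handed, units are mm;
* a :class:`VoxelGrid` stores ``origin`` as the position of the *center* of
  voxel index ``(0, 0, 0)``; voxel ``(i, j, k)`` therefore occupies the
  half-open box ``origin + idx*spacing ± spacing/2``;
* indices are 0-based, axis order is (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MATERIAL_CATALOG",
    "MATERIAL_IDS",
    "VoxelGrid",
    "StructureMask",
    "make_water_tank",
    "make_slab_phantom",
    "make_sphere_mask",
    "radiological_path",
]

#: Material catalog: name -> (integer id, default mass density in g/cm^3).
MATERIAL_CATALOG: dict[str, tuple[int, float]] = {
    "water": (0, 1.0),
    "lung": (1, 0.26),
    "bone": (2, 1.85),
    "air": (3, 0.0012),
}
MATERIAL_IDS: dict[int, str] = {v[0]: k for k, v in MATERIAL_CATALOG.items()}


@dataclass
class VoxelGrid:
    """Density / material voxel lattice with geometry metadata.

    Parameters
    ----------
    origin
        Position (mm) of the center of voxel (0, 0, 0).
    spacing
        Voxel pitch (mm) per axis; strictly positive.
    density
        Per-voxel mass density in g/cm^3, shape ``dims``, C-order (x, y, z).
    material_id
        Per-voxel integer index into :data:`MATERIAL_CATALOG`.
    """

    origin: np.ndarray
    spacing: np.ndarray
    density: np.ndarray
    material_id: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.material_id = np.asarray(self.material_id, dtype=np.int8)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3 vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.density.ndim != 3 or self.density.shape != self.material_id.shape:
            raise ValueError("density and material_id must share a 3-D shape")
        if not np.all(np.isfinite(self.density)) or np.any(self.density < 0):
            raise ValueError("density values must be finite and non-negative")
        known = np.array(sorted(MATERIAL_IDS))
        if not np.isin(np.unique(self.material_id), known).all():
            raise ValueError("material_id contains ids outside the catalog")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.density.size)

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer box of the lattice: (low corner, high corner) in mm."""
        lo = self.origin - self.spacing / 2.0
        hi = self.origin + (np.array(self.dims) - 0.5) * self.spacing
        return lo, hi

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Voxel index of each point (no bounds clipping), shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return np.floor((pts - self.origin) / self.spacing + 0.5).astype(np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.voxel_index(points)
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=-1)

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class StructureMask:
    """Boolean region-of-interest defined on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.dims:
            raise ValueError("mask shape must match grid dims")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _dims_from_extent(extent_mm, spacing_mm) -> np.ndarray:
    extent = np.asarray(extent_mm, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(extent <= 0) or np.any(spacing <= 0):
        raise ValueError("extent and spacing must be strictly positive")
    # round-to-nearest number of voxels, at least one per axis
    dims = np.maximum(1, np.round(extent / spacing).astype(int))
    return dims


def make_water_tank(extent_mm, spacing_mm, origin_mm=None) -> VoxelGrid:
    """Uniform water phantom.

    ``dims = round(extent / spacing)`` (round to nearest, minimum 1). The
    default origin centers the tank on the world origin.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    dims = _dims_from_extent(extent_mm, spacing_mm)
    if origin_mm is None:
        origin = -(dims - 1) * spacing / 2.0
    else:
        origin = np.asarray(origin_mm, dtype=float)
    wid, wrho = MATERIAL_CATALOG["water"]
    density = np.full(tuple(dims), wrho)
    material = np.full(tuple(dims), wid, dtype=np.int8)
    return VoxelGrid(origin, spacing, density, material)


def make_slab_phantom(extent_mm, spacing_mm, layers, axis: int = 2,
                      origin_mm=None, density_overrides=None) -> VoxelGrid:
    """Layered slab phantom; density varies only along ``axis``.

    Parameters
    ----------
    layers
        Sequence of ``(thickness_mm, density_or_None, material_name)``.
        ``None`` density uses the catalog default for the material.
        Thicknesses must sum to the extent along ``axis`` (1e-6 mm slack);
        zero-thickness layers are silently dropped. Layer boundaries are
        snapped to the nearest voxel plane: a voxel belongs to the layer
        containing its center.
    """
    grid = make_water_tank(extent_mm, spacing_mm, origin_mm=origin_mm)
    layers = [
        (float(t), d, m) for (t, d, m) in layers if float(t) > 0.0
    ]
    extent = np.asarray(extent_mm, dtype=float)
    total = sum(t for t, _, _ in layers)
    if abs(total - extent[axis]) > 1e-6:
        raise ValueError(
            f"layer thicknesses sum to {total} mm, extent along axis is "
            f"{extent[axis]} mm"
        )
    centers = grid.voxel_centers_axis(axis)
    low = grid.origin[axis] - grid.spacing[axis] / 2.0
    edges = low + np.cumsum([0.0] + [t for t, _, _ in layers])
    # voxel center in [edges[i], edges[i+1]) -> layer i (last layer closed)
    layer_of = np.clip(np.searchsorted(edges, centers, side="right") - 1,
                       0, len(layers) - 1)
    prof_rho = np.empty(len(centers))
    prof_mat = np.empty(len(centers), dtype=np.int8)
    for i, (_, dens, mat) in enumerate(layers):
        if mat not in MATERIAL_CATALOG:
            raise ValueError(f"unknown material {mat!r}")
        mid, mrho = MATERIAL_CATALOG[mat]
        if density_overrides and mat in density_overrides:
            mrho = density_overrides[mat]
        rho = mrho if dens is None else float(dens)
        sel = layer_of == i
        prof_rho[sel] = rho
        prof_mat[sel] = mid
    shape = [1, 1, 1]
    shape[axis] = len(centers)
    grid.density = np.broadcast_to(
        prof_rho.reshape(shape), grid.dims
    ).copy()
    grid.material_id = np.broadcast_to(
        prof_mat.reshape(shape), grid.dims
    ).copy()
    return grid


def make_sphere_mask(grid: VoxelGrid, center_mm, radius_mm: float,
                     label: str = "PTV") -> StructureMask:
    """Spherical structure mask (voxel included if its center is inside)."""
    c = np.asarray(center_mm, dtype=float)
    axes = [grid.voxel_centers_axis(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    mask = r2 <= radius_mm**2
    return StructureMask(grid, mask, label)


def _ray_box(p0: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray,
             t_max: float) -> tuple[float, float]:
    """Intersection [t0, t1] of segment p0 + t*d (t in [0, t_max]) with box."""
    t0, t1 = 0.0, t_max
    for a in range(3):
        if abs(d[a]) < 1e-300:
            if p0[a] < lo[a] or p0[a] >= hi[a]:
                return 1.0, 0.0  # empty
            continue
        ta = (lo[a] - p0[a]) / d[a]
        tb = (hi[a] - p0[a]) / d[a]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
    return t0, t1


def radiological_path(grid: VoxelGrid, p0, p1) -> float:
    """Water-equivalent length of the segment p0 -> p1 in mm.

    Exact voxel-boundary (Siddon-style) traversal of ``integral rho ds``;
    densities in g/cm^3 make the result mm of water. A segment fully outside
    the grid, or a degenerate segment (p0 == p1), contributes 0.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0.0:
        return 0.0
    lo, hi = grid.bounds()
    t0, t1 = _ray_box(p0, d, lo, hi, 1.0)
    if t1 <= t0:
        return 0.0
    spacing = grid.spacing
    origin = grid.origin
    dims = np.asarray(grid.dims)
    # crossing parameters with every voxel plane, per axis
    ts = [np.array([t0, t1])]
    for a in range(3):
        if abs(d[a]) < 1e-300:
            continue
        planes = (origin[a] - spacing[a] / 2.0) + spacing[a] * np.arange(
            dims[a] + 1
        )
        t_planes = (planes - p0[a]) / d[a]
        ts.append(t_planes[(t_planes > t0) & (t_planes < t1)])
    t_all = np.unique(np.concatenate(ts))
    t_all = t_all[(t_all >= t0) & (t_all <= t1)]
    if t_all.size < 2:
        return 0.0
    t_mid = 0.5 * (t_all[:-1] + t_all[1:])
    pts = p0[None, :] + t_mid[:, None] * d[None, :]
    idx = grid.voxel_index(pts)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    seg_len = np.diff(t_all) * length
    rho = np.zeros(len(t_mid))
    ii = idx[inside]
    rho[inside] = grid.density[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(np.sum(rho * seg_len))
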
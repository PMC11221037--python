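"""Effective-path-length ray-tracing dose engine.

This is the comparator algorithm: dose at a voxel is looked up from
water-tank beam data (depth dose, off-center ratios, per-collimator
output) at the *water-equivalent* depth obtained by integrating density
along the source ray, with an inverse-square correction from the
equivalent to the geometric distance. Density only shortens or stretches
the depth axis; lateral scatter and electron transport changes caused by
heterogeneity are ignored — which is exactly the mechanism that makes
this class of algorithm overestimate dose in and beyond low-density
media.

Formulation (per beam, SAD = 800 mm, beam data measured at SSD 800 /
detector plane 800):

    T(d)   = PDD(d) * ((800 + d) / 815)^2          (Mayneord-corrected)
    D(v)   = MU * K_c * T(d_eff) / T(15) * OCR(r_800, d_eff)
             * (815 / r_geo)^2

where ``d_eff`` is the radiological depth from the beam-entry surface to
the voxel, ``r_geo`` its geometric distance from the source, ``r_800``
its off-axis distance scaled to the 800 mm plane, and ``K_c`` the
collimator's absolute output (cGy/MU at 15 mm depth on the axis). In
uniform water at the commissioning geometry this reduces exactly to the
commissioned PDD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import VoxelGrid
from .source import Curve
from .transport import Beam, BeamPlan, DoseGrid, beam_basis

__all__ = [
    "CollimatorBeamData",
    "BeamData",
    "rt_dose",
    "effective_depth",
]

_REF_DEPTH_MM = 15.0
_SAD_MM = 800.0


@dataclass
class CollimatorBeamData:
    """Water beam data for one collimator.

    ``pdd``: depth (mm) -> percent of maximum (max 100), measured at
    SSD 800. ``ocr``: depth (mm) -> radial off-center ratio curve, off-axis
    coordinate on the 800 mm plane, axis value 1. ``output_dose_per_mu``:
    absolute axis dose (cGy/MU) at the reference depth.
    """

    pdd: Curve
    ocr: dict[float, Curve]
    output_dose_per_mu: float

    def __post_init__(self) -> None:
        if abs(self.pdd.y.max() - 100.0) > 1e-6:
            raise ValueError("PDD must be normalized to max 100")
        if len(self.ocr) < 1:
            raise ValueError("need OCR data at one or more depths")
        for depth, curve in self.ocr.items():
            axis_val = curve(0.0)
            if abs(axis_val - 1.0) > 1e-6:
                raise ValueError(
                    f"OCR at depth {depth} mm must be 1 on the axis")
        if self.output_dose_per_mu <= 0:
            raise ValueError("output must be positive")


@dataclass
class BeamData:
    """Commissioned beam data per collimator diameter (mm)."""

    collimators: dict[float, CollimatorBeamData]
    ssd_mm: float = _SAD_MM
    meta: dict = field(default_factory=dict)

    def __getitem__(self, diameter: float) -> CollimatorBeamData:
        return self.collimators[float(diameter)]

    def __contains__(self, diameter: float) -> bool:
        return float(diameter) in self.collimators


def effective_depth(phantom: VoxelGrid, source: np.ndarray,
                    points: np.ndarray, n_samples: int = 512,
                    surface_density: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Radiological depth (mm water) and geometric depth (mm) from the
    beam-entry surface to each point, along the ray from ``source``.

    Density is sampled at ``n_samples`` evenly spaced positions on each
    source->point ray (trilinear interpolation, zero outside the phantom);
    the surface is the first sample with density above
    ``surface_density`` g/cm^3. Accuracy is set by the sampling pitch,
    about ray-length / n_samples.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = np.asarray(source, dtype=float)
    vec = pts - src[None, :]
    r_geo = np.linalg.norm(vec, axis=1)
    u = (np.arange(n_samples) + 0.5) / n_samples  # (S,)
    d_eff = np.empty(len(pts))
    d_geo = np.empty(len(pts))
    chunk = max(1, int(4e6) // n_samples)
    g = phantom
    lo, hi = g.bounds()
    for a in range(0, len(pts), chunk):
        b = min(a + chunk, len(pts))
        p = src[None, None, :] + u[None, :, None] * vec[a:b, None, :]
        coords = ((p - g.origin) / g.spacing).reshape(-1, 3).T
        # edge voxels extend to the physical face; outside the box is zero
        rho = map_coordinates(g.density, coords, order=1, mode="nearest")
        in_box = np.all((p >= lo) & (p < hi), axis=2).reshape(-1)
        rho = np.where(in_box, rho, 0.0).reshape(b - a, n_samples)
        ds = (r_geo[a:b] / n_samples)[:, None]
        inside = rho > surface_density
        # first above-threshold sample marks the surface
        first = np.argmax(inside, axis=1)
        never = ~inside.any(axis=1)
        taps = np.arange(n_samples)[None, :] >= first[:, None]
        d_eff[a:b] = np.sum(rho * ds * taps, axis=1)
        d_geo[a:b] = r_geo[a:b] * (1.0 - (first + 0.5) / n_samples)
        d_eff[a:b][never] = 0.0
        d_geo[a:b][never] = 0.0
    return d_eff, d_geo


def _tmr_like(pdd: Curve, d: np.ndarray) -> np.ndarray:
    d_clamped = np.clip(d, pdd.x[0], pdd.x[-1])
    return pdd(d_clamped) * ((_SAD_MM + d_clamped) / (_SAD_MM
                                                      + _REF_DEPTH_MM)) ** 2


def _ocr_lookup(ocr: dict[float, Curve], r_800: np.ndarray,
                depth: np.ndarray) -> np.ndarray:
    depths = np.array(sorted(ocr))
    curves = [ocr[d] for d in depths]
    vals = np.stack([c(np.clip(r_800, c.x[0], c.x[-1])) for c in curves])
    if len(depths) == 1:
        return vals[0]
    d = np.clip(depth, depths[0], depths[-1])
    j = np.clip(np.searchsorted(depths, d) - 1, 0, len(depths) - 2)
    f = (d - depths[j]) / (depths[j + 1] - depths[j])
    return vals[j, np.arange(len(d))] * (1 - f) \
        + vals[j + 1, np.arange(len(d))] * f


def rt_dose(phantom: VoxelGrid, plan: BeamPlan, beam_data: BeamData
            ) -> DoseGrid:
    """Effective-path-length dose for a plan; beams are summed and the
    result is linear in each beam's MU."""
    for beam in plan.beams:
        if beam.collimator_diameter not in beam_data:
            raise KeyError(
                f"beam data missing for collimator "
                f"{beam.collimator_diameter} mm")
    axes = [phantom.voxel_centers_axis(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    total = np.zeros(len(pts))
    for beam in plan.beams:
        if beam.mu == 0.0:
            continue
        data = beam_data[beam.collimator_diameter]
        source = beam.isocenter - plan.sad * beam.direction
        d_eff, _d_geo = effective_depth(phantom, source, pts)
        vec = pts - source[None, :]
        r_geo = np.linalg.norm(vec, axis=1)
        z_ax = vec @ beam.direction
        r_perp = np.sqrt(np.maximum(r_geo**2 - z_ax**2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_800 = np.where(z_ax > 1e-6, r_perp * _SAD_MM / z_ax, np.inf)
        t = _tmr_like(data.pdd, d_eff)
        t_ref = _tmr_like(data.pdd, np.array([_REF_DEPTH_MM]))[0]
        ocr = _ocr_lookup(data.ocr, r_800, d_eff)
        isl = ((_SAD_MM + _REF_DEPTH_MM) / np.maximum(r_geo, 1.0)) ** 2
        # output_dose_per_mu is already absolute (cGy/MU); the plan's
        # Monte Carlo calibration factor does not apply here
        total += (beam.mu * data.output_dose_per_mu
                  * t / t_ref * ocr * isl)
    dose = total.reshape(phantom.dims)
    return DoseGrid(grid=phantom, dose=dose,
                    rel_uncertainty=np.zeros(phantom.dims),
                    histories=0, batches=1, batch_doses=None,
                    meta={"engine": "raytrace"})
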
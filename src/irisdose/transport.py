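"""Monte Carlo photon dose engine on voxel phantoms.

Photons are tracked with Woodcock (delta) tracking against a majorant
attenuation coefficient, interact by photoelectric absorption, Compton
(Klein-Nishina) scattering or Rayleigh (Thomson-form) scattering, and hand
their secondary-electron energy to a condensed straight-ahead electron
model with Highland-style multiple-scatter blur. Scoring is energy per
voxel mass (dose to medium); statistical uncertainty comes from batch
means; absolute dose is tied to the machine calibration
(1 MU = 1 cGy at 800 mm from the source, 15 mm deep in water, 60 mm
collimator).

Everything is vectorized over particle arrays; there are no per-particle
Python loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MATERIAL_IDS, VoxelGrid
from .physics import (CROSS_SECTIONS, STOPPING_POWERS, ENERGY_MIN,
                      ENERGY_MAX, EnergyOutOfRangeError)
from .source import PhaseSpace

__all__ = [
    "ELECTRON_REST_MEV",
    "SimulationConfig",
    "Beam",
    "BeamPlan",
    "DoseGrid",
    "CalibrationResult",
    "CalibrationUnstableError",
    "sample_compton",
    "sample_rayleigh_cos",
    "sample_free_path",
    "deposit_electron",
    "run_mc",
    "estimate_uncertainty",
    "calibrate",
    "make_calibration_phantom",
    "beam_basis",
    "MEV_PER_G_TO_CGY",
]

ELECTRON_REST_MEV = 0.51099895
_X0_WATER_G_CM2 = 36.08  # radiation length of water
#: 1 MeV/g = 1.602176634e-10 Gy = 1.602176634e-8 cGy (bookkeeping only;
#: absolute dose always goes through the MU calibration).
MEV_PER_G_TO_CGY = 1.602176634e-8


class CalibrationUnstableError(RuntimeError):
    """Reference-point uncertainty too large for a reliable calibration."""


@dataclass
class SimulationConfig:
    """Monte Carlo run settings (desk-scale defaults).

    ``histories`` is the number of source histories *per beam*;
    ``batches`` independent batches provide the uncertainty estimate.
    ``photon_cutoff_mev`` photons deposit locally below this energy.
    ``electron_transport=False`` switches to the collision-kerma
    approximation (secondary-electron energy deposited at the interaction
    site). ``target_rel_uncertainty``, if set, stops adding batches once
    the scalar uncertainty (voxels above 50% of the maximum dose) drops
    below it.
    """

    histories: int = 200_000
    batches: int = 10
    seed: int = 0
    photon_cutoff_mev: float = 0.01
    electron_transport: bool = True
    electron_steps: int = 20
    target_rel_uncertainty: float | None = None
    chunk_size: int = 200_000

    def __post_init__(self) -> None:
        if self.batches < 2:
            raise ValueError("need at least 2 batches")
        if self.histories < self.batches:
            raise ValueError("need histories >= batches")
        if not (ENERGY_MIN <= self.photon_cutoff_mev <= ENERGY_MAX):
            raise ValueError("photon cutoff outside physics table range")


@dataclass
class Beam:
    isocenter: np.ndarray
    direction: np.ndarray
    collimator_diameter: float
    mu: float

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("beam direction must be a unit vector")
            self.direction = self.direction / n
        if self.mu < 0:
            raise ValueError("MU must be non-negative")


@dataclass
class BeamPlan:
    """One or more beams plus the absolute-dose calibration factor.

    ``calibration_factor`` converts the engine's raw per-history dose
    (MeV/g per history) into cGy per MU; see :func:`calibrate`.
    """

    beams: list[Beam]
    sad: float = 800.0
    calibration_factor: float = 1.0


@dataclass
class DoseGrid:
    """Per-voxel dose (cGy for the plan's MU) with batch statistics."""

    grid: VoxelGrid
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    histories: int
    batches: int
    batch_doses: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose.shape != self.grid.dims:
            raise ValueError("dose shape must match grid dims")
        if np.any(self.dose < 0) or np.any(self.rel_uncertainty < 0):
            raise ValueError("dose and uncertainty must be non-negative")


# ----------------------------------------------------------------------
# physics sampling


def sample_compton(energy, rng: np.random.Generator):
    """Sample Klein-Nishina scattering: returns ``(E_out, cos_theta)``.

    Composition-rejection sampling of the scattered-to-incident energy
    ratio; the returned pair satisfies the Compton kinematic identity
    ``E_out = E / (1 + (E/m_e c^2)(1 - cos_theta))`` exactly by
    construction.
    """
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    a = e / ELECTRON_REST_MEV
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    eps = np.empty_like(e)
    t = np.empty_like(e)
    todo = np.ones(len(e), dtype=bool)
    while todo.any():
        idx = np.flatnonzero(todo)
        m = len(idx)
        r1, r2, r3 = rng.random(m), rng.random(m), rng.random(m)
        use_ln = r1 < a1[idx] / (a1[idx] + a2[idx])
        cand = np.where(
            use_ln,
            eps0[idx] * np.exp(a1[idx] * r2),
            np.sqrt(eps0[idx] ** 2 + (1.0 - eps0[idx] ** 2) * r2),
        )
        tc = (1.0 - cand) / (a[idx] * cand)
        sin2 = tc * (2.0 - tc)
        accept = r3 <= 1.0 - cand * sin2 / (1.0 + cand**2)
        acc = idx[accept]
        eps[acc] = cand[accept]
        t[acc] = tc[accept]
        todo[acc] = False
    cos_theta = 1.0 - t
    e_out = eps * e
    if np.isscalar(energy):
        return float(e_out[0]), float(cos_theta[0])
    return e_out, cos_theta


def sample_rayleigh_cos(n: int, rng: np.random.Generator) -> np.ndarray:
    """Thomson-form angular sampling, p(cos) ~ 1 + cos^2 (rejection)."""
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        mu = 2.0 * rng.random(m) - 1.0
        acc = rng.random(m) < 0.5 * (1.0 + mu**2)
        idx = np.flatnonzero(todo)[acc]
        out[idx] = mu[acc]
        todo[idx] = False
    return out


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2) perpendicular to each row of d."""
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    small_z = np.abs(dz) < 0.9
    # e1 = d x h with h = z-hat where |dz| < 0.9, else h = x-hat
    e1 = np.empty_like(d)
    e1[:, 0] = np.where(small_z, dy, 0.0)
    e1[:, 1] = np.where(small_z, -dx, dz)
    e1[:, 2] = np.where(small_z, 0.0, -dy)
    e1 /= np.sqrt(e1[:, 0] ** 2 + e1[:, 1] ** 2
                  + e1[:, 2] ** 2)[:, None]
    e2 = np.empty_like(d)
    e2[:, 0] = dy * e1[:, 2] - dz * e1[:, 1]
    e2[:, 1] = dz * e1[:, 0] - dx * e1[:, 2]
    e2[:, 2] = dx * e1[:, 1] - dy * e1[:, 0]
    return e1, e2


def _rotate(d: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    e1, e2 = _perp_basis(d)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    out = (cos_t[:, None] * d
           + (sin_t * np.cos(phi))[:, None] * e1
           + (sin_t * np.sin(phi))[:, None] * e2)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ----------------------------------------------------------------------
# material lookup tables


class _MaterialLUT:
    """Per-run attenuation lookup: component curves per material plus a
    guaranteed majorant over the voxels actually present in the grid."""

    def __init__(self, grid: VoxelGrid) -> None:
        names = [MATERIAL_IDS[i] for i in sorted(MATERIAL_IDS)]
        ref = CROSS_SECTIONS[names[0]]
        self.log_e = np.log(ref.energy_grid)
        self.log_comp = np.stack(
            [np.log(CROSS_SECTIONS[n].components) for n in names]
        )  # (n_mat, 3, nE)
        self.log_tot = np.stack(
            [np.log(CROSS_SECTIONS[n].total) for n in names]
        )  # (n_mat, nE)
        mat = grid.material_id
        rho_max = np.zeros(len(names))
        for i in range(len(names)):
            sel = mat == i
            if sel.any():
                rho_max[i] = float(grid.density[sel].max())
        with np.errstate(divide="ignore"):
            log_rho = np.where(rho_max > 0, np.log(rho_max), -np.inf)
        self.log_majorant = np.max(
            self.log_tot + log_rho[:, None], axis=0
        )  # (nE,); may be -inf everywhere for a vacuum grid
        self.rho_max = rho_max

    def _locate(self, energy: np.ndarray):
        log_e = np.log(energy)
        j = np.clip(np.searchsorted(self.log_e, log_e) - 1, 0,
                    len(self.log_e) - 2)
        f = (log_e - self.log_e[j]) / (self.log_e[j + 1] - self.log_e[j])
        return j, f

    def murho_total(self, mat_ids: np.ndarray, energy: np.ndarray
                    ) -> np.ndarray:
        j, f = self._locate(energy)
        lt = self.log_tot
        return np.exp(lt[mat_ids, j] * (1.0 - f) + lt[mat_ids, j + 1] * f)

    def component_cdf(self, mat_ids: np.ndarray, energy: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(P_pe, P_pe + P_compton) per particle."""
        j, f = self._locate(energy)
        lc = self.log_comp
        comp = np.exp(lc[mat_ids, :, j] * (1.0 - f)[:, None]
                      + lc[mat_ids, :, j + 1] * f[:, None])  # (n, 3)
        tot = comp.sum(axis=1)
        return comp[:, 0] / tot, (comp[:, 0] + comp[:, 1]) / tot

    def mu_majorant(self, energy: np.ndarray) -> np.ndarray:
        """Majorant linear attenuation (cm^-1); >= mu_tot of every voxel at
        the same energy, by construction (log-linear interpolation of the
        nodewise maximum dominates the interpolation of each curve)."""
        j, f = self._locate(energy)
        lm = self.log_majorant
        out = lm[j] * (1.0 - f) + lm[j + 1] * f
        return np.where(np.isfinite(out), np.exp(out), 0.0)

    def assert_majorant(self, grid: VoxelGrid) -> None:
        """Check mu_tot(voxel) <= mu_majorant on every table node."""
        for i, rho in enumerate(self.rho_max):
            if rho <= 0:
                continue
            if np.any(np.exp(self.log_tot[i]) * rho
                      > np.exp(self.log_majorant) * (1 + 1e-12)):
                raise AssertionError("majorant property violated")


# ----------------------------------------------------------------------
# free-path sampling (public, also used in transport loop)


def _advance_into_grid(pos: np.ndarray, dirs: np.ndarray, grid: VoxelGrid
                       ) -> np.ndarray:
    """Move particles outside the grid box to their entry point.

    Returns a boolean mask of particles that hit (or already are in) the
    box; positions are updated in place.
    """
    lo, hi = grid.bounds()
    t0 = np.zeros(len(pos))
    t1 = np.full(len(pos), np.inf)
    for a in range(3):
        d = dirs[:, a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[a] - pos[:, a]) / d
            tb = (hi[a] - pos[:, a]) / d
        lo_t = np.minimum(ta, tb)
        hi_t = np.maximum(ta, tb)
        par = np.abs(d) < 1e-300
        inside_a = (pos[:, a] >= lo[a]) & (pos[:, a] < hi[a])
        lo_t[par] = np.where(inside_a[par], -np.inf, np.inf)
        hi_t[par] = np.where(inside_a[par], np.inf, -np.inf)
        t0 = np.maximum(t0, lo_t)
        t1 = np.minimum(t1, hi_t)
    hit = t1 > t0
    t_entry = np.where(hit, np.maximum(t0, 0.0) + 1e-6, 0.0)
    pos += t_entry[:, None] * dirs
    return hit


def sample_free_path(grid: VoxelGrid, position, direction, energy,
                     rng: np.random.Generator):
    """Woodcock-track photons to their first real interaction.

    Returns ``(positions, interacted)``: for each particle either the
    interaction site (``interacted`` True) or its last position before
    leaving the grid (False). Vectorized; scalar inputs give scalar-ish
    (1-particle) outputs.
    """
    pos = np.array(np.atleast_2d(np.asarray(position, dtype=float)))
    dirs = np.atleast_2d(np.asarray(direction, dtype=float))
    e = np.broadcast_to(np.atleast_1d(np.asarray(energy, dtype=float)),
                        (len(pos),)).copy()
    lut = _MaterialLUT(grid)
    lut.assert_majorant(grid)
    out_pos = pos.copy()
    interacted = np.zeros(len(pos), dtype=bool)
    hit = _advance_into_grid(pos, dirs, grid)
    active = hit.copy()
    out_pos[hit] = pos[hit]
    dims = np.asarray(grid.dims)
    while active.any():
        idx = np.flatnonzero(active)
        mu_maj = lut.mu_majorant(e[idx])
        alive = mu_maj > 0
        active[idx[~alive]] = False
        idx = idx[alive]
        if len(idx) == 0:
            break
        step_mm = -np.log(rng.random(len(idx))) / mu_maj[alive] * 10.0
        pos[idx] += step_mm[:, None] * dirs[idx]
        vi = grid.voxel_index(pos[idx])
        inside = np.all((vi >= 0) & (vi < dims), axis=1)
        gone = idx[~inside]
        out_pos[gone] = pos[gone]
        active[gone] = False
        idx = idx[inside]
        vi = vi[inside]
        rho = grid.density[vi[:, 0], vi[:, 1], vi[:, 2]]
        mat = grid.material_id[vi[:, 0], vi[:, 1], vi[:, 2]]
        mu_tot = rho * lut.murho_total(mat, e[idx])
        real = rng.random(len(idx)) < mu_tot / lut.mu_majorant(e[idx])
        hit_idx = idx[real]
        out_pos[hit_idx] = pos[hit_idx]
        interacted[hit_idx] = True
        active[hit_idx] = False
    return out_pos, interacted


# ----------------------------------------------------------------------
# electron deposition


def deposit_electron(origin, direction, energy, weight, grid: VoxelGrid,
                     edep_flat: np.ndarray, rng: np.random.Generator,
                     n_steps: int = 20,
                     local_range_voxel_fraction: float = 0.5) -> float:
    """Condensed straight-ahead electron energy deposition.

    Each electron deposits ``E/n_steps`` per step into the voxel containing
    its current position, advances by the density-scaled CSDA step length,
    and scatters by a Highland-style Gaussian multiple-scatter angle.
    Electrons whose full density-scaled range at the origin voxel is below
    ``local_range_voxel_fraction`` of the smallest voxel pitch cannot be
    resolved by the grid and deposit on the spot. Energy carried outside
    the grid is returned as escaped energy (MeV, weighted); everything
    else lands in ``edep_flat`` (flattened C-order voxel array).
    """
    pos = np.array(np.atleast_2d(np.asarray(origin, dtype=float)))
    dirs = np.array(np.atleast_2d(np.asarray(direction, dtype=float)))
    e = np.atleast_1d(np.asarray(energy, dtype=float)).copy()
    w = np.broadcast_to(np.atleast_1d(np.asarray(weight, dtype=float)),
                        e.shape).copy()
    dims = np.asarray(grid.dims)
    nxyz = grid.dims
    escaped = 0.0
    table = STOPPING_POWERS["water"]
    e_clip = np.clip(e, table.energy_grid[0], table.energy_grid[-1])
    r_gcm2 = table.range_g_cm2(e_clip)
    # short-range (or below-table) electrons deposit on the spot
    vi0 = grid.voxel_index(pos)
    in0 = np.all((vi0 >= 0) & (vi0 < dims), axis=1)
    rho0 = np.ones(len(e))
    ii = vi0[in0]
    rho0[in0] = np.maximum(grid.density[ii[:, 0], ii[:, 1], ii[:, 2]], 1e-6)
    range_mm = r_gcm2 / rho0 * 10.0
    tiny = (e < table.energy_grid[0]) | (
        range_mm < local_range_voxel_fraction * float(grid.spacing.min()))
    if tiny.any():
        ok = tiny & in0
        flat = np.ravel_multi_index(
            (vi0[ok, 0], vi0[ok, 1], vi0[ok, 2]), nxyz)
        edep_flat += np.bincount(flat, weights=(e * w)[ok],
                                 minlength=edep_flat.size)
        escaped += float((e * w)[tiny & ~in0].sum())
    live = ~tiny
    pos, dirs = pos[live], dirs[live]
    e, w, r_gcm2 = e[live], w[live], r_gcm2[live]
    n = len(e)
    if n == 0:
        return escaped
    mass_step = r_gcm2 / n_steps  # g/cm^2 per step
    de = e / n_steps
    active = np.ones(n, dtype=bool)
    for istep in range(n_steps):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        vi = grid.voxel_index(pos[idx])
        inside = np.all((vi >= 0) & (vi < dims), axis=1)
        gone = idx[~inside]
        escaped += float((de[gone] * w[gone]).sum() * (n_steps - istep))
        active[gone] = False
        idx = idx[inside]
        vi = vi[inside]
        if len(idx) == 0:
            break
        flat = np.ravel_multi_index((vi[:, 0], vi[:, 1], vi[:, 2]), nxyz)
        edep_flat += np.bincount(flat, weights=de[idx] * w[idx],
                                 minlength=edep_flat.size)
        rho = np.maximum(grid.density[vi[:, 0], vi[:, 1], vi[:, 2]], 1e-6)
        step_mm = mass_step[idx] / rho * 10.0
        # Highland multiple-scatter angle for the remaining kinetic energy
        t_kin = np.maximum(e[idx] * (1.0 - istep / n_steps), 1e-3)
        p_beta = t_kin * (t_kin + 2 * ELECTRON_REST_MEV) / (
            t_kin + ELECTRON_REST_MEV)
        theta0 = 13.6 / p_beta * np.sqrt(
            np.maximum(mass_step[idx], 1e-12) / _X0_WATER_G_CM2)
        e1, e2 = _perp_basis(dirs[idx])
        kick = (rng.normal(size=len(idx)) * theta0)[:, None] * e1 \
            + (rng.normal(size=len(idx)) * theta0)[:, None] * e2
        nd = dirs[idx] + kick
        dirs[idx] = nd / np.linalg.norm(nd, axis=1, keepdims=True)
        pos[idx] += step_mm[:, None] * dirs[idx]
    return escaped


# ----------------------------------------------------------------------
# the transport loop


def beam_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal transverse axes (e1, e2) for a beam direction."""
    d = np.asarray(direction, dtype=float)
    e1, e2 = _perp_basis(d[None, :])
    return e1[0], e2[0]


def _transport_batch(grid: VoxelGrid, lut: _MaterialLUT, ps: PhaseSpace,
                     source: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                     axis: np.ndarray, n_histories: int,
                     rng: np.random.Generator, config: SimulationConfig,
                     edep_flat: np.ndarray, counters: dict) -> None:
    """Transport ``n_histories`` sampled phase-space particles, accumulating
    energy deposition (MeV, weighted) into ``edep_flat``."""
    dims = np.asarray(grid.dims)
    nxyz = grid.dims
    n_stored = len(ps)
    scale = n_stored / ps.n_source  # compaction correction
    cutoff = config.photon_cutoff_mev
    done = 0
    # electron bank for the whole batch
    bank_pos: list[np.ndarray] = []
    bank_dir: list[np.ndarray] = []
    bank_e: list[np.ndarray] = []
    bank_w: list[np.ndarray] = []

    def local_deposit(flat_idx, energies):
        np.add.at(edep_flat, flat_idx, energies)

    while done < n_histories:
        m = min(config.chunk_size, n_histories - done)
        done += m
        pick = rng.integers(0, n_stored, size=m)
        e = ps.energy[pick].copy()
        w = ps.weight[pick] * scale
        pos = (source[None, :]
               + ps.position[pick, 0, None] * e1[None, :]
               + ps.position[pick, 1, None] * e2[None, :]
               + ps.plane_z * axis[None, :])
        dirs = (ps.direction[pick, 0, None] * e1[None, :]
                + ps.direction[pick, 1, None] * e2[None, :]
                + ps.direction[pick, 2, None] * axis[None, :])
        counters["launched"] += float((e * w).sum())
        live = w > 0
        counters["escaped"] += float((e[~live] * w[~live]).sum())
        pos, dirs, e, w = pos[live], dirs[live], e[live], w[live]
        hit = _advance_into_grid(pos, dirs, grid)
        counters["escaped"] += float((e[~hit] * w[~hit]).sum())
        pos, dirs, e, w = pos[hit], dirs[hit], e[hit], w[hit]
        rounds = 0
        while len(e) > 0:
            rounds += 1
            if rounds > 500:  # safety: tally stragglers as escaped
                counters["escaped"] += float((e * w).sum())
                break
            mu_maj = lut.mu_majorant(e)
            vac = mu_maj <= 0
            if vac.any():
                counters["escaped"] += float((e[vac] * w[vac]).sum())
                pos, dirs, e, w = pos[~vac], dirs[~vac], e[~vac], w[~vac]
                mu_maj = mu_maj[~vac]
                if len(e) == 0:
                    break
            step_mm = -np.log(rng.random(len(e))) / mu_maj * 10.0
            pos += step_mm[:, None] * dirs
            vi = grid.voxel_index(pos)
            inside = np.all((vi >= 0) & (vi < dims), axis=1)
            counters["escaped"] += float((e[~inside] * w[~inside]).sum())
            pos, dirs, e, w = pos[inside], dirs[inside], e[inside], w[inside]
            vi = vi[inside]
            if len(e) == 0:
                break
            mu_maj = mu_maj[inside]
            rho = grid.density[vi[:, 0], vi[:, 1], vi[:, 2]]
            mat = grid.material_id[vi[:, 0], vi[:, 1], vi[:, 2]]
            mu_tot = rho * lut.murho_total(mat, e)
            real = rng.random(len(e)) < mu_tot / mu_maj
            if not real.any():
                continue
            ridx = np.flatnonzero(real)
            flat = np.ravel_multi_index(
                (vi[ridx, 0], vi[ridx, 1], vi[ridx, 2]), nxyz)
            p_pe, p_pc = lut.component_cdf(mat[ridx], e[ridx])
            u = rng.random(len(ridx))
            is_pe = u < p_pe
            is_compton = (~is_pe) & (u < p_pc)
            is_rayleigh = ~(is_pe | is_compton)

            # photoelectric: all photon energy to a local electron
            if is_pe.any():
                sel = ridx[is_pe]
                if config.electron_transport:
                    bank_pos.append(pos[sel])
                    bank_dir.append(dirs[sel])
                    bank_e.append(e[sel])
                    bank_w.append(w[sel])
                else:
                    local_deposit(flat[is_pe], e[sel] * w[sel])
                    counters["kerma"] += float((e[sel] * w[sel]).sum())

            # Compton: scatter photon, bank the recoil electron
            if is_compton.any():
                sel = ridx[is_compton]
                e_out, cos_t = sample_compton(e[sel], rng)
                phi = 2.0 * np.pi * rng.random(len(sel))
                new_dir = _rotate(dirs[sel], cos_t, phi)
                e_e = e[sel] - e_out
                if config.electron_transport:
                    pe_vec = (e[sel][:, None] * dirs[sel]
                              - e_out[:, None] * new_dir)
                    norm = np.linalg.norm(pe_vec, axis=1, keepdims=True)
                    fallback = norm[:, 0] < 1e-12
                    pe_vec[fallback] = dirs[sel][fallback]
                    norm[fallback] = 1.0
                    bank_pos.append(pos[sel])
                    bank_dir.append(pe_vec / norm)
                    bank_e.append(e_e)
                    bank_w.append(w[sel])
                else:
                    local_deposit(flat[is_compton], e_e * w[sel])
                    counters["kerma"] += float((e_e * w[sel]).sum())
                dirs[sel] = new_dir
                e[sel] = e_out

            # Rayleigh: direction change only
            if is_rayleigh.any():
                sel = ridx[is_rayleigh]
                cos_t = sample_rayleigh_cos(len(sel), rng)
                phi = 2.0 * np.pi * rng.random(len(sel))
                dirs[sel] = _rotate(dirs[sel], cos_t, phi)

            # retire photoelectric-absorbed and below-cutoff photons
            dead = np.zeros(len(e), dtype=bool)
            dead[ridx[is_pe]] = True
            low = e < cutoff
            low_new = low & ~dead
            if low_new.any():
                vi_low = grid.voxel_index(pos[low_new])
                flat_low = np.ravel_multi_index(
                    (vi_low[:, 0], vi_low[:, 1], vi_low[:, 2]), nxyz)
                local_deposit(flat_low, e[low_new] * w[low_new])
                counters["cutoff"] += float((e[low_new] * w[low_new]).sum())
            dead |= low
            keep = ~dead
            pos, dirs, e, w = pos[keep], dirs[keep], e[keep], w[keep]

    if bank_e:
        counters["escaped"] += deposit_electron(
            np.concatenate(bank_pos), np.concatenate(bank_dir),
            np.concatenate(bank_e), np.concatenate(bank_w),
            grid, edep_flat, rng, n_steps=config.electron_steps)


def run_mc(phantom: VoxelGrid, plan: BeamPlan,
           ps_per_collimator: dict[float, PhaseSpace],
           config: SimulationConfig) -> DoseGrid:
    """Run the Monte Carlo engine for a plan on a phantom.

    ``ps_per_collimator`` maps collimator projection diameter (mm) to a
    commissioned :class:`~irisdose.source.PhaseSpace`. The returned dose is
    ``calibration_factor * sum_beams MU_b * (per-history dose)`` in cGy;
    per-batch doses are retained for the uncertainty estimate. Global
    energy bookkeeping (launched = deposited + escaped per batch, within
    1e-6 relative) is recorded in ``meta["energy_accounting"]``.
    """
    for beam in plan.beams:
        if beam.collimator_diameter not in ps_per_collimator:
            raise KeyError(
                f"no phase space for collimator "
                f"{beam.collimator_diameter} mm")
    lut = _MaterialLUT(phantom)
    lut.assert_majorant(phantom)
    mass = phantom.density * phantom.voxel_volume_cm3  # g
    n_batches = config.batches
    hist_per_batch = config.histories // n_batches
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_batches * max(1, len(plan.beams)))
    batch_doses = np.zeros((n_batches,) + phantom.dims)
    accounting = []
    used_batches = 0
    for b in range(n_batches):
        edep = {}
        counters = {"launched": 0.0, "escaped": 0.0, "cutoff": 0.0,
                    "kerma": 0.0}
        dose_b = np.zeros(phantom.dims)
        for ib, beam in enumerate(plan.beams):
            if beam.mu == 0.0:
                continue
            ps = ps_per_collimator[beam.collimator_diameter].compact()
            if len(ps) == 0:
                continue
            rng = np.random.default_rng(children[b * len(plan.beams) + ib])
            e1, e2 = beam_basis(beam.direction)
            source = beam.isocenter - plan.sad * beam.direction
            edep_flat = np.zeros(phantom.n_voxels)
            _transport_batch(phantom, lut, ps, source, e1, e2,
                             beam.direction, hist_per_batch, rng, config,
                             edep_flat, counters)
            per_hist = edep_flat.reshape(phantom.dims) / hist_per_batch
            with np.errstate(divide="ignore", invalid="ignore"):
                dose_raw = np.where(mass > 0, per_hist / np.where(
                    mass > 0, mass, 1.0), 0.0)
            dose_b += plan.calibration_factor * beam.mu * dose_raw
            counters.setdefault("deposited", 0.0)
            counters["deposited"] += float(edep_flat.sum())
        batch_doses[b] = dose_b
        accounting.append(counters)
        used_batches = b + 1
        if config.target_rel_uncertainty is not None and used_batches >= 2:
            _, scalar = estimate_uncertainty(batch_doses[:used_batches])
            if scalar < config.target_rel_uncertainty:
                break
    batch_doses = batch_doses[:used_batches]
    rel, scalar = estimate_uncertainty(batch_doses)
    dose = batch_doses.mean(axis=0)
    return DoseGrid(
        grid=phantom, dose=dose, rel_uncertainty=rel,
        histories=hist_per_batch * used_batches, batches=used_batches,
        batch_doses=batch_doses,
        meta={
            "energy_accounting": accounting,
            "average_rel_uncertainty": scalar,
            "seed": config.seed,
        },
    )


def estimate_uncertainty(batch_doses: np.ndarray,
                         reporting_threshold: float = 0.5
                         ) -> tuple[np.ndarray, float]:
    """Per-voxel relative standard error of the batch mean, plus the scalar
    average over voxels receiving more than ``reporting_threshold`` of the
    maximum dose (the engine's reported uncertainty)."""
    bd = np.asarray(batch_doses, dtype=float)
    if bd.ndim < 2 or bd.shape[0] < 2:
        raise ValueError("need at least 2 batches")
    nb = bd.shape[0]
    mean = bd.mean(axis=0)
    se = bd.std(axis=0, ddof=1) / math.sqrt(nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), 0.0)
    peak = mean.max()
    if peak <= 0:
        return rel, 0.0
    sel = mean > reporting_threshold * peak
    return rel, float(rel[sel].mean())


# ----------------------------------------------------------------------
# absolute calibration


@dataclass
class CalibrationResult:
    factor: float  # cGy per MU per raw per-history dose unit
    reference_dose_raw: float
    rel_uncertainty: float
    histories: int


def make_calibration_phantom(voxel_mm: float = 5.0,
                             lateral_mm: float = 160.0,
                             depth_mm: float = 300.0,
                             sad: float = 800.0,
                             ref_depth_mm: float = 15.0) -> VoxelGrid:
    """Water tank for the reference geometry: beam along +z, surface at
    ``sad - ref_depth_mm`` from the source, and a voxel center exactly at
    the reference point ``(0, 0, sad)``.

    The axial spacing is chosen as ``ref_depth/2.5`` (6 mm for the default
    15 mm reference depth) so the reference point falls on a voxel center.
    """
    from .geometry import make_water_tank

    sz = ref_depth_mm / 2.5
    nz = int(round(depth_mm / sz))
    nxy = int(round(lateral_mm / voxel_mm))
    ssd = sad - ref_depth_mm
    origin = np.array([-(nxy - 1) * voxel_mm / 2.0,
                       -(nxy - 1) * voxel_mm / 2.0,
                       ssd + sz / 2.0])
    return make_water_tank((lateral_mm, lateral_mm, nz * sz),
                           (voxel_mm, voxel_mm, sz), origin_mm=origin)


def calibrate(ps60: PhaseSpace, config: SimulationConfig, sad: float = 800.0,
              ref_depth_mm: float = 15.0,
              max_rel_uncertainty: float = 0.02) -> CalibrationResult:
    """Tie the raw engine output to absolute dose: 1 MU = 1 cGy at 800 mm
    from the source and 15 mm depth in water with the 60 mm collimator.

    Simulates the reference geometry, averages the raw per-history dose
    over a 3 x 3 x 1-voxel region centered on the reference point, and
    returns the factor mapping 1 MU to 1 cGy there. Raises
    :class:`CalibrationUnstableError` if the region's relative standard
    error exceeds ``max_rel_uncertainty``.
    """
    phantom = make_calibration_phantom(sad=sad, ref_depth_mm=ref_depth_mm)
    plan = BeamPlan(
        beams=[Beam(isocenter=np.array([0.0, 0.0, sad]),
                    direction=np.array([0.0, 0.0, 1.0]),
                    collimator_diameter=ps60.collimator_diameter, mu=1.0)],
        sad=sad, calibration_factor=1.0)
    dose = run_mc(phantom, plan, {ps60.collimator_diameter: ps60}, config)
    ref, rel = reference_point_dose(dose, np.array([0.0, 0.0, sad]))
    if ref <= 0:
        raise CalibrationUnstableError("zero dose at the reference point")
    if rel > max_rel_uncertainty:
        raise CalibrationUnstableError(
            f"reference-region uncertainty {rel:.3f} exceeds "
            f"{max_rel_uncertainty}")
    return CalibrationResult(factor=1.0 / ref, reference_dose_raw=ref,
                             rel_uncertainty=rel, histories=dose.histories)


def reference_point_dose(dose: DoseGrid, point_mm: np.ndarray,
                         half_voxels: int = 1) -> tuple[float, float]:
    """Dose averaged over the (2h+1) x (2h+1) x 1 voxel region centered on
    ``point_mm``, with its batch-based relative standard error."""
    g = dose.grid
    c = g.voxel_index(point_mm)
    sl = (slice(c[0] - half_voxels, c[0] + half_voxels + 1),
          slice(c[1] - half_voxels, c[1] + half_voxels + 1),
          slice(c[2], c[2] + 1))
    region_batches = dose.batch_doses[(slice(None),) + sl].reshape(
        dose.batches, -1).mean(axis=1)
    mean = float(region_batches.mean())
    if mean <= 0:
        return 0.0, np.inf
    se = float(region_batches.std(ddof=1) / math.sqrt(dose.batches))
    return mean, se / mean
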
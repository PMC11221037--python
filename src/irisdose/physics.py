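"""Embedded photon cross sections and electron ranges, with interpolation
and interaction-type sampling.

Tables live in ``irisdose/data`` (see the README there for provenance).
Photon mass-attenuation components (photoelectric, Compton/incoherent,
Rayleigh/coherent) are interpolated log-log in energy; electron CSDA range
is interpolated linearly in log energy (of the log range). Energies outside
the tabulated 0.01-7 MeV window raise :class:`EnergyOutOfRangeError` rather
than extrapolating silently.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .geometry import MATERIAL_CATALOG

__all__ = [
    "EnergyOutOfRangeError",
    "PHOTOELECTRIC",
    "COMPTON",
    "RAYLEIGH",
    "CrossSectionTable",
    "StoppingPowerTable",
    "mu_components",
    "sample_interaction",
    "csda_range",
    "energy_range",
]

PHOTOELECTRIC, COMPTON, RAYLEIGH = 0, 1, 2
_INTERACTION_NAMES = {0: "photoelectric", 1: "compton", 2: "rayleigh"}


class EnergyOutOfRangeError(ValueError):
    """Photon/electron energy outside the tabulated range."""


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("irisdose.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


class CrossSectionTable:
    """Mass-attenuation components for one material, cm^2/g vs MeV."""

    def __init__(self, material: str, energy_grid: np.ndarray,
                 mu_pe: np.ndarray, mu_compton: np.ndarray,
                 mu_rayleigh: np.ndarray) -> None:
        self.material = material
        self.energy_grid = np.asarray(energy_grid, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        self.components = np.vstack([mu_pe, mu_compton, mu_rayleigh])
        if np.any(self.components <= 0):
            raise ValueError("mass attenuation components must be positive")
        self.total = self.components.sum(axis=0)
        self._log_e = np.log(self.energy_grid)
        self._log_c = np.log(self.components)

    def check_energy(self, energy: np.ndarray) -> None:
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise EnergyOutOfRangeError(
                f"energy outside tabulated range "
                f"[{self.energy_grid[0]}, {self.energy_grid[-1]}] MeV"
            )

    def mass_attenuation(self, energy) -> np.ndarray:
        """Interpolated (mu_pe, mu_C, mu_R)/rho, shape (3,) + shape(E)."""
        self.check_energy(energy)
        log_e = np.log(np.asarray(energy, dtype=float))
        return np.exp(
            np.vstack([np.interp(log_e, self._log_e, lc) for lc in self._log_c])
        )


class StoppingPowerTable:
    """Electron CSDA range (g/cm^2) vs kinetic energy for one material."""

    def __init__(self, material: str, energy_grid: np.ndarray,
                 csda_g_cm2: np.ndarray) -> None:
        self.material = material
        self.energy_grid = np.asarray(energy_grid, dtype=float)
        self.csda_g_cm2 = np.asarray(csda_g_cm2, dtype=float)
        if np.any(np.diff(self.csda_g_cm2) <= 0):
            raise ValueError("CSDA range must increase with energy")
        self._log_e = np.log(self.energy_grid)
        self._log_r = np.log(self.csda_g_cm2)

    def range_g_cm2(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise EnergyOutOfRangeError(
                "electron energy outside tabulated range"
            )
        return np.exp(np.interp(np.log(e), self._log_e, self._log_r))


def _load_tables() -> tuple[dict[str, CrossSectionTable],
                            dict[str, StoppingPowerTable]]:
    xs = _load_csv("cross_sections.csv")
    sp = _load_csv("csda_range.csv")
    xs_tables, sp_tables = {}, {}
    for mat in MATERIAL_CATALOG:
        sub = xs[xs.material == mat].sort_values("energy_MeV")
        xs_tables[mat] = CrossSectionTable(
            mat, sub.energy_MeV.to_numpy(), sub.mu_pe.to_numpy(),
            sub.mu_compton.to_numpy(), sub.mu_rayleigh.to_numpy()
        )
        sub = sp[sp.material == mat].sort_values("energy_MeV")
        sp_tables[mat] = StoppingPowerTable(
            mat, sub.energy_MeV.to_numpy(), sub.csda_g_cm2.to_numpy()
        )
    return xs_tables, sp_tables


CROSS_SECTIONS, STOPPING_POWERS = _load_tables()

#: lowest/highest tabulated photon energy, MeV
ENERGY_MIN = float(CROSS_SECTIONS["water"].energy_grid[0])
ENERGY_MAX = float(CROSS_SECTIONS["water"].energy_grid[-1])


def energy_range() -> tuple[float, float]:
    return ENERGY_MIN, ENERGY_MAX


def mu_components(material: str, energy, density):
    """Linear attenuation components ``(mu_pe, mu_C, mu_R, mu_tot)`` in cm^-1.

    Log-log interpolation of the stored mass coefficients multiplied by the
    mass density (g/cm^3).
    """
    table = CROSS_SECTIONS[material]
    mass = table.mass_attenuation(energy) * np.asarray(density, dtype=float)
    if np.isscalar(energy) and np.isscalar(density):
        return (float(mass[0, 0]), float(mass[1, 0]), float(mass[2, 0]),
                float(mass.sum(axis=0)[0]))
    return mass[0], mass[1], mass[2], mass.sum(axis=0)


def sample_interaction(material: str, energy, u):
    """Interaction type for uniform deviate(s) ``u`` in [0, 1).

    Returns :data:`PHOTOELECTRIC` if ``u < mu_pe/mu_tot``, :data:`COMPTON`
    if ``u < (mu_pe+mu_C)/mu_tot``, else :data:`RAYLEIGH`. Vectorized over
    ``energy`` and ``u``.
    """
    mu_pe, mu_c, _mu_r, mu_tot = mu_components(material, energy, 1.0)
    u = np.asarray(u, dtype=float)
    f_pe = mu_pe / mu_tot
    f_pc = (mu_pe + mu_c) / mu_tot
    out = np.full(np.broadcast(u, f_pe).shape, RAYLEIGH, dtype=np.int8)
    out[u < f_pc] = COMPTON
    out[u < f_pe] = PHOTOELECTRIC
    if out.ndim == 0:
        return int(out)
    return out


def csda_range(material: str, energy, density):
    """Electron CSDA range in mm at the given mass density (g/cm^3)."""
    r = STOPPING_POWERS[material].range_g_cm2(energy)
    return r / np.asarray(density, dtype=float) * 10.0  # cm -> mm
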
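"""Regenerate the embedded photon cross-section and electron-range tables.

Writes ``src/irisdose/data/cross_sections.csv`` and
``src/irisdose/data/csda_range.csv``.  The construction is documented in
``src/irisdose/data/README.md``: incoherent (Compton) mass attenuation is the
exact free-electron Klein-Nishina cross section times the electron density
Z/A * N_A; photoelectric and coherent (Rayleigh) components are smooth power
laws anchored at published 10 keV mass-attenuation values; electron CSDA
ranges are log-log interpolated from published water anchors.

Run from the repository root:  python scripts/generate_physics_tables.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "irisdose" / "data"

ELECTRON_REST_MEV = 0.51099895
R_E_CM = 2.8179403262e-13  # classical electron radius
N_AVOGADRO = 6.02214076e23

# material -> (Z/A, photoelectric tau/rho at 10 keV [cm^2/g], PE exponent,
#              coherent sigma/rho at 10 keV [cm^2/g], coherent exponent)
MATERIALS = {
    "water": (0.5551, 4.944, 3.0, 0.34, 1.9),
    "lung": (0.5551, 4.944, 3.0, 0.34, 1.9),  # soft tissue ~ water composition
    "bone": (0.5148, 28.0, 3.0, 1.05, 1.9),
    "air": (0.4992, 4.61, 3.0, 0.31, 1.9),
}

# Electron CSDA range anchors in liquid water: (kinetic energy MeV, g/cm^2)
CSDA_WATER = [
    (0.01, 2.52e-4), (0.02, 8.57e-4), (0.05, 4.32e-3), (0.1, 1.431e-2),
    (0.2, 4.497e-2), (0.3, 8.42e-2), (0.5, 0.1766), (0.7, 0.2706),
    (1.0, 0.4367), (1.5, 0.7075), (2.0, 0.9785), (3.0, 1.514),
    (4.0, 2.037), (5.0, 2.550), (6.0, 3.052), (7.0, 3.545),
]


def klein_nishina_total(energy_mev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    a = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def main() -> None:
    energy = np.geomspace(0.01, 7.0, 40)
    rows = []
    for name, (za, tau10, pe_exp, coh10, coh_exp) in MATERIALS.items():
        mu_compton = klein_nishina_total(energy) * N_AVOGADRO * za
        mu_pe = tau10 * (energy / 0.01) ** (-pe_exp)
        mu_rayleigh = coh10 * (energy / 0.01) ** (-coh_exp)
        mu_total = mu_pe + mu_compton + mu_rayleigh
        for i, e in enumerate(energy):
            rows.append(
                {
                    "material": name,
                    "energy_MeV": e,
                    "mu_pe": mu_pe[i],
                    "mu_compton": mu_compton[i],
                    "mu_rayleigh": mu_rayleigh[i],
                    "mu_total": mu_total[i],
                }
            )
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(DATA_DIR / "cross_sections.csv", index=False,
                              float_format="%.8e")

    e_anchor = np.array([e for e, _ in CSDA_WATER])
    r_anchor = np.array([r for _, r in CSDA_WATER])
    log_r = np.interp(np.log(energy), np.log(e_anchor), np.log(r_anchor))
    csda = np.exp(log_r)
    rows = []
    for name in MATERIALS:
        for e, r in zip(energy, csda):
            rows.append({"material": name, "energy_MeV": e, "csda_g_cm2": r})
    pd.DataFrame(rows).to_csv(DATA_DIR / "csda_range.csv", index=False,
                              float_format="%.8e")
    print(f"wrote tables to {DATA_DIR}")


if __name__ == "__main__":
    main()
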
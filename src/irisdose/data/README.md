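# Embedded physics tables

Both CSV files are generated by `scripts/generate_physics_tables.py`; edit
that script, not the CSVs.

## cross_sections.csv

Photon mass-attenuation components per material on a 40-point log-spaced
energy grid covering 0.01–7 MeV. Columns:

- `material` — catalog id (`water`, `lung`, `bone`, `air`)
- `energy_MeV` — photon energy
- `mu_pe`, `mu_compton`, `mu_rayleigh` — photoelectric, incoherent and
  coherent mass attenuation coefficients in cm²/g
- `mu_total` — sum of the three components (pair production is deliberately
  omitted; the beam spectrum tops out near 7 MeV and the contribution is
  small at these energies)

Provenance: the incoherent component is the exact free-electron
Klein–Nishina total cross section multiplied by the electron density
Z/A·N_A (Z/A: water/lung 0.5551, cortical bone 0.5148, air 0.4992); at
1 MeV this reproduces the published water value 0.0707 cm²/g to <1%.
Photoelectric and coherent components are single power laws in energy
(exponents −3 and −1.9) anchored at published 10 keV mass-attenuation
values for water (4.944 / 0.34 cm²/g), bone (28.0 / 1.05) and air
(4.61 / 0.31); lung uses the water (soft-tissue) composition. These
components are small above ~50 keV where this engine operates, and every
quantitative claim the package makes is internally self-consistent against
these same tables (the engine is self-calibrated), so the anchored power
laws are adequate; they are not a substitute-grade reproduction of full
tabulations below ~30 keV.

## csda_range.csv

Electron CSDA range in g/cm² on the same energy grid (kinetic energy),
log–log interpolated from published liquid-water anchors. The water range
is reused for all catalog materials — mass stopping powers of the catalog
materials agree with water to within a few percent over 0.01–7 MeV, and the
electron model scales geometric ranges by local mass density anyway.
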
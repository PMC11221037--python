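# Methods

This note records the physics model, the numerical choices, and the
limits of what the synthetic test surface demonstrates.

## Coordinate and unit conventions

World frame is right-handed, millimetres. A `VoxelGrid` stores the
*center* of voxel (0,0,0) as its origin; voxel (i,j,k) is the half-open
box `origin + idx*spacing ± spacing/2`; indices are 0-based, axis order
(x, y, z). Densities are g/cm³, energies MeV, attenuation coefficients
cm⁻¹ (free paths are converted to mm at the sampling step). Beams live
in a beam-local frame with the source at z = 0 and the axis along +z;
SAD is 800 mm and collimator "projection diameter" is defined on the
800 mm plane, the stereotactic convention for variable circular
apertures.

## Photon physics data

Cross sections are embedded tables on a 40-point log grid over
0.01–7 MeV (see `src/irisdose/data/README.md` for construction and
provenance): Klein–Nishina incoherent scattering (exact, free-electron),
plus anchored power laws for photoelectric and coherent components.
Interpolation is log–log per component; the total is the sum of the
interpolated components, so the component/total consistency invariant
holds by construction. Energies outside the table raise rather than
extrapolate. Pair production is omitted: the spectrum tops out near
6.5 MeV, where its contribution to attenuation in water is ~1%, and the
engine's absolute scale comes from calibration, not from table fidelity.
Electron CSDA ranges are water values reused for all materials (mass
stopping powers of the catalog materials agree with water to a few
percent; geometric ranges are scaled by local mass density anyway).

Material catalog: water (1.0 g/cm³), lung (0.26), bone (1.85), air
(0.0012); densities are overridable per phantom, and lung shares the
water (soft-tissue) composition.

## Source model and commissioning

The synthetic phase space replaces a treatment-head simulation: particles
start at a 2-D Gaussian focal spot (σ = 1.5 mm default) aimed uniformly
at the 60 mm disc of the 800 mm plane, with energies from a
flattening-filter-free-like histogram p(E) ∝ E·exp(−E/0.75) on
0.05–6.5 MeV (mean ≈ 1.4 MeV). All weights start at 1; records are taken
on the plane at 700 mm.

Two corrections adapt this raw source to "measured" water-tank curves:

* **Radial correction.** The 800 mm plane is divided into 60 annuli of
  1 mm (half-open bins [k, k+1) mm; radii ≥ 60 mm are left untouched).
  A fixed-point iteration multiplies each annulus coefficient by
  (measured/simulated)^0.7 of the off-center ratio at 10 cm depth until
  the worst region is within tolerance (0.5% default) or 20 iterations;
  the 0.7 damping and a [0.1, 10] coefficient clip guard against Monte
  Carlo noise. The forward model in the loop is the radial fluence
  profile of the projected, weighted particles (annulus-area weighted):
  at these field sizes the OCR shape is fluence-dominated, and the same
  forward operator generates the synthetic "measured" curves, so the
  fixed point recovers perturbations exactly in the noiseless limit.
* **Aperture correction** for collimators below 60 mm, radius R: weights
  of particles projecting beyond R are set to zero; then, for near-axial
  particles (direction cosine along the axis above 0.99), weight W₁ on
  the band (R, R+δR₁] and W₂ on [R−δR₂, R]. Zeroing is applied first and
  the axial-band rules override it, so near-axial particles just outside
  the aperture can carry W₁ while all other out-of-aperture particles
  carry zero. The four factors are fitted by coordinate descent on the
  OCR RMS deviation; the band width and its weight only act jointly, so
  the descent moves the pairs (δR₁, W₁) and (δR₂, W₂) together over
  successively refined grids, accepting only improvements (the objective
  is therefore non-increasing). The commissioning pipeline's default
  softening (δ = 1 mm, W₁ = 0.3, W₂ = 0.7) is used when no measured
  curve is being fitted.

Dropping zero-weight particles after collimation keeps the stored
per-history normalization through the `n_source` field, so output
factors for small collimators emerge from the surviving weight and the
physics rather than from renormalization.

## Monte Carlo transport

Photons are tracked with Woodcock (delta) tracking: free paths are drawn
against a majorant attenuation μ_max(E) built as the nodewise maximum
over the materials present (times each material's maximum density in the
grid), interpolated in log–log. Because a log-linear interpolation of a
nodewise maximum dominates the interpolation of every component curve,
the majorant property holds exactly at all energies; it is asserted at
run start. Voxels of zero density are transparent (vacuum), and an empty
majorant means immediate exit.

Interactions: photoelectric absorbs the photon into a local electron;
Compton scattering samples the Klein–Nishina ratio by
composition–rejection (the returned pair satisfies the Compton kinematic
identity exactly by construction) and hands the recoil electron its
momentum-conservation direction; Rayleigh scattering redirects with the
Thomson 1+cos²θ shape (form-factor-free — a documented simplification).
Photons below 10 keV deposit locally.

Electrons use condensed straight-ahead transport: 20 equal energy steps,
each depositing E/20 in the current voxel and advancing by the
density-scaled CSDA step, with a Highland-style Gaussian
multiple-scatter kick per step (X₀ = 36.08 g/cm² for all media).
Electrons whose full density-scaled range is below half the smallest
voxel pitch cannot be resolved by the grid and deposit on the spot; this
threshold only bypasses sub-voxel tracks, so build-up, penumbra and
low-density disequilibrium — which are carried by longer-range
electrons — are unaffected. Energy leaving the grid is tallied as
escaped; per batch, deposited + escaped equals launched weighted energy
to better than 10⁻⁶ relative, and this is recorded in the run manifest.
A `SimulationConfig(electron_transport=False)` switch deposits
secondary-electron energy at the interaction site (collision kerma), used
where electron-range smearing would mask an analytic comparison (e.g.
the inverse-square check in a near-massless phantom).

Scoring is energy per voxel mass — dose to medium. Runs are split into
batches (10 default) with independent generators spawned from one seed
(`SeedSequence`), giving reproducibility and the batch-based uncertainty
estimate: per-voxel relative standard error of the batch mean, reported
as a scalar averaged over voxels above 50% of the maximum dose.

**Calibration.** The absolute scale is set by simulating the reference
geometry — water surface at 785 mm so the scoring point at 15 mm depth
sits 800 mm from the source, 60 mm collimator — and averaging the raw
per-history dose over a 3×3×1-voxel region centered on the reference
point (the axial spacing, 6 mm, is chosen so a voxel center lands
exactly at the point). The returned factor maps 1 MU to 1 cGy there; a
reference-region uncertainty above 2% raises instead of returning an
unstable factor.

## The ray-trace comparator

The effective-path-length dose is
D = MU · K_c · T(d_eff)/T(15) · OCR(r₈₀₀, d_eff) · (815/r_geo)², with
T(d) = PDD(d)·((800+d)/815)² the Mayneord-corrected (TMR-like) depth
dose, d_eff the radiological depth from the beam-entry surface (first
sample above 0.05 g/cm³) to the voxel, r₈₀₀ the off-axis distance scaled
to the 800 mm plane, r_geo the geometric source distance, and K_c the
collimator's absolute output (cGy/MU at 15 mm depth). In uniform water
at the commissioning geometry this reduces algebraically to the
commissioned PDD. Depth doses are commissioned at SSD 800; OCR curves at
15/100/300 mm depth are interpolated linearly in depth and off-axis
position and clamped at their ends; d_eff outside the PDD domain is
clamped. d_eff is computed by sampling density at 512 evenly spaced
points per source→voxel ray (trilinear, zero outside the phantom), an
accuracy of roughly ray-length/512 ≈ 2 mm in surface position and well
under 1 mm in water-equivalent depth; the exact Siddon traversal
(`radiological_path`) is the reference it is tested against.

Commissioning both engines from the same Monte Carlo water runs keeps
them self-consistent in water, so any disagreement on heterogeneous
phantoms is the heterogeneity physics, not a scale offset. Per
collimator, one SSD-800 water-tank run yields the PDD (averaged over a
7.5 mm axis region, tail smoothed with a one-node Gaussian beyond the
build-up peak — commissioning practice, and it removes the Monte Carlo
point-to-point noise that would otherwise alias into the ray-trace
lookup), the OCR curves (azimuthally averaged annuli of the measurement
plane, rescaled to the 800 mm plane — far lower variance than a line
profile), and the absolute output at 15 mm.

## Evaluation suite

The global 3-D gamma of a reference voxel is the minimum over candidate
positions of sqrt[(ΔD/(tol%·max ref))² + (Δr/DTA)²], with the evaluated
dose trilinearly interpolated on a candidate lattice of step 0.1·DTA
within radius 3·DTA (candidates outside the evaluated grid's
interpolation domain are skipped; ties resolve to the exact minimum of
the sampled set). Voxels below the low-dose threshold (10% of the
reference maximum, global normalization) are excluded. The
implementation processes candidates in distance-sorted order and retires
a voxel once the remaining distance penalty alone exceeds its running
minimum — an exact pruning, verified against a dense brute-force oracle
on random grids to 10⁻⁶. Pass rates are not symmetric in the pair; the
reference is always the first-named distribution. Because the candidate
lattice scales with DTA, gamma is only guaranteed monotone across DTA
values when the lattices are aligned; the test suite checks it that way.

DVH metrics follow the convention D_i = minimum dose to the hottest i%
of the structure: the dose at the (100−i)-th percentile from the bottom,
with linear interpolation between order statistics. ΔD maps are
voxel-wise differences, restricted to a body mask (density above
0.05 g/cm³) when provided.

## The lung-slab benchmark

The chest-like case is 50 mm water / 80 mm lung (ρ = 0.26) / 170 mm
water at 5 mm voxels, a 20 mm-diameter spherical target centered in the
lung layer, and three coplanar 25 mm beams at −20°/0°/+20° converging on
the target (100 MU each). The comparison triplet is ray-trace vs two
independent-seed Monte Carlo runs; the expected signature — positive
(RT − MC) target D_mean, and an RT-vs-MC 2%/2 mm pass rate below the
MC-vs-MC noise baseline — is the qualitative content of the clinical
chest-case finding, and is what the acceptance suite asserts. Magnitudes
depend on the synthetic spectrum, slab geometry and statistics and are
not claimed to match any clinical cohort.

## Problem sizes and defaults

Desk-scale defaults: 5 mm voxels, 10 batches, 2×10⁵ histories per beam
for exploration; the uncertainty-sensitive runs use more (1.6×10⁶ per
beam for the benchmark, ≈ 2% scalar uncertainty; 3.2×10⁶ for the
calibration round-trip in `scripts/acceptance.py`, ≈ 1.4% reference
uncertainty). The clinical-scale settings (1 mm grid, 0.5% uncertainty)
remain configurable but are not the test surface. The vectorized engine
transports roughly 10⁵ histories per second per core on commodity
hardware.

## What the synthetic surface does and does not show

The generator emulates: a small-field circular-aperture beam with
focal-spot penumbra, a commissioning mismatch correctable by radial
reweighting, water-tank curve measurement, and lung-like heterogeneity.
It does not emulate: a real treatment head (no electron contamination,
no exact spectrum), CT-derived anatomy and HU calibration, detector
response, MLC fields, or the vendor's proprietary ray-trace scatter
handling. Consequently the package's quantitative claims are
self-consistency claims (calibration round-trip, oracle equivalence,
parameter recovery, statistical scaling) plus the *sign and ordering* of
the heterogeneity effect; numeric parity with any clinical system is out
of scope. Within the engine itself, the known simplifications — no pair
production, Thomson-shaped coherent scattering, water stopping powers
and radiation length for all media, straight-ahead condensed electrons —
bound the physics fidelity and are the first places to look if the
engine is ever compared against a full-physics code.
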
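"""Synthetic phase-space source model and its two commissioning corrections.

The beam source is a set of weighted particle records (energy, position,
direction) on a scoring plane perpendicular to the beam axis, in the
beam-local frame: source at z = 0, beam axis +z, plane at ``plane_z`` mm.

Two corrections adapt a 60 mm-aperture phase space to measured water-tank
data:

* a **radial correction** — 60 weight coefficients on 1 mm annuli of the
  800 mm projection plane, fitted by fixed-point iteration so the simulated
  off-center ratio (OCR) at 10 cm depth matches the measured curve;
* a **four-factor aperture correction** ``(dR1, dR2, W1, W2)`` for smaller
  collimators — particles projecting outside the aperture radius R are
  removed, and near-axial particles (direction cosine along the beam axis
  above 0.99) in the bands just outside/inside R are reweighted to soften
  the penumbra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "COLLIMATOR_DIAMETERS_MM",
    "PROJECTION_PLANE_MM",
    "EnergySpectrum",
    "PhaseSpace",
    "RadialCorrection",
    "ApertureFactors",
    "Curve",
    "FitDegenerateError",
    "default_spectrum",
    "generate_phase_space",
    "projection_radius",
    "apply_radial_correction",
    "collimate",
    "fit_radial_correction",
    "fit_aperture_factors",
    "FluenceOCREngine",
    "make_synthetic_measurements",
]

#: Allowed collimator projection diameters (mm) at the 800 mm plane.
COLLIMATOR_DIAMETERS_MM = (5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0,
                           35.0, 40.0, 50.0, 60.0)

#: The plane (mm from source) where projection diameters are defined.
PROJECTION_PLANE_MM = 800.0

#: Number of 1 mm radial correction regions, covering 0-60 mm.
N_RADIAL_BINS = 60


class FitDegenerateError(RuntimeError):
    """A commissioning fit hit a degenerate configuration."""


@dataclass
class Curve:
    """A sampled 1-D curve (e.g. PDD depth->value, OCR off-axis->value)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("curve x and y must be equal-length 1-D arrays")

    def __call__(self, x) -> np.ndarray:
        return np.interp(x, self.x, self.y)


@dataclass
class EnergySpectrum:
    """Histogram spectrum: ``edges`` (MeV, len n+1) and bin probabilities."""

    edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) != len(self.probabilities) + 1:
            raise ValueError("need len(edges) == len(probabilities) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample energies: categorical bin choice, uniform within bin."""
        k = rng.choice(len(self.probabilities), size=n, p=self.probabilities)
        u = rng.random(n)
        return self.edges[k] + u * (self.edges[k + 1] - self.edges[k])

    def mean_energy(self) -> float:
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(np.sum(mids * self.probabilities))


def default_spectrum(n_bins: int = 30) -> EnergySpectrum:
    """Flattening-filter-free-like 6 MV bremsstrahlung histogram.

    Shape p(E) proportional to E*exp(-E/0.75) on 0.05-6.5 MeV, giving a mean
    energy of ~1.4 MeV.
    """
    edges = np.linspace(0.05, 6.5, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    p = mids * np.exp(-mids / 0.75)
    p /= p.sum()
    return EnergySpectrum(edges, p)


@dataclass
class PhaseSpace:
    """Weighted particle records on a scoring plane (beam-local frame).

    Arrays are parallel: ``energy`` (MeV), ``position`` (n, 2) mm on the
    plane, ``direction`` (n, 3) unit vectors with positive z component,
    ``weight`` dimensionless. ``n_source`` is the number of source
    histories the records represent — it stays fixed when zero-weight
    particles are dropped by :meth:`compact`, so per-history normalization
    is preserved.
    """

    energy: np.ndarray
    position: np.ndarray
    direction: np.ndarray
    weight: np.ndarray
    plane_z: float
    collimator_diameter: float
    n_source: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        n = len(self.energy)
        if self.position.shape != (n, 2) or self.direction.shape != (n, 3):
            raise ValueError("inconsistent phase-space array shapes")
        if self.plane_z <= 0:
            raise ValueError("plane_z must be positive")
        if float(self.collimator_diameter) not in COLLIMATOR_DIAMETERS_MM:
            raise ValueError(
                f"collimator diameter {self.collimator_diameter} mm not in "
                f"{COLLIMATOR_DIAMETERS_MM}"
            )
        norms = np.linalg.norm(self.direction, axis=1)
        if n and (np.max(np.abs(norms - 1.0)) > 1e-9):
            raise ValueError("directions must be unit vectors within 1e-9")
        if n and np.any(self.direction[:, 2] <= 0):
            raise ValueError("direction z components must be positive")
        if np.any(~np.isfinite(self.weight)) or np.any(self.weight < 0):
            raise ValueError("weights must be finite and non-negative")
        if self.n_source <= 0:
            self.n_source = n

    def __len__(self) -> int:
        return len(self.energy)

    def compact(self) -> "PhaseSpace":
        """Drop zero-weight particles; ``n_source`` is retained."""
        keep = self.weight > 0
        return replace(
            self,
            energy=self.energy[keep],
            position=self.position[keep],
            direction=self.direction[keep],
            weight=self.weight[keep],
        )

    def total_weight(self) -> float:
        return float(self.weight.sum())


def generate_phase_space(spectrum: EnergySpectrum, focal_spot_sigma: float,
                         plane_z: float, n: int, seed,
                         cone_diameter_mm: float = 60.0) -> PhaseSpace:
    """Synthetic 60 mm-aperture phase space.

    Each particle starts at a 2-D Gaussian focal spot (sigma
    ``focal_spot_sigma`` mm) at z = 0 and is aimed at a point drawn
    uniformly on the ``cone_diameter_mm`` disc of the 800 mm projection
    plane; its record is taken where the ray crosses ``plane_z``. Energies
    are i.i.d. from ``spectrum``; all weights are 1. Deterministic given
    ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    energy = spectrum.sample(n, rng)
    focal = rng.normal(scale=focal_spot_sigma, size=(n, 2))
    # uniform disc at the projection plane
    r = 0.5 * cone_diameter_mm * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    aim = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    d = np.column_stack([aim - focal,
                         np.full(n, PROJECTION_PLANE_MM)])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    t = plane_z / d[:, 2]
    pos = focal + t[:, None] * d[:, :2]
    return PhaseSpace(
        energy=energy, position=pos, direction=d, weight=np.ones(n),
        plane_z=float(plane_z), collimator_diameter=60.0, n_source=n,
        provenance={
            "seed": seed, "focal_spot_sigma_mm": focal_spot_sigma,
            "cone_diameter_mm": cone_diameter_mm,
            "spectrum_mean_MeV": spectrum.mean_energy(),
        },
    )


def projection_radius(position: np.ndarray, direction: np.ndarray,
                      plane_z_from: float,
                      plane_z_to: float = PROJECTION_PLANE_MM) -> np.ndarray:
    """Radial distance from the beam axis of the straight-line extension of
    each particle to ``plane_z_to``.

    ``position`` is (n, 2) on the plane at ``plane_z_from``; raises for
    non-positive axial direction components.
    """
    position = np.atleast_2d(np.asarray(position, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    if np.any(direction[:, 2] <= 0):
        raise ValueError("particle axial direction component must be > 0")
    dz = plane_z_to - plane_z_from
    xy = position + direction[:, :2] / direction[:, 2:3] * dz
    return np.hypot(xy[:, 0], xy[:, 1])


@dataclass
class RadialCorrection:
    """60 weight coefficients on the 1 mm annuli [k, k+1) mm of the 800 mm
    projection plane."""

    coefficients: np.ndarray
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(N_RADIAL_BINS + 1, dtype=float)
    )

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.coefficients.shape != (N_RADIAL_BINS,):
            raise ValueError(f"need exactly {N_RADIAL_BINS} coefficients")
        if len(self.bin_edges) != N_RADIAL_BINS + 1:
            raise ValueError("need 61 bin edges (0..60 mm)")
        if np.any(~np.isfinite(self.coefficients)) or np.any(
            self.coefficients <= 0
        ):
            raise ValueError("coefficients must be positive and finite")

    @classmethod
    def identity(cls) -> "RadialCorrection":
        return cls(np.ones(N_RADIAL_BINS))


@dataclass
class ApertureFactors:
    """Four-factor aperture correction for a collimator of radius R (mm).

    Particles with projection radius R_p > R are removed; near-axial
    particles (axial direction cosine > ``axial_cosine_threshold``) get
    weight W1 on (R, R + dR1] and weight W2 on [R - dR2, R].
    """

    R: float
    delta_R1: float = 0.0
    delta_R2: float = 0.0
    W1: float = 0.0
    W2: float = 1.0
    axial_cosine_threshold: float = 0.99

    def __post_init__(self) -> None:
        vals = [self.R, self.delta_R1, self.delta_R2, self.W1, self.W2]
        if not np.all(np.isfinite(vals)):
            raise ValueError("aperture factors must be finite")
        if self.delta_R1 < 0 or self.delta_R2 < 0 or self.W1 < 0 or self.W2 < 0:
            raise ValueError("aperture factors must be non-negative")
        if self.R - self.delta_R2 < 0:
            raise ValueError("need R - delta_R2 >= 0")


def apply_radial_correction(ps: PhaseSpace, corr: RadialCorrection,
                            projection_plane_z: float = PROJECTION_PLANE_MM
                            ) -> PhaseSpace:
    """Multiply each particle's weight by the coefficient of the 1 mm bin
    containing its projection radius; radii >= 60 mm are left unchanged."""
    r = projection_radius(ps.position, ps.direction, ps.plane_z,
                          projection_plane_z)
    k = np.floor(r).astype(int)
    w = ps.weight.copy()
    inside = k < N_RADIAL_BINS
    w[inside] *= corr.coefficients[k[inside]]
    return replace(ps, weight=w)


def collimate(ps: PhaseSpace, factors: ApertureFactors) -> PhaseSpace:
    """Aperture correction at the 800 mm projection plane.

    Rule order: (1) weight := 0 where R_p > R; then, for particles whose
    axial direction cosine exceeds the threshold, (2) weight := W1 on
    R_p in (R, R + dR1], (3) weight := W2 on R_p in [R - dR2, R].
    """
    r = projection_radius(ps.position, ps.direction, ps.plane_z)
    w = ps.weight.copy()
    w[r > factors.R] = 0.0
    axial = ps.direction[:, 2] > factors.axial_cosine_threshold
    band1 = axial & (r > factors.R) & (r <= factors.R + factors.delta_R1)
    band2 = axial & (r >= factors.R - factors.delta_R2) & (r <= factors.R)
    w[band1] = factors.W1 * ps.weight[band1]
    w[band2] = factors.W2 * ps.weight[band2]
    new_d = min(COLLIMATOR_DIAMETERS_MM, key=lambda c: abs(c - 2 * factors.R))
    return replace(ps, weight=w, collimator_diameter=new_d)


class FluenceOCREngine:
    """Fast forward model of the off-center ratio at depth in water.

    Projects the weighted particles to the measurement plane (source-to-
    detector distance 800 mm) and forms the radial fluence profile on the
    60 one-millimetre annuli (annulus-area weighted), optionally blurred by
    a small Gaussian standing in for lateral secondary-electron transport,
    then normalizes to the central bin. Primary fluence dominates the OCR
    shape at these field sizes, which makes this the natural forward engine
    for the iterative source-commissioning loops; the full Monte Carlo OCR
    is available through the transport engine when absolute curves are
    needed.
    """

    def __init__(self, depth_mm: float = 100.0, sdd_mm: float = 800.0,
                 blur_sigma_mm: float = 0.0) -> None:
        self.depth_mm = depth_mm
        self.sdd_mm = sdd_mm
        self.blur_sigma_mm = blur_sigma_mm
        self.bin_centers = np.arange(N_RADIAL_BINS) + 0.5

    def radial_fluence(self, ps: PhaseSpace) -> np.ndarray:
        r = projection_radius(ps.position, ps.direction, ps.plane_z,
                              self.sdd_mm)
        hist, _ = np.histogram(r, bins=np.arange(N_RADIAL_BINS + 1),
                               weights=ps.weight)
        edges = np.arange(N_RADIAL_BINS + 1, dtype=float)
        area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        fluence = hist / area
        if self.blur_sigma_mm > 0:
            fluence = gaussian_filter1d(fluence, self.blur_sigma_mm,
                                        mode="nearest")
        return fluence

    def __call__(self, ps: PhaseSpace) -> Curve:
        fluence = self.radial_fluence(ps)
        if fluence[0] <= 0:
            raise FitDegenerateError("zero fluence in the central region")
        return Curve(self.bin_centers, fluence / fluence[0])


def _resample_measured(measured, bin_centers: np.ndarray) -> np.ndarray:
    if isinstance(measured, Curve):
        return measured(bin_centers)
    if callable(measured):
        return np.asarray(measured(bin_centers), dtype=float)
    arr = np.asarray(measured, dtype=float)
    if arr.shape == bin_centers.shape:
        return arr
    raise ValueError("measured curve must be a Curve, callable, or 60-vector")


def fit_radial_correction(ps: PhaseSpace, measured_ocr_10cm, forward_engine,
                          tol: float = 0.005, max_iter: int = 20,
                          damping: float = 0.7,
                          clip: tuple[float, float] = (0.1, 10.0)
                          ) -> tuple[RadialCorrection, list[float]]:
    """Fixed-point fit of the 60 radial correction coefficients.

    Starting from all ones, iterate ``c_{k+1}(r) = c_k(r) *
    (measured(r)/simulated_k(r))**damping`` per 1 mm region until the worst
    region satisfies ``|measured/simulated - 1| < tol`` or ``max_iter`` is
    reached; coefficients are clipped to ``clip`` for robustness under
    Monte Carlo noise. Returns the correction and the residual trace.

    Raises :class:`FitDegenerateError` if a region simulates zero with a
    nonzero measured value.
    """
    engine = forward_engine
    centers = getattr(engine, "bin_centers", np.arange(N_RADIAL_BINS) + 0.5)
    target = _resample_measured(measured_ocr_10cm, centers)
    coeff = np.ones(N_RADIAL_BINS)
    trace: list[float] = []
    current = ps
    for _ in range(max_iter):
        sim = engine(current)
        sim_y = sim.y if isinstance(sim, Curve) else np.asarray(sim)
        bad = (sim_y <= 0) & (target > 0)
        if np.any(bad):
            region = int(np.argmax(bad))
            raise FitDegenerateError(
                f"simulated OCR is zero in region [{region}, {region + 1}) mm "
                "with nonzero measured value"
            )
        ratio = np.where(sim_y > 0, target / np.where(sim_y > 0, sim_y, 1.0),
                         1.0)
        resid = float(np.max(np.abs(ratio - 1.0)))
        trace.append(resid)
        if resid < tol:
            break
        coeff = np.clip(coeff * ratio**damping, *clip)
        current = apply_radial_correction(ps, RadialCorrection(coeff))
    return RadialCorrection(coeff), trace


def _ocr_objective(ps60: PhaseSpace, factors: ApertureFactors, engine,
                   target: np.ndarray) -> float:
    sim = engine(collimate(ps60, factors))
    sim_y = sim.y if isinstance(sim, Curve) else np.asarray(sim)
    obj = float(np.sqrt(np.mean((sim_y - target) ** 2)))
    if not np.isfinite(obj):
        raise FitDegenerateError("non-finite aperture-fit objective")
    return obj


def fit_aperture_factors(ps60: PhaseSpace, R: float, measured_ocr_10cm,
                         forward_engine, n_sweeps: int = 4
                         ) -> tuple[ApertureFactors, float, list[dict]]:
    """Coordinate-descent fit of ``(dR1, dR2, W1, W2)`` for radius R < 30 mm.

    Minimizes the RMS deviation between the simulated and measured OCR at
    10 cm depth over successively refined per-parameter grids; only
    improving steps are accepted, so the objective is non-increasing.
    Returns (factors, final objective, search trace).
    """
    if R >= 30.0:
        raise ValueError("aperture factors apply to collimators below 60 mm "
                         "(R < 30 mm)")
    engine = forward_engine
    centers = getattr(engine, "bin_centers", np.arange(N_RADIAL_BINS) + 0.5)
    target = _resample_measured(measured_ocr_10cm, centers)
    params = {"delta_R1": 0.0, "delta_R2": 0.0, "W1": 0.0, "W2": 1.0}
    spans = {"delta_R1": (0.0, 5.0), "delta_R2": (0.0, min(5.0, R)),
             "W1": (0.0, 1.5), "W2": (0.0, 1.5)}
    best = _ocr_objective(ps60, ApertureFactors(R=R, **params), engine,
                          target)
    trace = [{"params": dict(params), "objective": best}]
    widths = {k: (hi - lo) for k, (lo, hi) in spans.items()}
    # a band width and its weight only act together, so descend on the
    # (width, weight) pairs jointly
    pairs = (("delta_R1", "W1"), ("delta_R2", "W2"))
    for sweep in range(n_sweeps):
        for name_d, name_w in pairs:
            shrink = 2.0**sweep
            grids = []
            for name in (name_d, name_w):
                lo, hi = spans[name]
                w = widths[name] / shrink
                grids.append(np.unique(np.clip(
                    params[name] + np.linspace(-w, w, 9), lo, hi)))
            for vd in grids[0]:
                for vw in grids[1]:
                    cand = dict(params)
                    cand[name_d] = float(vd)
                    cand[name_w] = float(vw)
                    obj = _ocr_objective(ps60, ApertureFactors(R=R, **cand),
                                         engine, target)
                    if obj < best:
                        best = obj
                        params = cand
                        trace.append({"params": dict(params),
                                      "objective": best})
    return ApertureFactors(R=R, **params), best, trace


def make_synthetic_measurements(engine_config: dict, perturbation_spec: dict,
                                seed) -> tuple[Curve, dict[float, Curve]]:
    """Synthetic water-tank 'measured' commissioning curves.

    Stands in for diode measurements: the forward models are evaluated with
    a documented perturbation and optional Gaussian noise/smoothing.

    ``engine_config`` keys: ``phase_space`` (a 60 mm :class:`PhaseSpace`),
    ``ocr_depths_mm`` (default ``[100.0]``), ``pdd`` (optional measured-PDD
    :class:`Curve` to perturb; omitted -> an attenuation-law placeholder).
    ``perturbation_spec`` keys (all optional): ``radial_gain`` (callable
    g(r) applied to particle weights), ``aperture`` (:class:`ApertureFactors`
    applied before projection), ``noise_rel`` (relative Gaussian noise),
    ``smooth_sigma_mm`` (Gaussian smoothing of the noisy curves).
    """
    rng = np.random.default_rng(seed)
    ps: PhaseSpace = engine_config["phase_space"]
    depths = engine_config.get("ocr_depths_mm", [100.0])
    if perturbation_spec.get("radial_gain") is not None:
        g = perturbation_spec["radial_gain"]
        r = projection_radius(ps.position, ps.direction, ps.plane_z)
        ps = replace(ps, weight=ps.weight * np.asarray(g(r), dtype=float))
    if perturbation_spec.get("aperture") is not None:
        ps = collimate(ps, perturbation_spec["aperture"])
    noise = float(perturbation_spec.get("noise_rel", 0.0))
    smooth = float(perturbation_spec.get("smooth_sigma_mm", 0.0))

    def _finish(curve: Curve) -> Curve:
        y = curve.y.copy()
        if noise > 0:
            y = y * (1.0 + noise * rng.standard_normal(len(y)))
        if smooth > 0:
            y = gaussian_filter1d(y, smooth, mode="nearest")
        return Curve(curve.x, y)

    ocr_curves = {}
    for depth in depths:
        engine = FluenceOCREngine(depth_mm=depth)
        ocr_curves[float(depth)] = _finish(engine(ps))
    if "pdd" in engine_config:
        pdd = _finish(engine_config["pdd"])
    else:
        depths_mm = np.arange(0.0, 301.0, 5.0)
        y = 100.0 * np.exp(-0.00575 * depths_mm)  # ~6 MV water attenuation
        pdd = _finish(Curve(depths_mm, y))
    return pdd, ocr_curves
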
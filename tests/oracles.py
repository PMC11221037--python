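"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the gamma oracle is a
dense per-voxel search with hand-written trilinear interpolation, the path
oracle uses dense supersampling instead of exact plane traversal, the
Klein-Nishina oracle uses numerical quadrature, and the DVH oracle uses
explicit order statistics.
"""

import numpy as np
from scipy import integrate


def supersample_path(grid, p0, p1, n=10_000):
    """Radiological path by dense midpoint sampling (nearest-voxel lookup)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        return 0.0
    u = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + u[:, None] * (p1 - p0)[None, :]
    idx = np.floor((pts - grid.origin) / grid.spacing + 0.5).astype(int)
    dims = np.asarray(grid.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    rho = np.zeros(n)
    ii = idx[inside]
    rho[inside] = grid.density[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(rho.sum() * length / n)


def _trilinear(data, coords):
    """Hand-written trilinear interpolation; NaN outside [0, n-1]^3.

    ``coords``: (m, 3) fractional voxel coordinates.
    """
    dims = np.asarray(data.shape)
    c = np.asarray(coords, dtype=float)
    valid = np.all((c >= 0.0) & (c <= dims - 1), axis=1)
    i0 = np.floor(c).astype(int)
    i0 = np.minimum(i0, dims - 1)
    f = c - i0
    i1 = np.minimum(i0 + 1, dims - 1)
    out = np.zeros(len(c))
    for dx in (0, 1):
        wx = (1 - f[:, 0]) if dx == 0 else f[:, 0]
        ix = i0[:, 0] if dx == 0 else i1[:, 0]
        for dy in (0, 1):
            wy = (1 - f[:, 1]) if dy == 0 else f[:, 1]
            iy = i0[:, 1] if dy == 0 else i1[:, 1]
            for dz in (0, 1):
                wz = (1 - f[:, 2]) if dz == 0 else f[:, 2]
                iz = i0[:, 2] if dz == 0 else i1[:, 2]
                out += wx * wy * wz * data[np.clip(ix, 0, dims[0] - 1),
                                           np.clip(iy, 0, dims[1] - 1),
                                           np.clip(iz, 0, dims[2] - 1)]
    out[~valid] = np.nan
    return out


def brute_force_gamma(ref, ev, spacing, dose_tol_pct, dta_mm,
                      threshold_pct=10.0, radius_factor=3.0,
                      step_factor=0.1):
    """Dense-candidate gamma: every lattice offset evaluated for every
    voxel, no pruning. Returns (gamma array with NaN outside the evaluated
    mask, pass rate percent)."""
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(ev, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    norm = ref.max()
    tol_abs = dose_tol_pct / 100.0 * norm
    mask = ref >= threshold_pct / 100.0 * norm
    n = int(round(radius_factor / step_factor))
    k = np.arange(-n, n + 1)
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    keep = kx**2 + ky**2 + kz**2 <= n**2
    offs_mm = (np.stack([kx[keep], ky[keep], kz[keep]], axis=1)
               * step_factor * dta_mm)
    d2 = np.sum(offs_mm**2, axis=1) / dta_mm**2
    gamma = np.full(ref.shape, np.nan)
    for v in np.argwhere(mask):
        coords = v[None, :] + offs_mm / spacing[None, :]
        vals = _trilinear(ev, coords)
        with np.errstate(invalid="ignore"):
            g2 = ((vals - ref[tuple(v)]) / tol_abs) ** 2 + d2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        gamma[tuple(v)] = np.sqrt(g2.min())
    vals = gamma[mask]
    return gamma, 100.0 * float(np.mean(vals <= 1.0))


ELECTRON_REST_MEV = 0.51099895


def klein_nishina_mean_scattered_fraction(energy_mev):
    """Mean E_out/E by quadrature of the Klein-Nishina angular cross
    section."""
    a = energy_mev / ELECTRON_REST_MEV

    def eps(mu):
        return 1.0 / (1.0 + a * (1.0 - mu))

    def dsigma(mu):  # unnormalized dsigma/dmu
        e = eps(mu)
        return e**2 * (e + 1.0 / e - (1.0 - mu**2))

    num, _ = integrate.quad(lambda m: eps(m) * dsigma(m), -1, 1,
                            epsabs=1e-12)
    den, _ = integrate.quad(dsigma, -1, 1, epsabs=1e-12)
    return num / den


def dvh_percentile(values, i):
    """D_i by explicit order statistics with linear interpolation: the
    dose at the (100 - i)-th percentile from the bottom."""
    v = np.sort(np.asarray(values, dtype=float))
    q = (100.0 - i) / 100.0
    rank = q * (len(v) - 1)
    lo = int(np.floor(rank))
    hi = min(lo + 1, len(v) - 1)
    f = rank - lo
    return v[lo] * (1 - f) + v[hi] * f
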
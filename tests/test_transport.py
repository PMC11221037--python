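import numpy as np
import pytest
from scipy import stats

from irisdose.geometry import make_slab_phantom, make_water_tank
from irisdose.physics import mu_components
from irisdose.source import EnergySpectrum, generate_phase_space
from irisdose.transport import (Beam, BeamPlan, SimulationConfig,
                                deposit_electron, estimate_uncertainty,
                                reference_point_dose, run_mc,
                                sample_compton, sample_free_path,
                                sample_rayleigh_cos,
                                make_calibration_phantom, _MaterialLUT)

from oracles import klein_nishina_mean_scattered_fraction

ELECTRON_REST = 0.51099895


class TestSampleCompton:
    def test_kinematic_identity_exact(self, rng):
        e = np.exp(rng.uniform(np.log(0.02), np.log(6.0), 100_000))
        e_out, cos_t = sample_compton(e, rng)
        expected = e / (1.0 + e / ELECTRON_REST * (1.0 - cos_t))
        np.testing.assert_allclose(e_out, expected, rtol=1e-12)
        assert np.all(e_out > 0)
        assert np.all(np.abs(cos_t) <= 1.0)

    def test_low_energy_thomson_limit(self, rng):
        n = 1_000_000
        _, cos_t = sample_compton(np.full(n, 0.001), rng)
        # p(mu) ~ (1 + mu^2): mean |mu| = 9/16, symmetric mean 0
        mean_abs = np.abs(cos_t).mean()
        sd = np.sqrt(0.4 - 0.5625**2)
        assert abs(mean_abs - 0.5625) < 3 * sd / np.sqrt(n)
        sd_mu = np.sqrt(0.4)
        assert abs(cos_t.mean()) < 4 * sd_mu / np.sqrt(n)

    def test_mean_scattered_fraction_vs_quadrature(self, rng):
        n = 1_000_000
        e_out, _ = sample_compton(np.full(n, 1.0), rng)
        frac = (e_out / 1.0).mean()
        oracle = klein_nishina_mean_scattered_fraction(1.0)
        assert abs(frac - oracle) / oracle < 0.005


class TestRayleighSampling:
    def test_thomson_shape(self, rng):
        mu = sample_rayleigh_cos(500_000, rng)
        assert abs(mu.mean()) < 4 * np.sqrt(0.4 / 500_000)
        # E[mu^2] = 2/5 for p ~ (1 + mu^2)
        assert abs((mu**2).mean() - 0.4) < 0.01


class TestSampleFreePath:
    def test_homogeneous_exponential_law(self, rng):
        g = make_water_tank((400, 400, 2000), (10, 10, 10))
        lo, _ = g.bounds()
        n = 100_000
        start = np.tile([0.0, 0.0, lo[2] + 1e-3], (n, 1))
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        pos, interacted = sample_free_path(g, start, d, 1.0, rng)
        depth_cm = (pos[interacted, 2] - start[0, 2]) / 10.0
        _, _, _, mu = mu_components("water", 1.0, 1.0)
        # 2 m of water: essentially no transmission, the free-path law is
        # a clean exponential
        assert interacted.mean() > 0.99
        res = stats.kstest(depth_cm, "expon", args=(0, 1.0 / mu))
        assert res.pvalue > 0.01

    def test_two_slab_piecewise_exponential(self, rng):
        g = make_slab_phantom((200, 200, 400), (10, 10, 10),
                              [(200, None, "water"), (200, 0.26, "lung")],
                              origin_mm=(-95.0, -95.0, 5.0))
        n = 200_000
        start = np.tile([0.0, 0.0, 1e-6], (n, 1))
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        pos, interacted = sample_free_path(g, start, d, 1.0, rng)
        z = pos[interacted, 2]
        _, _, _, mu_w = mu_components("water", 1.0, 1.0)
        _, _, _, mu_l = mu_components("lung", 1.0, 0.26)
        edges = np.arange(0, 401, 25.0)

        def cdf(zz):
            zz = np.asarray(zz) / 10.0  # cm
            a = np.minimum(zz, 20.0)
            b = np.maximum(zz - 20.0, 0.0)
            return 1.0 - np.exp(-mu_w * a - mu_l * b)

        p_bins = np.diff(cdf(edges)) / cdf(400.0)
        counts, _ = np.histogram(z, bins=edges)
        n_int = counts.sum()
        expect = n_int * p_bins
        sigma = np.sqrt(n_int * p_bins * (1 - p_bins))
        # per-bin 4-sigma (Bonferroni across 16 bins)
        assert np.all(np.abs(counts - expect) <= 4 * sigma + 1)

    def test_majorant_dominates_every_voxel(self, rng):
        g = make_slab_phantom((100, 100, 100), (5, 5, 5),
                              [(30, None, "water"), (40, 0.26, "lung"),
                               (30, None, "bone")])
        lut = _MaterialLUT(g)
        lut.assert_majorant(g)
        e = np.exp(rng.uniform(np.log(0.011), np.log(6.9), 500))
        maj = lut.mu_majorant(e)
        flat_mat = g.material_id.ravel()
        flat_rho = g.density.ravel()
        for v in rng.integers(0, g.n_voxels, 50):
            mu_v = flat_rho[v] * lut.murho_total(
                np.full(len(e), flat_mat[v]), e)
            assert np.all(mu_v <= maj * (1 + 1e-12))

    def test_vacuum_grid_exits_immediately(self, rng):
        g = make_water_tank((50, 50, 50), (5, 5, 5))
        g.density[:] = 0.0
        pos, interacted = sample_free_path(
            g, np.array([[0.0, 0.0, -20.0]]),
            np.array([[0.0, 0.0, 1.0]]), 1.0, rng)
        assert not interacted[0]


class TestDepositElectron:
    def test_energy_conservation_contained_track(self, rng):
        g = make_water_tank((100, 100, 100), (2, 2, 2))
        edep = np.zeros(g.n_voxels)
        escaped = deposit_electron(np.zeros(3), np.array([0, 0, 1.0]),
                                   np.array([1.0]), 1.0, g, edep, rng)
        assert escaped == 0.0
        assert edep.sum() == pytest.approx(1.0, rel=1e-9)

    def test_deposit_within_csda_range(self, rng):
        from irisdose.physics import csda_range

        g = make_water_tank((100, 100, 100), (2, 2, 2))
        edep = np.zeros(g.n_voxels)
        n = 2000
        deposit_electron(np.zeros((n, 3)),
                         np.tile([0, 0, 1.0], (n, 1)),
                         np.full(n, 1.0), 1.0, g, edep, rng)
        r_mm = csda_range("water", 1.0, 1.0)
        centers = [g.voxel_centers_axis(a) for a in range(3)]
        xx, yy, zz = np.meshgrid(*centers, indexing="ij")
        dist = np.sqrt(xx**2 + yy**2 + zz**2).ravel()
        # 99% of the energy within the CSDA range (plus half a voxel)
        inside = edep[dist <= r_mm + 1.0].sum()
        assert inside / edep.sum() > 0.99

    def test_density_scaling_of_longitudinal_extent(self):
        def extent(density):
            g = make_water_tank((240, 240, 480), (4, 4, 4))
            g.density[:] = density
            edep = np.zeros(g.n_voxels)
            r = np.random.default_rng(7)
            n = 3000
            deposit_electron(
                np.tile([0, 0, -238.0], (n, 1)),
                np.tile([0, 0, 1.0], (n, 1)),
                np.full(n, 1.0), 1.0, g, edep, r)
            prof = edep.reshape(g.dims).sum(axis=(0, 1))
            z = g.voxel_centers_axis(2) + 238.0
            cum = np.cumsum(prof) / prof.sum()
            return np.interp(0.9, cum, z)

        ratio = extent(0.26) / extent(1.0)
        assert ratio == pytest.approx(1.0 / 0.26, rel=0.10)

    def test_escaping_energy_is_tallied(self, rng):
        g = make_water_tank((10, 10, 10), (2, 2, 2))
        edep = np.zeros(g.n_voxels)
        escaped = deposit_electron(np.zeros(3), np.array([0, 0, 1.0]),
                                   np.array([6.0]), 1.0, g, edep, rng)
        assert escaped + edep.sum() == pytest.approx(6.0, rel=1e-9)
        assert escaped > 0


@pytest.fixture(scope="module")
def mono_ps():
    spectrum = EnergySpectrum(np.array([0.999, 1.001]), np.array([1.0]))
    return generate_phase_space(spectrum, 1.0, 700.0, 50_000, seed=21)


class TestRunMC:
    def _plan(self, mu=1.0):
        return BeamPlan(beams=[Beam(isocenter=np.array([0, 0, 800.0]),
                                    direction=np.array([0, 0, 1.0]),
                                    collimator_diameter=60.0, mu=mu)])

    def test_zero_mu_gives_zero_dose(self, ps60_small):
        phantom = make_calibration_phantom(lateral_mm=100.0,
                                           depth_mm=120.0)
        cfg = SimulationConfig(histories=5000, batches=2, seed=1)
        dose = run_mc(phantom, self._plan(mu=0.0), {60.0: ps60_small}, cfg)
        assert np.all(dose.dose == 0.0)

    def test_mu_linearity_exact(self, ps60_small):
        phantom = make_calibration_phantom(lateral_mm=100.0,
                                           depth_mm=120.0)
        cfg = SimulationConfig(histories=20_000, batches=2, seed=1)
        d1 = run_mc(phantom, self._plan(mu=1.0), {60.0: ps60_small}, cfg)
        d2 = run_mc(phantom, self._plan(mu=2.0), {60.0: ps60_small}, cfg)
        np.testing.assert_allclose(d2.dose, 2.0 * d1.dose, rtol=1e-12)

    def test_missing_phase_space_raises(self, ps60_small):
        phantom = make_calibration_phantom(lateral_mm=100.0,
                                           depth_mm=120.0)
        cfg = SimulationConfig(histories=5000, batches=2, seed=1)
        plan = BeamPlan(beams=[Beam(isocenter=np.array([0, 0, 800.0]),
                                    direction=np.array([0, 0, 1.0]),
                                    collimator_diameter=25.0, mu=1.0)])
        with pytest.raises(KeyError):
            run_mc(phantom, plan, {60.0: ps60_small}, cfg)

    def test_energy_bookkeeping(self, ps60_small):
        phantom = make_calibration_phantom(lateral_mm=100.0,
                                           depth_mm=120.0)
        cfg = SimulationConfig(histories=30_000, batches=3, seed=2)
        dose = run_mc(phantom, self._plan(), {60.0: ps60_small}, cfg)
        for acc in dose.meta["energy_accounting"]:
            balance = (acc["deposited"] + acc["escaped"]) / acc["launched"]
            assert balance == pytest.approx(1.0, rel=1e-6)

    def test_subrun_consistency(self, ps60_small):
        # one long run vs two half-runs with partitioned seeds agree
        # within combined statistical error at the reference point
        phantom = make_calibration_phantom(lateral_mm=120.0,
                                           depth_mm=150.0)
        point = np.array([0.0, 0.0, 800.0])
        big = run_mc(phantom, self._plan(), {60.0: ps60_small},
                     SimulationConfig(histories=120_000, batches=6,
                                      seed=31))
        halves = [run_mc(phantom, self._plan(), {60.0: ps60_small},
                         SimulationConfig(histories=60_000, batches=3,
                                          seed=s)) for s in (32, 33)]
        ref_big, rel_big = reference_point_dose(big, point)
        vals = [reference_point_dose(h, point) for h in halves]
        mean_halves = 0.5 * (vals[0][0] + vals[1][0])
        se = np.sqrt((ref_big * rel_big) ** 2
                     + (0.5 * vals[0][0] * vals[0][1]) ** 2
                     + (0.5 * vals[1][0] * vals[1][1]) ** 2)
        assert abs(ref_big - mean_halves) < 3.5 * se

    def test_water_pdd_buildup_then_falloff(self, commissioned):
        # calibrated 60 mm beam: dose at 15 mm exceeds both the surface
        # voxel (~2 mm region, mid build-up) and 51 mm (fall-off)
        mc, _ = commissioned
        phantom = make_calibration_phantom()
        dose = mc.engine(seed=55)(phantom, self._plan())
        c = phantom.voxel_index(np.array([0, 0, 800.0]))
        prof = dose.dose[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, :].mean(
            axis=(0, 1))
        depth = phantom.voxel_centers_axis(2) - 785.0
        d15 = prof[np.argmin(np.abs(depth - 15))]
        d2 = prof[np.argmin(np.abs(depth - 3))]
        d51 = prof[np.argmin(np.abs(depth - 51))]
        assert d15 > d2
        assert d15 > d51

    def test_narrow_beam_transmission(self, rng):
        # never-scattered transmission through 100 mm water vs the
        # Beer-Lambert law
        g = make_water_tank((200, 200, 100), (5, 5, 5),
                            origin_mm=(-97.5, -97.5, 2.5))
        n = 100_000
        start = np.tile([0.0, 0.0, 1e-6], (n, 1))
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        _, interacted = sample_free_path(g, start, d, 1.0, rng)
        _, _, _, mu = mu_components("water", 1.0, 1.0)
        p_transmit = np.exp(-mu * 10.0)
        sigma = np.sqrt(p_transmit * (1 - p_transmit) / n)
        assert abs((1 - interacted.mean()) - p_transmit) < 3 * sigma


class TestEstimateUncertainty:
    def test_identical_batches_zero(self):
        bd = np.ones((4, 3, 3, 3))
        rel, scalar = estimate_uncertainty(bd)
        assert np.all(rel == 0.0)
        assert scalar == 0.0

    def test_two_batch_closed_form(self):
        bd = np.array([[[[9.0]]], [[[11.0]]]])
        rel, scalar = estimate_uncertainty(bd)
        # mean 10, std sqrt(2), SE 1 -> relative 0.1
        assert rel[0, 0, 0] == pytest.approx(0.1)
        assert scalar == pytest.approx(0.1)

    def test_requires_two_batches(self):
        with pytest.raises(ValueError):
            estimate_uncertainty(np.ones((1, 2, 2, 2)))

    def test_quadrupling_histories_halves_uncertainty(self, ps60_small):
        phantom = make_calibration_phantom(lateral_mm=120.0,
                                           depth_mm=150.0)
        plan = BeamPlan(beams=[Beam(isocenter=np.array([0, 0, 800.0]),
                                    direction=np.array([0, 0, 1.0]),
                                    collimator_diameter=60.0, mu=1.0)])
        scal = []
        for hist, seed in ((30_000, 41), (120_000, 42)):
            d = run_mc(phantom, plan, {60.0: ps60_small},
                       SimulationConfig(histories=hist, batches=6,
                                        seed=seed))
            scal.append(d.meta["average_rel_uncertainty"])
        assert scal[0] / scal[1] == pytest.approx(2.0, rel=0.20)


class TestSimulationConfigValidation:
    def test_bad_configs(self):
        with pytest.raises(ValueError):
            SimulationConfig(histories=10, batches=20)
        with pytest.raises(ValueError):
            SimulationConfig(batches=1)
        with pytest.raises(ValueError):
            SimulationConfig(photon_cutoff_mev=0.001)
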
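import numpy as np
import pytest
from dataclasses import replace

from irisdose.source import (ApertureFactors, Curve, EnergySpectrum,
                             FitDegenerateError, FluenceOCREngine,
                             PhaseSpace, RadialCorrection,
                             apply_radial_correction, collimate,
                             default_spectrum, fit_aperture_factors,
                             fit_radial_correction, generate_phase_space,
                             make_synthetic_measurements, projection_radius)


def _single_particle_ps(position, direction, weight=1.0, energy=1.0,
                        plane_z=400.0):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return PhaseSpace(energy=np.array([energy]),
                      position=np.array([position], float),
                      direction=d[None, :], weight=np.array([weight]),
                      plane_z=plane_z, collimator_diameter=60.0)


class TestGeneratePhaseSpace:
    def test_deterministic_given_seed(self, spectrum):
        a = generate_phase_space(spectrum, 1.5, 700.0, 1000, seed=5)
        b = generate_phase_space(spectrum, 1.5, 700.0, 1000, seed=5)
        np.testing.assert_array_equal(a.energy, b.energy)
        np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(a.direction, b.direction)

    def test_initial_weights_are_one(self, ps60_small):
        assert np.all(ps60_small.weight == 1.0)

    def test_energy_histogram_matches_spectrum(self, spectrum):
        n = 1_000_000
        ps = generate_phase_space(spectrum, 1.5, 700.0, n, seed=9)
        counts, _ = np.histogram(ps.energy, bins=spectrum.edges)
        expect = n * spectrum.probabilities
        sigma = np.sqrt(n * spectrum.probabilities
                        * (1 - spectrum.probabilities))
        # multinomial bounds: per-bin z at a Bonferroni-adjusted level for
        # the 30 simultaneous bins, plus a global chi-square check
        from scipy import stats
        assert np.all(np.abs(counts - expect) <= 4 * sigma + 1)
        chi2 = float(np.sum((counts - expect) ** 2 / expect))
        assert chi2 < stats.chi2.ppf(0.999, df=len(counts) - 1)

    def test_invalid_arguments(self, spectrum):
        with pytest.raises(ValueError):
            generate_phase_space(spectrum, 1.5, 700.0, 0, seed=1)

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            EnergySpectrum(np.array([1.0, 2.0]), np.array([0.5]))
        with pytest.raises(ValueError):
            EnergySpectrum(np.array([1.0, 2.0, 3.0]),
                           np.array([0.6, 0.6]))


class TestProjectionRadius:
    def test_on_axis(self):
        r = projection_radius(np.array([[0.0, 0.0]]),
                              np.array([[0.0, 0.0, 1.0]]), 400.0, 800.0)
        assert r[0] == 0.0

    def test_parallel_ray(self):
        r = projection_radius(np.array([[10.0, 0.0]]),
                              np.array([[0.0, 0.0, 1.0]]), 400.0, 800.0)
        assert r[0] == pytest.approx(10.0)

    def test_oblique_ray(self):
        tan = 0.01
        d = np.array([[tan, 0.0, 1.0]])
        d = d / np.linalg.norm(d)
        r = projection_radius(np.array([[10.0, 0.0]]), d, 400.0, 800.0)
        assert r[0] == pytest.approx(10.0 + 0.01 * 400.0, rel=1e-12)

    def test_nonpositive_axial_rejected(self):
        with pytest.raises(ValueError):
            projection_radius(np.array([[0.0, 0.0]]),
                              np.array([[1.0, 0.0, 0.0]]), 400.0)


class TestRadialCorrection:
    def test_identity_coefficients(self, ps60_small):
        out = apply_radial_correction(ps60_small,
                                      RadialCorrection.identity())
        np.testing.assert_array_equal(out.weight, ps60_small.weight)

    def test_bin_assignment(self):
        # particle projecting to 12.4 mm uses the [12, 13) coefficient
        ps = _single_particle_ps((6.2, 0.0), (6.2, 0, 400.0),
                                 plane_z=400.0)
        coeff = np.ones(60)
        coeff[12] = 2.5
        out = apply_radial_correction(ps, RadialCorrection(coeff))
        assert out.weight[0] == pytest.approx(2.5)

    def test_outside_disc_unchanged(self):
        ps = _single_particle_ps((70.0, 0.0), (0, 0, 1), plane_z=800.0)
        coeff = np.full(60, 3.0)
        out = apply_radial_correction(ps, RadialCorrection(coeff))
        assert out.weight[0] == 1.0

    def test_inverse_restores_weights(self, ps60_small, rng):
        coeff = rng.uniform(0.5, 2.0, 60)
        once = apply_radial_correction(ps60_small, RadialCorrection(coeff))
        back = apply_radial_correction(once, RadialCorrection(1.0 / coeff))
        np.testing.assert_allclose(back.weight, ps60_small.weight,
                                   rtol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            RadialCorrection(np.ones(59))
        with pytest.raises(ValueError):
            RadialCorrection(np.zeros(60))


class TestCollimate:
    def test_outside_aperture_zeroed(self):
        # non-axial particle (cosine 0.5) beyond R loses all weight
        d = np.array([np.sqrt(3) / 2, 0.0, 0.5])
        ps = _single_particle_ps((0.0, 0.0), d, plane_z=400.0)
        f = ApertureFactors(R=12.5, delta_R1=2.0, delta_R2=2.0, W1=0.4,
                            W2=0.7)
        assert collimate(ps, f).weight[0] == 0.0

    def test_axial_band_outside_gets_w1(self):
        # cosine 0.995 particle projecting into (R, R + dR1]
        d = np.array([np.sqrt(1 - 0.995**2), 0.0, 0.995])
        ps = _single_particle_ps((13.3 - d[0] / d[2] * 400.0, 0.0), d,
                                 plane_z=400.0)
        f = ApertureFactors(R=12.5, delta_R1=2.0, delta_R2=2.0, W1=0.4,
                            W2=0.7)
        r = projection_radius(ps.position, ps.direction, 400.0)
        assert 12.5 < r[0] <= 14.5
        assert collimate(ps, f).weight[0] == pytest.approx(0.4)

    def test_axial_band_inside_gets_w2(self):
        d = np.array([0.0, 0.0, 1.0])
        ps = _single_particle_ps((11.5, 0.0), d, plane_z=800.0)
        f = ApertureFactors(R=12.5, delta_R1=2.0, delta_R2=2.0, W1=0.4,
                            W2=0.7)
        assert collimate(ps, f).weight[0] == pytest.approx(0.7)

    def test_inside_all_bands_unchanged(self):
        d = np.array([np.sqrt(3) / 2, 0.0, 0.5])
        # projects close to the axis, below R - dR2
        ps = _single_particle_ps((2.0 - d[0] / d[2] * 400.0, 0.0), d,
                                 plane_z=400.0)
        f = ApertureFactors(R=12.5, delta_R1=2.0, delta_R2=2.0, W1=0.4,
                            W2=0.7)
        assert collimate(ps, f).weight[0] == 1.0

    def test_weights_nonnegative_and_total_not_increased(self, ps60_small):
        f = ApertureFactors(R=7.5, delta_R1=1.5, delta_R2=1.0, W1=0.5,
                            W2=0.8)
        out = collimate(ps60_small, f)
        assert np.all(out.weight >= 0)
        assert out.total_weight() <= ps60_small.total_weight()

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            ApertureFactors(R=5.0, delta_R2=6.0)
        with pytest.raises(ValueError):
            ApertureFactors(R=5.0, W1=-0.1)


class TestFitRadialCorrection:
    def test_fixed_point_at_identity(self, ps60_small):
        engine = FluenceOCREngine()
        measured = engine(ps60_small)
        corr, trace = fit_radial_correction(ps60_small, measured, engine)
        assert trace[-1] < 0.005
        np.testing.assert_allclose(corr.coefficients, 1.0, atol=0.02)

    def test_parameter_recovery(self, spectrum):
        # weights perturbed by known g(r); fit recovers 1/g(r)
        ps = generate_phase_space(spectrum, 1.5, 700.0, 1_000_000, seed=17)
        engine = FluenceOCREngine()
        measured = engine(ps)
        r = projection_radius(ps.position, ps.direction, ps.plane_z)
        g = 1.0 + 0.3 * np.sin(np.pi * r / 60.0)
        perturbed = replace(ps, weight=ps.weight * g)
        corr, trace = fit_radial_correction(perturbed, measured, engine)
        assert len(trace) <= 20
        centers = np.arange(60) + 0.5
        expected = 1.0 / (1.0 + 0.3 * np.sin(np.pi * centers / 60.0))
        # recovery is defined on the populated disc (the 60 mm cone fills
        # radii up to ~30 mm at the projection plane); normalization is
        # relative to the axis region
        populated = measured.y > 0
        ratio = corr.coefficients[populated] / expected[populated]
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 0.02

    def test_converged_ocr_matches_measured(self, ps60_small):
        engine = FluenceOCREngine()
        measured = engine(ps60_small)
        r = projection_radius(ps60_small.position, ps60_small.direction,
                              ps60_small.plane_z)
        perturbed = replace(ps60_small,
                            weight=ps60_small.weight * (1 + 0.2 * (r / 60)))
        tol = 0.01
        corr, trace = fit_radial_correction(perturbed, measured, engine,
                                            tol=tol)
        final = engine(apply_radial_correction(perturbed, corr))
        assert np.max(np.abs(final.y - measured.y)) < tol * 2

    def test_degenerate_region_raises(self, ps60_small):
        engine = FluenceOCREngine()
        # keep only near-axis particles: outer regions simulate zero
        r = projection_radius(ps60_small.position, ps60_small.direction,
                              ps60_small.plane_z)
        inner = replace(ps60_small,
                        weight=np.where(r < 20.0, ps60_small.weight, 0.0))
        measured = Curve(np.arange(60) + 0.5, np.ones(60))
        with pytest.raises(FitDegenerateError, match="region"):
            fit_radial_correction(inner, measured, engine)


class TestFitApertureFactors:
    def test_parameter_recovery(self, ps60_small):
        engine = FluenceOCREngine()
        true = ApertureFactors(R=12.5, delta_R1=2.0, delta_R2=2.0, W1=0.4,
                               W2=0.7)
        measured = engine(collimate(ps60_small, true))
        fitted, obj, trace = fit_aperture_factors(ps60_small, 12.5,
                                                  measured, engine)
        # RMS error below 1% of the axis value (axis value is 1)
        assert obj < 0.01
        assert abs(fitted.W1 - true.W1) < 0.1
        assert abs(fitted.W2 - true.W2) < 0.1
        objs = [t["objective"] for t in trace]
        assert all(b <= a + 1e-15 for a, b in zip(objs, objs[1:]))

    def test_hard_aperture_degenerate_case(self, ps60_small):
        engine = FluenceOCREngine()
        hard = ApertureFactors(R=14.0)  # no softening bands
        measured = engine(collimate(ps60_small, hard))
        fitted, obj, trace = fit_aperture_factors(ps60_small, 14.0,
                                                  measured, engine)
        baseline = trace[0]["objective"]
        assert obj <= baseline
        assert baseline - obj <= 1e-3 * max(baseline, 1e-12) + 1e-12

    def test_requires_small_collimator(self, ps60_small):
        engine = FluenceOCREngine()
        with pytest.raises(ValueError):
            fit_aperture_factors(ps60_small, 30.0, np.ones(60), engine)


class TestSyntheticMeasurements:
    def test_zero_perturbation_equals_forward(self, ps60_small):
        pdd, ocr = make_synthetic_measurements(
            {"phase_space": ps60_small}, {}, seed=3)
        direct = FluenceOCREngine()(ps60_small)
        np.testing.assert_allclose(ocr[100.0].y, direct.y)

    def test_deterministic(self, ps60_small):
        spec = {"noise_rel": 0.005, "smooth_sigma_mm": 2.0}
        _, a = make_synthetic_measurements({"phase_space": ps60_small},
                                           spec, seed=4)
        _, b = make_synthetic_measurements({"phase_space": ps60_small},
                                           spec, seed=4)
        np.testing.assert_array_equal(a[100.0].y, b[100.0].y)

    def test_noise_bounded_after_smoothing(self, ps60_small):
        # noise propagation: the noisy smoothed curve stays within 2% of
        # the noiseless curve under the same smoothing
        _, clean = make_synthetic_measurements(
            {"phase_space": ps60_small},
            {"smooth_sigma_mm": 2.0}, seed=5)
        _, noisy = make_synthetic_measurements(
            {"phase_space": ps60_small},
            {"noise_rel": 0.005, "smooth_sigma_mm": 2.0}, seed=5)
        dev = np.abs(noisy[100.0].y - clean[100.0].y)
        scale = np.maximum(clean[100.0].y, 0.05)
        assert np.max(dev / scale) < 0.02


class TestPhaseSpaceValidation:
    def test_bad_collimator_diameter(self):
        with pytest.raises(ValueError):
            PhaseSpace(energy=np.ones(1), position=np.zeros((1, 2)),
                       direction=np.array([[0.0, 0.0, 1.0]]),
                       weight=np.ones(1), plane_z=700.0,
                       collimator_diameter=42.0)

    def test_non_unit_direction(self):
        with pytest.raises(ValueError):
            PhaseSpace(energy=np.ones(1), position=np.zeros((1, 2)),
                       direction=np.array([[0.0, 0.0, 2.0]]),
                       weight=np.ones(1), plane_z=700.0,
                       collimator_diameter=60.0)

    def test_compact_preserves_normalization(self, ps60_small):
        f = ApertureFactors(R=7.5)
        out = collimate(ps60_small, f)
        compacted = out.compact()
        assert compacted.n_source == ps60_small.n_source
        assert np.all(compacted.weight > 0)
        assert compacted.total_weight() == pytest.approx(
            out.total_weight())
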
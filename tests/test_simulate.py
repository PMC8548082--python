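"""Multislice image formation: potentials, damage, propagation, optics, detector."""

import math

import numpy as np
import pytest
import scipy.fft as sp_fft
from scipy.optimize import brentq

from cryotwin import (
    apply_beam_damage,
    apply_detector,
    apply_optics,
    ctf_evaluate,
    electron_wavelength,
    interaction_constant,
    multislice,
    project_potential,
    simulate_tilt_series,
)
from cryotwin.config import (
    BeamModel,
    DetectorModel,
    LensModel,
    NoIce,
    ScanModel,
    SimulationConfig,
    SimulationOptions,
)
from cryotwin.sample import (
    AtomicModel,
    ParticleInstance,
    PlaneGeometry,
    Sample,
    make_phantom_particle,
    place_particles,
)
from cryotwin.scattering import gaussian_coefficients


def single_atom_sample(element="C", position=(0.0, 0.0, 0.0), depth=20.0):
    model = AtomicModel(np.array([element]), np.zeros((1, 3)), np.ones(1))
    inst = ParticleInstance("m", np.asarray(position, float),
                           np.array([1.0, 0, 0, 0]), 1.0)
    return Sample(geometry=PlaneGeometry(100, 100, depth),
                  particles=[inst], models={"m": model}, ice=NoIce())


class TestElectronWavelength:
    def test_300_kev(self):
        # h / sqrt(2 m0 e U (1 + e U / 2 m0 c^2)) evaluated independently
        assert electron_wavelength(300.0) == pytest.approx(0.01969, abs=1e-5)

    def test_100_kev(self):
        assert electron_wavelength(100.0) == pytest.approx(0.03701, abs=1e-5)

    def test_monotone_decreasing(self):
        energies = [50, 100, 200, 300, 1000]
        lams = [electron_wavelength(e) for e in energies]
        assert all(b < a for a, b in zip(lams, lams[1:]))

    def test_interaction_constant_scale(self):
        # ~0.32 rad through 100 A of 4.87 V vitreous ice at 300 keV
        phase = interaction_constant(300.0) * 4.87 * 100.0
        assert phase == pytest.approx(0.318, abs=0.01)


class TestProjectPotential:
    def test_empty_sample_all_zero(self):
        empty = Sample(geometry=PlaneGeometry(50, 50, 20), ice=NoIce())
        pot = project_potential(empty, 0.0, 32, 32)
        assert np.all(pot.slices == 0)

    def test_integrated_potential_independent_of_slice(self):
        # total projected potential is conserved wherever the atom sits in z
        totals = []
        for z in (-8.0, -2.5, 0.0, 4.0, 8.0):
            pot = project_potential(single_atom_sample(position=(0, 0, z)),
                                    0.0, 64, 64, pixel_size=1.0)
            totals.append(pot.total_projection().sum())
        assert np.ptp(totals) / np.mean(totals) < 1e-6

    def test_superposition_of_co_slice_atoms(self):
        one = project_potential(single_atom_sample(), 0.0, 64, 64)
        model = AtomicModel(np.array(["C", "C"]),
                            np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]),
                            np.ones(2))
        inst = ParticleInstance("m", np.zeros(3), np.array([1.0, 0, 0, 0]), 2.0)
        sample = Sample(geometry=PlaneGeometry(100, 100, 20),
                        particles=[inst], models={"m": model}, ice=NoIce())
        two = project_potential(sample, 0.0, 64, 64)
        assert two.total_projection().sum() == pytest.approx(
            2.0 * one.total_projection().sum(), rel=1e-6
        )

    def test_analytic_gaussian_integral(self):
        pot = project_potential(single_atom_sample(), 0.0, 128, 128,
                                pixel_size=1.0)
        amplitude, _ = gaussian_coefficients("C")
        assert pot.total_projection().sum() == pytest.approx(amplitude, rel=0.01)

    def test_atom_outside_grid_counted(self):
        sample = single_atom_sample(position=(200.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="clipped"):
            pot = project_potential(sample, 0.0, 32, 32)
        assert pot.clipped_atoms == 1


class TestBeamDamage:
    def test_zero_dose_identity(self):
        pot = project_potential(single_atom_sample(), 0.0, 64, 64)
        out = apply_beam_damage(pot, 0.0, 0.022)
        assert np.array_equal(out.slices, pot.slices)

    def test_b_factor_value(self):
        # B = 8 pi^2 D_E S_E; spot-check the filter at one frequency
        pot = project_potential(single_atom_sample(), 0.0, 64, 64)
        out = apply_beam_damage(pot, 1.0, 0.022)
        b = 8 * math.pi**2 * 1.0 * 0.022
        assert b == pytest.approx(1.737, abs=2e-3)
        q = np.hypot(*np.meshgrid(np.fft.fftfreq(64), np.fft.fftfreq(64)))
        ratio = sp_fft.fft2(out.slices.sum(axis=0)) / sp_fft.fft2(
            pot.slices.sum(axis=0)
        )
        assert np.allclose(np.abs(ratio), np.exp(-q.T**2 * b / 4), atol=1e-4)

    def test_mean_preserved_and_power_non_increasing(self):
        pot = project_potential(single_atom_sample(), 0.0, 64, 64)
        doses = [0.0, 5.0, 20.0, 80.0]
        spectra = [
            np.abs(sp_fft.fft2(apply_beam_damage(pot, d, 0.022)
                               .total_projection()))
            for d in doses
        ]
        for a, b in zip(spectra, spectra[1:]):
            assert np.all(b <= a + 1e-6)
            assert b[0, 0] == pytest.approx(a[0, 0], rel=1e-6)

    def test_analytic_damage_path_matches_fourier_filter(self):
        # widening the Gaussian kernels equals the Fourier damage filter
        dose, s_e = 30.0, 0.022
        direct = project_potential(single_atom_sample(), 0.0, 64, 64,
                                   damage_dose=dose, damage_sensitivity=s_e)
        filtered = apply_beam_damage(
            project_potential(single_atom_sample(), 0.0, 64, 64), dose, s_e
        )
        # the undamaged kernel is marginally resolved at 1 A sampling, so the
        # discretized routes differ by aliasing at the ~2% level
        peak = filtered.total_projection().max()
        assert np.allclose(direct.total_projection(),
                           filtered.total_projection(), atol=0.03 * peak)


class TestMultislice:
    def test_zero_potential_identity(self):
        empty = Sample(geometry=PlaneGeometry(50, 50, 100), ice=NoIce())
        pot = project_potential(empty, 0.0, 64, 64)
        wave = multislice(pot, BeamModel())
        assert np.allclose(np.abs(wave.psi), 1.0, atol=1e-6)

    def test_unitarity_through_100_slices(self):
        rng = np.random.default_rng(0)
        from cryotwin.simulate import PotentialSlices

        slices = rng.uniform(0, 5, size=(100, 64, 64)).astype(np.float32)
        # band-limit the potential so the anti-alias aperture removes nothing
        f = sp_fft.fft2(slices, axes=(-2, -1))
        q = np.hypot(*np.meshgrid(np.fft.fftfreq(64), np.fft.fftfreq(64)))
        f[:, q.T > 0.25] = 0
        slices = sp_fft.ifft2(f, axes=(-2, -1)).real.astype(np.float32)
        pot = PotentialSlices(slices=slices, slice_thickness=5.0,
                              pixel_size=1.0, z_origin=0.0)
        wave = multislice(pot, BeamModel(), check_aliasing=False)
        assert wave.total_intensity() / (64 * 64) == pytest.approx(1.0, abs=1e-6)

    def test_weak_phase_object_limit(self):
        # single weak slice: exit wave ~ 1 + i sigma V, deviation < 1%
        pot = project_potential(single_atom_sample(), 0.0, 128, 128,
                                slice_thickness=40.0)
        assert pot.slices.shape[0] == 1
        sigma = interaction_constant(300.0)
        scale = 0.05 / (sigma * pot.slices.max())  # cap phase at 0.05 rad
        pot.slices *= min(scale, 1.0)
        wave = multislice(pot, BeamModel(), check_aliasing=False)
        expected = 1.0 + 1j * sigma * pot.slices[0]
        # compare within the anti-alias band
        f_wave = sp_fft.fft2(wave.psi)
        f_exp = sp_fft.fft2(expected)
        q = np.hypot(*np.meshgrid(np.fft.fftfreq(128), np.fft.fftfreq(128))).T
        band = q <= 1.0 / 3.0
        dev = np.abs(f_wave - f_exp)[band].max() / np.abs(f_exp).max()
        assert dev < 0.01


class TestCTF:
    def test_envelope_unity_at_dc(self):
        ctf = ctf_evaluate(LensModel(), BeamModel(), (64, 64), 1.0)
        assert ctf.envelope[0, 0] == pytest.approx(1.0)
        assert np.all(ctf.envelope <= 1.0 + 1e-12)
        assert ctf.chi[0, 0] == 0.0

    def test_first_zero_crossing_against_root_find(self):
        lens, beam = LensModel(), BeamModel()
        lam = electron_wavelength(beam.energy)
        cs = lens.spherical_aberration * 1e7

        def chi(q):
            return math.pi * lam * lens.defocus * q**2 \
                - 0.5 * math.pi * cs * lam**3 * q**4

        q_zero = brentq(lambda q: chi(q) - math.pi, 1e-4, 0.2)
        ctf = ctf_evaluate(lens, beam, (1, 4096), 0.5)
        sin_chi = np.sin(ctf.chi[0])
        q_axis = np.fft.fftfreq(4096, d=0.5)
        pos = q_axis > 1e-4
        sign_change = np.where(np.diff(np.sign(sin_chi[pos])))[0][0]
        q_found = q_axis[pos][sign_change]
        assert q_found == pytest.approx(q_zero, rel=0.01)

    def test_ideal_phase_plate(self):
        lens = LensModel(defocus=0.0, spherical_aberration=0.0,
                         phase_plate_shift=math.pi / 2)
        ctf = ctf_evaluate(lens, BeamModel(), (64, 64), 1.0)
        assert np.allclose(np.abs(ctf.imaginary_part()), ctf.envelope)


class TestApplyOptics:
    def test_identity_transfer(self):
        from cryotwin.simulate import WaveField

        rng = np.random.default_rng(1)
        psi = (rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64)))
        ctf = ctf_evaluate(
            LensModel(defocus=0.0, spherical_aberration=0.0,
                      chromatic_aberration=0.0),
            BeamModel(energy_spread=0, voltage_spread=0, current_spread=0,
                      source_spread=0),
            (64, 64), 1.0,
        )
        wave = WaveField(psi=psi, wavelength=0.0197, pixel_size=1.0)
        img = apply_optics(wave, ctf)
        assert np.allclose(img, np.abs(psi) ** 2, rtol=1e-6, atol=1e-9)

    def test_uniform_wave_gives_uniform_image(self):
        from cryotwin.simulate import WaveField

        wave = WaveField(psi=np.ones((32, 32), complex), wavelength=0.0197,
                         pixel_size=1.0)
        ctf = ctf_evaluate(LensModel(), BeamModel(), (32, 32), 1.0)
        img = apply_optics(wave, ctf)
        assert np.allclose(img, img[0, 0])

    def test_grid_mismatch_rejected(self):
        from cryotwin.simulate import WaveField

        wave = WaveField(psi=np.ones((32, 32), complex), wavelength=0.0197,
                         pixel_size=1.0)
        ctf = ctf_evaluate(LensModel(), BeamModel(), (64, 64), 1.0)
        with pytest.raises(ValueError, match="grid"):
            apply_optics(wave, ctf)

    def test_weak_phase_image_matches_linear_imaging(self):
        # full wave-optical image of a weak phase object vs 2 sigma V sin(chi) E
        sample = single_atom_sample()
        pot = project_potential(sample, 0.0, 128, 128)
        wave = multislice(pot, BeamModel(), check_aliasing=False)
        ctf = ctf_evaluate(LensModel(), BeamModel(), (128, 128), 1.0)
        img = apply_optics(wave, ctf)
        contrast = sp_fft.fft2(img / img.mean() - 1.0)
        sigma = interaction_constant(300.0)
        pred = 2.0 * sigma * sp_fft.fft2(pot.total_projection()) \
            * ctf.imaginary_part()
        q = ctf.q
        band = (q <= 1.0 / 3.0) & (q > 0)
        dev = np.abs(contrast - pred)[band].max() / np.abs(pred[band]).max()
        assert dev < 0.02


class TestDetector:
    def test_zero_dose_all_zero(self):
        det = DetectorModel(nx=32, ny=32, pixel_size=1.0)
        out = apply_detector(np.ones((32, 32)), det, 0.0)
        assert np.all(out == 0)

    def test_poisson_mean_and_variance(self):
        det = DetectorModel(nx=128, ny=128, pixel_size=1.0, dqe0=1.0,
                            dqe_falloff=0.0)
        rng = np.random.default_rng(7)
        counts = apply_detector(np.ones((128, 128)), det, 100.0, rng)
        # >= 10^4 pixels of iid Poisson(100)
        assert counts.mean() == pytest.approx(100.0, rel=0.01)
        assert counts.var() == pytest.approx(100.0, rel=0.05)

    def test_dqe0_scales_expectation(self):
        det = DetectorModel(nx=64, ny=64, pixel_size=1.0, dqe0=0.5,
                            dqe_falloff=0.0)
        expected = apply_detector(np.ones((64, 64)), det, 100.0, poisson=False)
        assert np.allclose(expected, 50.0)

    def test_fixed_seed_bit_identical(self):
        det = DetectorModel(nx=32, ny=32, pixel_size=1.0)
        a = apply_detector(np.ones((32, 32)), det, 10.0,
                           np.random.default_rng(3))
        b = apply_detector(np.ones((32, 32)), det, 10.0,
                           np.random.default_rng(3))
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def small_setup():
    phantom = make_phantom_particle(1, 200, 15.0)
    geo = PlaneGeometry(120, 120, 60)
    sample = place_particles(geo, {"m": phantom},
                             [{"model_id": "m", "count": 1}], ice=NoIce())
    config = SimulationConfig(
        beam=BeamModel(flux=10.0),
        detector=DetectorModel(nx=64, ny=64, pixel_size=2.0),
        scan=ScanModel(max_tilt=60.0, mode="fixed_count", num_images=5,
                       exposure=1.0),
        simulation=SimulationOptions(pixel_size=2.0, seed=11),
    )
    return config, sample


class TestSimulateTiltSeries:

    def test_image_count_and_angles(self, small_setup):
        config, sample = small_setup
        ts = simulate_tilt_series(config, sample)
        assert ts.n_images == 5
        assert sorted(ts.angles) == pytest.approx([-60, -30, 0, 30, 60])

    def test_dose_bookkeeping(self, small_setup):
        config, sample = small_setup
        ts = simulate_tilt_series(config, sample)
        d = config.beam.flux * config.scan.exposure
        assert np.allclose(ts.accumulated_dose,
                           d * np.arange(1, ts.n_images + 1))
        assert np.all(np.diff(ts.accumulated_dose) > 0)

    def test_total_dose_invariant_under_fractionation(self, small_setup):
        config, sample = small_setup
        cfg2 = config.model_copy(deep=True)
        cfg2.scan.num_images = 10
        cfg2.scan.exposure = 0.5  # same total dose over twice the images
        ts1 = simulate_tilt_series(config, sample)
        ts2 = simulate_tilt_series(cfg2, sample)
        assert ts2.dose_per_image == pytest.approx(ts1.dose_per_image / 2)
        assert ts2.accumulated_dose[-1] == pytest.approx(
            ts1.accumulated_dose[-1]
        )

    def test_deterministic_per_seed(self, small_setup):
        config, sample = small_setup
        a = simulate_tilt_series(config, sample)
        b = simulate_tilt_series(config, sample)
        assert np.array_equal(a.images, b.images)

    def test_mrc_round_trip_with_metadata(self, small_setup, tmp_path):
        from cryotwin import TiltSeries

        config, sample = small_setup
        ts = simulate_tilt_series(config, sample)
        path = tmp_path / "stack.mrc"
        ts.to_mrc(str(path))
        loaded = TiltSeries.from_mrc(str(path))
        assert np.allclose(loaded.images, ts.images)
        assert np.allclose(loaded.angles, ts.angles, atol=1e-5)
        assert np.allclose(loaded.accumulated_dose, ts.accumulated_dose,
                           rtol=1e-6)
        assert loaded.pixel_size == pytest.approx(ts.pixel_size)


class TestBeamDrift:
    def test_drift_shifts_the_projection(self):
        sample = single_atom_sample()
        still = project_potential(sample, 0.0, 64, 64).total_projection()
        moved = project_potential(sample, 0.0, 64, 64,
                                  translation=(6.0, -4.0)).total_projection()
        # the atom peak moves by the drift offset, in pixels
        p0 = np.unravel_index(still.argmax(), still.shape)
        p1 = np.unravel_index(moved.argmax(), moved.shape)
        assert p1[1] - p0[1] == 6
        assert p1[0] - p0[0] == -4

    def test_sinusoidal_drift_deterministic(self, small_setup):
        config, sample = small_setup
        cfg = config.model_copy(deep=True)
        cfg.beam.drift.kind = "sinusoidal"
        cfg.beam.drift.amplitude = 5.0
        a = simulate_tilt_series(cfg, sample)
        b = simulate_tilt_series(cfg, sample)
        assert np.array_equal(a.images, b.images)
        # drift changes the images relative to the drift-free series
        base = simulate_tilt_series(config, sample)
        assert not np.array_equal(a.images, base.images)


class TestPlanarAttenuation:
    def test_exit_intensity_decreases_with_tilt(self):
        # thicker projected ice at tilt scatters more electrons out of the
        # aperture: mean exit intensity is monotone decreasing in |tilt|
        from cryotwin.config import GRFIce

        geo = PlaneGeometry(400, 80, 100)
        sample = Sample(
            geometry=geo,
            ice=GRFIce(mean=4.87, variance=3000.0, correlation_length=0.25,
                       seed=0),
        )
        means = []
        for tilt in (0.0, 30.0, 50.0, 65.0):
            pot = project_potential(
                sample, tilt, 128, 32, pixel_size=2.0,
                ice_rng=np.random.default_rng(1),
            )
            wave = multislice(pot, BeamModel(), check_aliasing=False)
            centre = wave.intensity()[:, 54:74]
            means.append(centre.mean())
        assert all(b < a for a, b in zip(means, means[1:]))
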
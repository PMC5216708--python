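"""Ground-truth properties of the point-scatterer RF simulator."""

import numpy as np
import pytest
from scipy.signal import hilbert

import qustools as q
from qustools.simulate import gaussian_form_factor


class TestSampleField:
    def test_poisson_count_matches_expectation(self):
        medium = q.MediumSpec(number_density=5.0)
        # 10 x 10 mm plane, 2 mm elevational slab -> 200 mm^3 -> ~1000 scatterers
        field = q.sample_field(medium, (0.0, 0.01), 0.01, seed=4, elevation_mm=2.0)
        assert abs(field.axial.size - 1000) < 160  # ~5 sigma of Poisson(1000)

    def test_same_spec_and_seed_is_reproducible(self):
        medium = q.MediumSpec(regular_spacing_mm=1.0, regular_fraction=2.0)
        f1 = q.sample_field(medium, (0.0, 0.02), 0.01, seed=9)
        f2 = q.sample_field(medium, (0.0, 0.02), 0.01, seed=9)
        np.testing.assert_array_equal(f1.axial, f2.axial)
        np.testing.assert_array_equal(f1.amplitude, f2.amplitude)

    def test_lattice_count_matches_spacing(self):
        medium = q.MediumSpec(
            number_density=1.0, regular_spacing_mm=1.0, regular_fraction=2.0
        )
        field = q.sample_field(medium, (0.0, 0.01), 0.25e-3, seed=1, elevation_mm=1.0)
        lattice = field.amplitude == field.amplitude.max()
        # ~10 lattice scatterers over 10 mm depth in the single column
        assert 8 <= np.sum(lattice) <= 12

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            q.sample_field(q.MediumSpec(number_density=0.001), (0.0, 1e-4), 1e-4, 0)


class TestSynthesizeRF:
    def test_zero_attenuation_gives_depth_flat_rms(self, acq, pulse):
        medium = q.MediumSpec(attenuation=0.0)
        frame = q.simulate_medium_frame(medium, acq, 11, pulse=pulse, snr_db=None)
        seg = frame.samples[:, 400:1600].reshape(frame.n_lines, 4, 300)
        rms = np.sqrt(np.mean(seg**2, axis=(0, 2)))
        spread_db = 20 * np.log10(rms.max() / rms.min())
        assert spread_db < 1.0

    def test_attenuation_law_matches_band_integrated_oracle(self, acq, pulse):
        """Measured depth-loss equals the closed-form attenuation law integrated
        over the echo band (power from depth z loses 2*alpha*f*z dB)."""
        alpha = 1.0
        medium = q.MediumSpec(attenuation=alpha, scatterer_radius_um=25.0)
        flat = q.MediumSpec(attenuation=0.0, scatterer_radius_um=25.0)
        z1, z2 = 1.0, 2.0  # cm

        def band_power(frame, z_cm):
            j = int(round((z_cm / 100) / frame.axial_step))
            seg = frame.samples[:, j - 100 : j + 100]
            spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2
            f = np.fft.rfftfreq(seg.shape[1], 1 / frame.sampling_rate) / 1e6
            m = (f >= 3) & (f <= 8)
            return spec[:, m].mean()

        # oracle: model power spectrum S(f) ~ f^4 F(f) |P(f)|^2 under the law
        f = np.linspace(3e6, 8e6, 200)
        S = (
            (f / 1e6) ** 4
            * gaussian_form_factor(f, 25.0, 1540.0)
            * np.exp(-((f - pulse.center_frequency) ** 2) / pulse.sigma_f**2)
        )
        def model_band_power(z_cm):
            return np.sum(S * 10 ** (-2 * alpha * (f / 1e6) * z_cm / 10))

        expected_db = 10 * np.log10(model_band_power(z1) / model_band_power(z2))

        diffs = []
        for seed in range(5):
            fa = q.simulate_medium_frame(medium, acq, 300 + seed, pulse=pulse, snr_db=None)
            f0 = q.simulate_medium_frame(flat, acq, 300 + seed, pulse=pulse, snr_db=None)
            # difference of differences removes speckle-realization variance
            meas = 10 * np.log10(band_power(fa, z1) / band_power(fa, z2))
            ctrl = 10 * np.log10(band_power(f0, z1) / band_power(f0, z2))
            diffs.append(meas - ctrl)
        assert abs(np.mean(diffs) - expected_db) < 1.0

    def test_zero_scatterers_gives_noise_floor_frame(self, acq, pulse):
        field = q.simulate.ScattererField(
            axial=np.array([]), lateral=np.array([]), amplitude=np.array([]),
            medium=q.MediumSpec(), seed=0,
        )
        frame = q.synthesize_rf(field, pulse, acq, snr_db=40.0)
        rms = np.sqrt(np.mean(frame.samples**2))
        assert 0 < rms < 0.1  # pure electronic noise at the SNR floor

    def test_aliasing_guard(self, acq):
        hot = q.PulseSpec(center_frequency=18e6, fractional_bandwidth=1.0)
        medium = q.MediumSpec()
        field = q.sample_field(medium, (0.0, 0.01), 0.005, 1)
        with pytest.raises(ValueError, match="Nyquist"):
            q.synthesize_rf(field, hot, acq)


class TestReference:
    def test_reference_speckle_is_fully_developed(self, reference_frames):
        """Envelope SNR (mean/SD) of the homogeneous reference phantom matches
        the Rayleigh value 1.91 after removing the slow depth trend."""
        env = np.abs(hilbert(reference_frames[0].samples[:, 500:1400], axis=1))
        profile = np.convolve(env.mean(axis=0), np.ones(101) / 101, mode="same")
        flat = (env / profile)[:, 60:-60]
        snr = flat.mean() / flat.std()
        assert abs(snr - 1.91) < 0.08

    def test_same_seed_same_frame(self, acq, pulse):
        a = q.synthesize_reference(acq, 5, pulse=pulse)
        b = q.synthesize_reference(acq, 5, pulse=pulse)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestPlanarReflector:
    def test_echo_arrival_sample_matches_delay_formula(self, acq, pulse):
        depth = 3.0
        frame = q.synthesize_planar_reflector(acq, depth, pulse=pulse)
        expected = 2 * (depth / 100) / 1540.0 * acq.sampling_rate
        peak = np.argmax(np.abs(frame.samples[0]))
        assert abs(peak - expected) <= 2

    def test_depth_outside_bank_range_rejected(self, acq, pulse):
        with pytest.raises(ValueError):
            q.synthesize_planar_reflector(acq, 0.5, pulse=pulse)
        with pytest.raises(ValueError):
            q.synthesize_planar_reflector(acq, 7.0, pulse=pulse)

    def test_bank_covers_six_depths(self, reflector_bank_frames):
        assert sorted(reflector_bank_frames) == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]

    def test_gated_echo_spectrum_peaks_at_pulse_center(self, acq, pulse):
        frame = q.synthesize_planar_reflector(acq, 2.0, pulse=pulse)
        from qustools.spacing import reflector_spectrum_bank

        spec = reflector_spectrum_bank({2.0: frame})[2.0]
        m = spec.band_mask((3.0, 9.0))
        peak_f = spec.frequencies_mhz[m][np.argmax(spec.power_db[m])]
        assert abs(peak_f - 6.0) < 0.5


class TestAnalyticBSC:
    def test_rayleigh_limit_is_f4(self):
        medium = q.MediumSpec(scatterer_radius_um=0.01)
        f = np.array([3.0, 6.0])
        b = q.analytic_bsc(medium, f)
        assert b[1] / b[0] == pytest.approx(2.0**4, rel=1e-6)

    def test_log_bsc_over_f4_is_linear_in_f2_with_exact_slope(self):
        medium = q.MediumSpec(scatterer_radius_um=30.0, sound_speed=1540.0)
        f = np.linspace(3, 8, 40)
        y = np.log(q.analytic_bsc(medium, f)) - 4 * np.log(f)
        slope, _ = np.polyfit(f**2, y, 1)
        expected = -0.827 * (2 * np.pi * 1e6 / 1540.0 * 30e-6) ** 2
        assert slope == pytest.approx(expected, rel=1e-10)

    def test_doubling_density_doubles_bsc(self):
        f = np.linspace(3, 8, 10)
        b1 = q.analytic_bsc(q.MediumSpec(number_density=50.0), f)
        b2 = q.analytic_bsc(q.MediumSpec(number_density=100.0), f)
        np.testing.assert_allclose(b2, 2 * b1, rtol=1e-12)
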
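"""Spectral estimation: periodograms, normalization, ACE, linear fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qustools as q
from qustools.spectral import Spectrum


def make_spectrum(power_db, fmin=2.0, fmax=10.0, depth=1.5):
    f = np.linspace(fmin, fmax, 161)
    p = np.broadcast_to(power_db, f.shape).astype(float) if np.isscalar(power_db) else power_db(f)
    return Spectrum(frequencies_mhz=f, power_db=np.asarray(p, float), center_depth_cm=depth)


class TestBlockPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs = 40e6
        t = np.arange(512) / fs
        block = np.tile(np.sin(2 * np.pi * 5e6 * t), (4, 1))
        spec = q.block_power_spectrum(block, sampling_rate=fs)
        peak = spec.frequencies_mhz[np.argmax(spec.power_db)]
        assert abs(peak - 5.0) < 0.1

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        spec = q.block_power_spectrum(rng.normal(size=(200, 256)), sampling_rate=40e6)
        m = spec.band_mask((2.0, 18.0))
        assert spec.power_db[m].max() - spec.power_db[m].min() < 2.0

    def test_parseval_total_power_equals_time_domain_energy(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 128))
        spec = q.block_power_spectrum(data, sampling_rate=40e6)
        n_fft = 2 * (spec.frequencies_mhz.size - 1)
        win = np.hanning(data.shape[1])
        weights = np.full(spec.frequencies_mhz.size, 2.0)
        weights[0] = weights[-1] = 1.0
        total_freq = np.sum(weights * spec.linear_power())
        total_time = n_fft * np.mean(np.sum((data * win) ** 2, axis=1)) / np.sum(win**2)
        assert total_freq == pytest.approx(total_time, rel=1e-9)

    def test_single_line_block_rejected(self):
        with pytest.raises(ValueError):
            q.block_power_spectrum(np.zeros((1, 128)), sampling_rate=40e6)

    def test_frequency_resolution_fine_enough(self):
        spec = q.block_power_spectrum(np.zeros((2, 104)) + 1e-6, sampling_rate=40e6)
        assert np.diff(spec.frequencies_mhz)[0] <= 0.1


class TestNormalize:
    def test_identical_spectra_give_zero_dbr(self):
        s = make_spectrum(-25.0)
        out = q.normalize_spectrum(s, s)
        np.testing.assert_allclose(out.power_db, 0.0)

    def test_constant_offset_preserved(self):
        s = make_spectrum(-19.0)
        r = make_spectrum(-25.0)
        np.testing.assert_allclose(q.normalize_spectrum(s, r).power_db, 6.0)

    def test_grid_mismatch_rejected(self):
        s = make_spectrum(-10.0)
        r = make_spectrum(-10.0, fmin=1.0)
        with pytest.raises(ValueError):
            q.normalize_spectrum(s, r)


class TestEstimateACE:
    @staticmethod
    def analytic_blocks(alpha, alpha_ref, depths, base=lambda f: -10.0 + 0 * f):
        """Noiseless sample/reference spectra built from the attenuation law:
        power-dB at depth z loses 2*alpha*f*z dB."""
        samp, ref = [], []
        for z in depths:
            samp.append(make_spectrum(lambda f, z=z: base(f) - 2 * alpha * f * z, depth=z))
            ref.append(make_spectrum(lambda f, z=z: base(f) - 2 * alpha_ref * f * z, depth=z))
        return samp, ref

    def test_exact_on_noiseless_analytic_spectra(self):
        samp, ref = self.analytic_blocks(1.0, 0.15, [1.0, 1.5, 2.0, 2.5])
        ace = q.estimate_ace(samp, ref, band_mhz=(3, 8), alpha_ref=0.15)
        assert ace == pytest.approx(1.0, abs=1e-9)

    def test_sample_matching_reference_returns_alpha_ref(self):
        samp, ref = self.analytic_blocks(0.15, 0.15, [1.0, 1.4, 1.8])
        ace = q.estimate_ace(samp, ref, alpha_ref=0.15)
        assert ace == pytest.approx(0.15, abs=1e-9)

    def test_depth_independent_normalized_amplitude_returns_alpha_ref(self):
        samp, ref = self.analytic_blocks(0.0, 0.0, [1.0, 1.5, 2.0])
        assert q.estimate_ace(samp, ref, alpha_ref=0.15) == pytest.approx(0.15, abs=1e-9)

    def test_too_few_depths_rejected(self):
        samp, ref = self.analytic_blocks(1.0, 0.15, [1.0, 1.5])
        with pytest.raises(ValueError, match="shallow"):
            q.estimate_ace(samp, ref)


class TestAttenuationCorrect:
    def test_zero_model_is_identity(self):
        s = make_spectrum(-12.0, depth=0.0)
        model = q.AttenuationModel(alpha0=0.0, x0_cm=0.0, alpha1=0.0, x1_cm=0.0)
        np.testing.assert_allclose(q.attenuation_correct(s, model).power_db, s.power_db)

    def test_one_cm_at_one_db_adds_two_db_per_mhz_tilt(self):
        s = make_spectrum(-10.0, depth=1.0)
        model = q.AttenuationModel(alpha0=0.0, x0_cm=0.0, alpha1=1.0, x1_cm=1.0)
        out = q.attenuation_correct(s, model)
        before = q.fit_spectral_line(s)
        after = q.fit_spectral_line(out)
        assert after.ss_dbr_mhz - before.ss_dbr_mhz == pytest.approx(2.0, abs=1e-9)

    def test_inconsistent_path_rejected(self):
        s = make_spectrum(-10.0, depth=2.0)
        model = q.AttenuationModel(alpha0=1.0, x0_cm=0.5, alpha1=0.5, x1_cm=0.5)
        with pytest.raises(ValueError, match="inconsistent"):
            q.attenuation_correct(s, model)

    def test_correcting_with_true_alpha_recovers_unattenuated_fit(self):
        base = lambda f: -5.0 - 0.8 * f
        z = 2.0
        attenuated = make_spectrum(lambda f: base(f) - 2 * 0.7 * f * z, depth=z)
        model = q.AttenuationModel(alpha0=0.7, x0_cm=z, alpha1=0.0, x1_cm=0.0)
        fit = q.fit_spectral_line(q.attenuation_correct(attenuated, model))
        ref_fit = q.fit_spectral_line(make_spectrum(base, depth=z))
        assert fit.ss_dbr_mhz == pytest.approx(ref_fit.ss_dbr_mhz, abs=1e-9)
        assert fit.mbf_dbr == pytest.approx(ref_fit.mbf_dbr, abs=1e-9)


class TestSpectralLineFit:
    def test_flat_spectrum(self):
        fit = q.fit_spectral_line(make_spectrum(-10.0))
        assert fit.ss_dbr_mhz == pytest.approx(0.0, abs=1e-12)
        assert fit.si_dbr == pytest.approx(-10.0, abs=1e-9)
        assert fit.mbf_dbr == pytest.approx(-10.0, abs=1e-9)

    def test_exact_line_recovered(self):
        fit = q.fit_spectral_line(make_spectrum(lambda f: 2 * f - 5))
        assert fit.ss_dbr_mhz == pytest.approx(2.0, abs=1e-9)
        assert fit.si_dbr == pytest.approx(-5.0, abs=1e-9)
        assert fit.mbf_dbr == pytest.approx(6.0, abs=1e-9)  # at 5.5 MHz
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        f = np.linspace(2, 10, 161)
        y = 1.3 * f - 7.0 + rng.normal(0, 2.0, f.size)
        spec = Spectrum(frequencies_mhz=f, power_db=y)
        fit = q.fit_spectral_line(spec, (3.0, 8.0))
        m = (f >= 3) & (f <= 8)
        X = np.column_stack([np.ones(m.sum()), f[m]])
        beta = np.linalg.solve(X.T @ X, X.T @ y[m])
        assert fit.si_dbr == pytest.approx(beta[0], abs=1e-9)
        assert fit.ss_dbr_mhz == pytest.approx(beta[1], abs=1e-9)

    @given(
        slope=st.floats(-5, 5),
        intercept=st.floats(-40, 10),
        noise_seed=st.integers(0, 1000),
    )
    def test_mbf_identity_holds_for_any_fit(self, slope, intercept, noise_seed):
        """MBF == SI + SS * f_center to machine precision, whatever the data."""
        rng = np.random.default_rng(noise_seed)
        f = np.linspace(2, 10, 81)
        y = slope * f + intercept + rng.normal(0, 3, f.size)
        fit = q.fit_spectral_line(Spectrum(frequencies_mhz=f, power_db=y), (3.0, 8.0))
        assert fit.mbf_dbr == pytest.approx(
            fit.si_dbr + fit.ss_dbr_mhz * 5.5, abs=1e-9
        )

    def test_too_few_points_rejected(self):
        spec = Spectrum(frequencies_mhz=np.array([5.0]), power_db=np.array([0.0]))
        with pytest.raises(ValueError):
            q.fit_spectral_line(spec, (3.0, 8.0))
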
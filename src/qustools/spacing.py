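"""Mean scatterer spacing (SAS) from AR-modeled, planar-reflector-normalized spectra.

Coherent (regularly spaced) scatterers imprint a periodic ripple of period
``delta_f = c / (2 d)`` on the backscatter power spectrum.  The spacing-among-
scatterers estimator therefore:

1. models each gated RF segment with a high-order autoregressive (AR) process
   fitted by Burg's recursion (default order 50) — AR spectra give more
   conspicuous ripple peaks than the FFT periodogram at 2 mm gate lengths;
2. normalizes the AR power spectrum (dB subtraction) by the spectrum of a
   planar-reflector recording at the nearest of six reference depths
   (1-6 cm), removing the system's spectral shape;
3. locates the dominant peak of the spectral autocorrelation of the
   normalized, mean-subtracted linear power over a search window of frequency
   lags, giving SAS = c / (2 * delta_f_peak) in mm.

Blocks whose autocorrelation has no local maximum in the window yield a
missing value (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rf import RFFrame
from .spectral import ANALYSIS_BAND_MHZ, Spectrum

__all__ = [
    "ARSpectrum",
    "burg_ar",
    "burg_coefficients",
    "ar_power_spectrum",
    "planar_normalize",
    "reflector_spectrum_bank",
    "estimate_sas",
    "DEFAULT_AR_ORDER",
    "DEFAULT_SAS_SEARCH_MHZ",
]

DEFAULT_AR_ORDER = 50
DEFAULT_SAS_SEARCH_MHZ = (0.2, 2.5)
#: FFT length for AR / reflector spectra (grid step ~0.02 MHz at 40 MHz).
_SAS_NFFT = 2048


@dataclass
class ARSpectrum:
    """Burg AR model of a gated RF segment and its implied power spectrum."""

    ar_coefficients: np.ndarray  # a[1..p]; polynomial A(z) = 1 + sum a_k z^-k
    noise_variance: float
    order: int
    sampling_rate: float

    def power_spectrum(self, n_fft: int = _SAS_NFFT, center_depth_cm: float = 0.0) -> Spectrum:
        return ar_power_spectrum(
            self.ar_coefficients[None, :],
            np.array([self.noise_variance]),
            self.sampling_rate,
            n_fft=n_fft,
            center_depth_cm=center_depth_cm,
        )


def burg_coefficients(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg's recursion, vectorized over rows.

    Parameters
    ----------
    x
        Array of shape ``(..., n)``: each row an independent signal.
    order
        AR model order ``p``; requires ``n > 2 * p`` for stable estimates
        (hard error when ``p >= n``).

    Returns
    -------
    a, E
        ``a`` of shape ``(..., p)`` holding coefficients a_1..a_p of
        ``A(z) = 1 + sum_k a_k z^-k`` (minimizing forward+backward prediction
        error; all reflection coefficients lie in (-1, 1) by construction),
        and ``E`` the final prediction-error variance per row.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    if order >= n:
        raise ValueError(f"AR order ({order}) must be smaller than the signal length ({n})")
    lead = x.shape[:-1]
    f = x.copy()
    b = x.copy()
    a = np.ones(lead + (1,))
    E = np.mean(x**2, axis=-1)
    for m in range(order):
        fm = f[..., m + 1 :]
        bm = b[..., m : n - 1]
        den = np.sum(fm**2, axis=-1) + np.sum(bm**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = -2.0 * np.sum(fm * bm, axis=-1) / den
        k = np.where(den > 0, k, 0.0)
        a = np.concatenate([a, np.zeros(lead + (1,))], axis=-1)
        a = a + k[..., None] * a[..., ::-1]
        f_new = fm + k[..., None] * bm
        b_new = bm + k[..., None] * fm
        f[..., m + 1 :] = f_new
        b[..., m + 1 : n] = b_new
        E = E * (1.0 - k**2)
    return a[..., 1:], E


def burg_ar(signal: np.ndarray, order: int = DEFAULT_AR_ORDER, sampling_rate: float = 40e6) -> ARSpectrum:
    """Fit a single gated RF line segment with a Burg AR model."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("burg_ar expects a 1-D gated segment; use burg_coefficients for batches")
    a, E = burg_coefficients(signal[None, :], order)
    return ARSpectrum(
        ar_coefficients=a[0], noise_variance=float(E[0]), order=order, sampling_rate=sampling_rate
    )


def ar_power_spectrum(
    a: np.ndarray,
    noise_variance: np.ndarray,
    sampling_rate: float,
    n_fft: int = _SAS_NFFT,
    center_depth_cm: float = 0.0,
) -> Spectrum:
    """Mean AR power spectrum of a batch of models: P(f) = E / |A(e^-jw)|^2.

    Rows are averaged in linear power (lines of a block are averaged at this
    stage), and the result is returned in dB on the shared rfft grid.
    """
    a = np.atleast_2d(a)
    poly = np.concatenate([np.ones((a.shape[0], 1)), a], axis=-1)
    A = np.fft.rfft(poly, n=n_fft, axis=-1)
    power = np.asarray(noise_variance)[:, None] / np.abs(A) ** 2
    mean_power = power.mean(axis=0)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate) / 1e6
    return Spectrum(
        frequencies_mhz=freqs,
        power_db=10.0 * np.log10(mean_power),
        center_depth_cm=center_depth_cm,
    )


def reflector_spectrum_bank(
    frames: dict[float, RFFrame],
    gate_half_mm: float = 2.0,
    n_fft: int = _SAS_NFFT,
) -> dict[float, Spectrum]:
    """Periodogram spectra of planar-reflector frames, gated around each echo.

    Keys are depths in cm.  The gate is centered on the peak-envelope sample
    and the periodogram is evaluated on the same grid as the AR spectra.
    """
    bank: dict[float, Spectrum] = {}
    for depth_cm, frame in frames.items():
        mean_line = frame.samples.mean(axis=0)
        peak = int(np.argmax(np.abs(mean_line)))
        half = frame.mm_to_samples(gate_half_mm)
        lo, hi = max(0, peak - half), min(frame.n_samples, peak + half)
        gated = frame.samples[:, lo:hi]
        # periodogram on the fixed SAS grid (shared with the AR spectra)
        win = np.hanning(gated.shape[1])
        fft = np.fft.rfft(gated * win, n=n_fft, axis=-1)
        power = np.mean(np.abs(fft) ** 2, axis=0) / np.sum(win**2)
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / frame.sampling_rate) / 1e6
        bank[depth_cm] = Spectrum(
            frequencies_mhz=freqs, power_db=10.0 * np.log10(power), center_depth_cm=depth_cm
        )
    return bank


def planar_normalize(
    spec: Spectrum, block_depth_cm: float, reflector_bank: dict[float, Spectrum]
) -> Spectrum:
    """Subtract (dB) the planar-reflector spectrum nearest in depth to the block.

    Exact distance ties are broken toward the shallower reference depth.
    """
    if not reflector_bank:
        raise ValueError("reflector bank is empty")
    depths = sorted(reflector_bank)
    dist = [abs(d - block_depth_cm) for d in depths]
    best = depths[int(np.argmin(dist))]  # argmin returns first minimum -> shallower on ties
    ref = reflector_bank[best]
    if spec.frequencies_mhz.shape != ref.frequencies_mhz.shape or not np.allclose(
        spec.frequencies_mhz, ref.frequencies_mhz
    ):
        raise ValueError("spectrum and reflector bank must share a frequency grid")
    return Spectrum(
        frequencies_mhz=spec.frequencies_mhz,
        power_db=spec.power_db - ref.power_db,
        center_depth_cm=block_depth_cm,
    )


def estimate_sas(
    norm_spec: Spectrum,
    sound_speed: float = 1540.0,
    search_mhz: tuple[float, float] = DEFAULT_SAS_SEARCH_MHZ,
    band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ,
) -> float:
    """Spacing among scatterers (mm) from the spectral autocorrelation peak.

    The normalized spectrum is converted to linear power over the analysis
    band, mean-subtracted, and autocorrelated over frequency lag.  The
    dominant local maximum at lag ``delta_f`` within the search window
    (default 0.2-2.5 MHz; lags closer than two grid cells to zero are always
    excluded) gives ``SAS = c / (2 delta_f)``.  Returns NaN when no local
    maximum exists in the window.
    """
    f_all = norm_spec.frequencies_mhz
    if f_all.min() > band_mhz[0] + 0.25 or f_all.max() < band_mhz[1] - 0.25:
        raise ValueError("normalized spectrum must cover the analysis band")
    m = norm_spec.band_mask(band_mhz)
    if m.sum() < 8:
        raise ValueError("normalized spectrum must cover the analysis band")
    power = 10.0 ** (norm_spec.power_db[m] / 10.0)
    power = power - power.mean()
    ac = np.correlate(power, power, mode="full")[power.size - 1 :]
    if ac[0] <= 0:
        return float("nan")
    ac = ac / ac[0]
    df = float(np.mean(np.diff(norm_spec.frequencies_mhz[m])))
    lags = df * np.arange(ac.size)

    lo = max(search_mhz[0], 2.0 * df)
    hi = search_mhz[1]
    interior = (ac[1:-1] > ac[:-2]) & (ac[1:-1] >= ac[2:])
    peak_idx = np.flatnonzero(interior) + 1
    peak_idx = peak_idx[(lags[peak_idx] >= lo) & (lags[peak_idx] <= hi)]
    if peak_idx.size == 0:
        return float("nan")
    best = peak_idx[np.argmax(ac[peak_idx])]
    delta_f_hz = lags[best] * 1e6
    return float(sound_speed / (2.0 * delta_f_hz) * 1e3)
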
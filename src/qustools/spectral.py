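"""Block power spectra, reference normalization, attenuation and linear spectral fits.

This module carries the spectral half of the QUS parameter set:

* ``block_power_spectrum`` — Hann-windowed, line-averaged periodogram of a
  2 x 2 mm RF block, in dB.
* ``normalize_spectrum`` — reference-phantom normalization (dB subtraction),
  which cancels the system transfer function and diffraction effects.
* ``estimate_ace`` — attenuation coefficient estimate via the reference-phantom
  (spectral-difference) method: the rate of change of the normalized spectral
  magnitude with depth and frequency against a reference of known attenuation.
* ``attenuation_correct`` — point attenuation compensation with a two-segment
  path model A(f) = (alpha0*x0 + alpha1*x1) * f (intervening tissue +
  intratumoral path).
* ``fit_spectral_line`` — ordinary least squares of the corrected, normalized
  spectrum over the usable band, yielding spectral slope (SS), spectral
  intercept (SI) and midband fit (MBF = SI + SS * f_center).

dB convention: all power spectra are 10*log10(power).  A one-way amplitude
attenuation of ``alpha`` dB/cm-MHz removes ``2 * alpha * f * z`` dB from the
power spectrum of an echo from depth z (round-trip path 2z; amplitude dB and
power dB coincide numerically).  Consequently depth-slope fits are performed on
power-dB and converted with the round-trip factor 2 in ``estimate_ace``, and
``attenuation_correct`` adds ``2 * A(f)`` dB with ``A(f)`` the one-way
amplitude loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rf import RFBlock

__all__ = [
    "Spectrum",
    "AttenuationModel",
    "SpectralFit",
    "ANALYSIS_BAND_MHZ",
    "block_power_spectrum",
    "normalize_spectrum",
    "estimate_ace",
    "attenuation_correct",
    "equalize_attenuation",
    "fit_spectral_line",
]

#: Usable (-6 dB) analysis band of the 6 MHz transducer, MHz.
ANALYSIS_BAND_MHZ = (3.0, 8.0)


@dataclass
class Spectrum:
    """Power vs frequency in dB (10*log10), with the depth of its source block."""

    frequencies_mhz: np.ndarray
    power_db: np.ndarray
    center_depth_cm: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies_mhz = np.asarray(self.frequencies_mhz, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.frequencies_mhz.shape != self.power_db.shape:
            raise ValueError("frequency grid and power must have the same shape")

    def band_mask(self, band_mhz: tuple[float, float]) -> np.ndarray:
        lo, hi = band_mhz
        return (self.frequencies_mhz >= lo) & (self.frequencies_mhz <= hi)

    def linear_power(self) -> np.ndarray:
        return 10.0 ** (self.power_db / 10.0)


@dataclass
class AttenuationModel:
    """Two-segment total attenuation path from the transducer face to a block center.

    ``alpha0`` (default 1 dB/cm-MHz, the literature value for breast tissue
    from ultrasound tomography) acts over the intervening-tissue path ``x0``
    (cm, from the skin line to the top of the ROI); ``alpha1`` is the local
    attenuation (ACE) of the tumor acting over ``x1`` (cm, ROI top to block
    center).  ``total_db(f) = (alpha0*x0 + alpha1*x1) * f`` is the one-way
    amplitude loss A(f).
    """

    alpha0: float = 1.0
    x0_cm: float = 0.0
    alpha1: float = 0.0
    x1_cm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha0, self.alpha1) < 0:
            raise ValueError("attenuation coefficients must be >= 0")
        if min(self.x0_cm, self.x1_cm) < 0:
            raise ValueError("path lengths must be >= 0")

    def total_db(self, freqs_mhz: np.ndarray) -> np.ndarray:
        """One-way amplitude attenuation A(f) in dB at each frequency (MHz)."""
        return (self.alpha0 * self.x0_cm + self.alpha1 * self.x1_cm) * np.asarray(
            freqs_mhz, dtype=float
        )


@dataclass
class SpectralFit:
    """Linear-regression spectral parameters over a band.

    MBF (midband fit) is the fitted line evaluated at the band center
    (5.5 MHz for the 3-8 MHz band); SI the extrapolated 0-MHz intercept; SS the
    slope.  MBF = SI + SS * f_center holds by construction.
    """

    mbf_dbr: float
    ss_dbr_mhz: float
    si_dbr: float
    band_mhz: tuple[float, float]
    r_squared: float

    @property
    def f_center_mhz(self) -> float:
        return 0.5 * (self.band_mhz[0] + self.band_mhz[1])


def block_power_spectrum(
    block: RFBlock | np.ndarray,
    sampling_rate: float | None = None,
    center_depth_cm: float = 0.0,
    window: str = "hann",
    min_pad_factor: int = 4,
) -> Spectrum:
    """Line-averaged windowed periodogram of an RF block, in dB.

    Each scan line is Hann-windowed and zero-padded to the next power of two
    at least ``min_pad_factor`` times the block length (giving a frequency
    resolution <= 0.1 MHz for 2 mm blocks at 40 MHz); the periodograms are
    averaged across lines before conversion to dB.
    """
    if isinstance(block, RFBlock):
        data = block.samples
        fs = block.frame.sampling_rate
        depth = block.center_depth_cm
    else:
        data = np.asarray(block, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for raw-array input")
        fs = sampling_rate
        depth = center_depth_cm
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("block must have >= 2 scan lines")

    n = data.shape[1]
    if window == "hann":
        win = np.hanning(n)
    elif window in ("boxcar", "rect", "none"):
        win = np.ones(n)
    else:
        raise ValueError(f"unsupported window {window!r}")
    n_fft = int(2 ** np.ceil(np.log2(min_pad_factor * n)))
    # periodogram normalized by window energy (Parseval-consistent)
    spec = np.fft.rfft(data * win, n=n_fft, axis=-1)
    power = np.mean(np.abs(spec) ** 2, axis=0) / np.sum(win**2)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs) / 1e6
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    return Spectrum(frequencies_mhz=freqs, power_db=power_db, center_depth_cm=depth)


def normalize_spectrum(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Reference-phantom normalization: sample_dB - reference_dB (dBr)."""
    if sample.frequencies_mhz.shape != reference.frequencies_mhz.shape or not np.allclose(
        sample.frequencies_mhz, reference.frequencies_mhz
    ):
        raise ValueError("sample and reference must share the same frequency grid")
    return Spectrum(
        frequencies_mhz=sample.frequencies_mhz,
        power_db=sample.power_db - reference.power_db,
        center_depth_cm=sample.center_depth_cm,
    )


def _noise_floor_db(spectra: list[Spectrum], above_mhz: float = 15.0) -> float | None:
    """Median out-of-band power as a crude electronic-noise floor estimate."""
    vals = []
    for s in spectra:
        m = s.frequencies_mhz >= above_mhz
        if m.any():
            vals.append(np.median(s.power_db[m]))
    return float(np.median(vals)) if vals else None


def estimate_ace(
    sample_blocks: list[Spectrum],
    reference_blocks: list[Spectrum],
    band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ,
    alpha_ref: float = 0.15,
    depth_decimals: int = 3,
    min_ref_snr_db: float = 6.0,
) -> float:
    """Attenuation coefficient estimate (dB/cm-MHz) by the reference-phantom method.

    Sample and reference block spectra are averaged (linear power) across
    laterally adjacent blocks at each depth; the normalized power (dB) is then
    regressed on depth (cm) independently at every frequency in the band.  A
    sample more attenuating than the reference makes the normalized power fall
    with depth, so with slope ``s(f)`` (dB/cm)::

        ACE = alpha_ref - mean_f [ s(f) / (2 f) ]

    (the factor 2 converts the round-trip power-dB slope to a one-way
    amplitude coefficient).  Frequencies where the depth-averaged reference
    power is within ``min_ref_snr_db`` of the out-of-band noise floor are
    excluded from the average.
    """

    def by_depth(spectra: list[Spectrum]) -> dict[float, Spectrum]:
        groups: dict[float, list[Spectrum]] = {}
        for s in spectra:
            groups.setdefault(round(s.center_depth_cm, depth_decimals), []).append(s)
        out = {}
        for depth, members in groups.items():
            lin = np.mean([m.linear_power() for m in members], axis=0)
            out[depth] = Spectrum(
                frequencies_mhz=members[0].frequencies_mhz,
                power_db=10.0 * np.log10(lin),
                center_depth_cm=depth,
            )
        return out

    samp = by_depth(sample_blocks)
    ref = by_depth(reference_blocks)
    depths = sorted(samp)
    if len(depths) < 3:
        raise ValueError("ROI too shallow for ACE: need >= 3 distinct block depths")

    ref_depths = np.array(sorted(ref))
    freqs = sample_blocks[0].frequencies_mhz
    mask = (freqs >= band_mhz[0]) & (freqs <= band_mhz[1])

    floor = _noise_floor_db(reference_blocks)
    if floor is not None:
        mean_ref = np.mean([r.power_db for r in ref.values()], axis=0)
        mask = mask & (mean_ref > floor + min_ref_snr_db)
    if mask.sum() < 2:
        raise ValueError("no usable frequencies in the analysis band")

    z = np.array(depths)
    norm = np.empty((len(depths), int(mask.sum())))
    for i, d in enumerate(depths):
        nearest = ref_depths[np.argmin(np.abs(ref_depths - d))]
        norm[i] = samp[d].power_db[mask] - ref[nearest].power_db[mask]

    # per-frequency least-squares slope of normalized power-dB vs depth (cm)
    zc = z - z.mean()
    slopes = zc @ (norm - norm.mean(axis=0)) / np.sum(zc**2)
    f = freqs[mask]
    return float(alpha_ref - np.mean(slopes / (2.0 * f)))


def attenuation_correct(
    spec: Spectrum, model: AttenuationModel, depth_tol_cm: float = 0.11
) -> Spectrum:
    """Point attenuation compensation: add the round-trip loss 2*A(f) back, in dB.

    The model path must end at the block center: ``x0 + x1 ==
    spec.center_depth_cm`` within ``depth_tol_cm`` (about half a block).
    """
    total_path = model.x0_cm + model.x1_cm
    if abs(total_path - spec.center_depth_cm) > depth_tol_cm:
        raise ValueError(
            f"attenuation path ({total_path:.3f} cm) inconsistent with block depth "
            f"({spec.center_depth_cm:.3f} cm)"
        )
    return Spectrum(
        frequencies_mhz=spec.frequencies_mhz,
        power_db=spec.power_db + 2.0 * model.total_db(spec.frequencies_mhz),
        center_depth_cm=spec.center_depth_cm,
    )


def equalize_attenuation(
    frame: RFFrame, alpha_db_cm_mhz: float, f_max_hz: float = 12e6
) -> RFFrame:
    """Undo depth-dependent attenuation on the RF lines themselves.

    Multiplies each line's spectrum by the exact inverse round-trip loss
    ``10^(+alpha * f * 2 z / 20)`` per sample depth — a chirp z-transform on a
    spiral contour outside the unit circle — and band-limits the result at
    ``f_max_hz`` (the inverse gain grows without bound in frequency).

    Short-gate spectral estimates of strongly attenuated RF are biased: the
    window's spectral kernel smears a steeply tilted spectrum and inflates its
    band edges (Jensen effect), flattening the apparent frequency dependence.
    Equalizing the RF *before* gating removes the tilt, so block periodograms
    become unbiased; the equalized spectra then need no further point
    attenuation compensation.
    """
    from dataclasses import replace as dc_replace

    from scipy.signal import czt

    x = frame.samples
    n = x.shape[1]
    if alpha_db_cm_mhz == 0.0:
        return frame
    if alpha_db_cm_mhz < 0:
        raise ValueError("attenuation must be >= 0")
    n_fft = int(2 ** np.ceil(np.log2(n + 512)))
    df_hz = frame.sampling_rate / n_fft
    dz_cm = frame.axial_step * 100.0
    gamma = np.log(10.0) / 20.0 * alpha_db_cm_mhz * (df_hz / 1e6) * 2.0 * dz_cm
    k_max = min(n_fft // 2, int(f_max_hz / df_hz))
    w = np.exp(-2j * np.pi / n_fft + gamma)
    spec = czt(x, m=k_max + 1, w=w, a=1.0, axis=-1)
    if frame.depth_origin != 0.0:
        k = np.arange(k_max + 1)
        gain0 = 10.0 ** (
            alpha_db_cm_mhz * (k * df_hz / 1e6) * 2.0 * (frame.depth_origin * 100.0) / 20.0
        )
        spec = spec * gain0
    full = np.zeros((x.shape[0], n_fft // 2 + 1), dtype=complex)
    full[:, : k_max + 1] = spec
    y = np.fft.irfft(full, n=n_fft, axis=-1)[:, :n]
    return dc_replace(frame, samples=y)


def fit_spectral_line(
    spec: Spectrum, band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ
) -> SpectralFit:
    """OLS fit of dBr power on frequency over the band -> (MBF, SS, SI, r^2)."""
    m = spec.band_mask(band_mhz)
    if m.sum() < 2:
        raise ValueError("need >= 2 frequency points in the band for a line fit")
    f = spec.frequencies_mhz[m]
    y = spec.power_db[m]
    ss, si = np.polyfit(f, y, 1)
    resid = y - (si + ss * f)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
    f_center = 0.5 * (band_mhz[0] + band_mhz[1])
    return SpectralFit(
        mbf_dbr=float(si + ss * f_center),
        ss_dbr_mhz=float(ss),
        si_dbr=float(si),
        band_mhz=band_mhz,
        r_squared=float(r2),
    )
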
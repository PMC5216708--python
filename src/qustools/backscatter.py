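"""Backscatter coefficient estimation and Gaussian form-factor fitting.

The backscatter coefficient (BSC) of a tumor block is obtained by the
reference-phantom technique: the attenuation-corrected, reference-normalized
power ratio scales the known BSC of the reference phantom.  Fitting the
Gaussian form-factor model

    BSC(f) = 10^(AAC/10) * C * f^4 * exp(-0.827 k^2 a_eff^2)

to the estimated BSC yields the average scatterer diameter (ASD = 2 a_eff, um)
and average acoustic concentration (AAC = 10 log10(n gamma^2), dB relative
concentration; absolute units are unknowable after normalization, so AAC is
reported relative to the fixed prefactor C).

The primary fit is the linearized log-domain regression of ln(BSC/f^4) on f^2
(convex, robust), followed by one nonlinear least-squares refinement pass;
a pure nonlinear fit is available via ``method="nonlinear"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .simulate import BSC_PREFACTOR, GAUSSIAN_FF_COEF
from .spectral import ANALYSIS_BAND_MHZ, Spectrum

__all__ = ["BSCCurve", "FormFactorFit", "estimate_bsc", "fit_gaussian_form_factor"]


@dataclass
class BSCCurve:
    """Backscatter coefficient vs frequency, linear 1/(cm sr) units."""

    frequencies_mhz: np.ndarray
    bsc: np.ndarray
    provenance: str = "estimated"  # "estimated" | "analytic"

    def __post_init__(self) -> None:
        self.frequencies_mhz = np.asarray(self.frequencies_mhz, dtype=float)
        self.bsc = np.asarray(self.bsc, dtype=float)

    @property
    def bsc_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.bsc)


@dataclass
class FormFactorFit:
    """Gaussian form-factor fit result: ASD (um), AAC (dB), log-domain r^2."""

    asd_um: float
    aac_db: float
    r_squared: float
    asd_at_lower_bound: bool = False
    ka_warning: bool = False


def estimate_bsc(
    norm_corrected: Spectrum, ref_bsc: BSCCurve, band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ
) -> BSCCurve:
    """Reference-phantom BSC estimate: BSC_sample(f) = BSC_ref(f) * 10^(dBr(f)/10).

    ``norm_corrected`` must already be reference-normalized and attenuation-
    corrected for both media (the reference with its known 0.15 dB/cm-MHz).
    """
    if ref_bsc.frequencies_mhz.shape != norm_corrected.frequencies_mhz.shape or not np.allclose(
        ref_bsc.frequencies_mhz, norm_corrected.frequencies_mhz
    ):
        raise ValueError("reference BSC must be tabulated on the spectrum's frequency grid")
    m = norm_corrected.band_mask(band_mhz)
    if np.any(ref_bsc.bsc[m] <= 0):
        raise ValueError("reference BSC must be positive over the analysis band")
    return BSCCurve(
        frequencies_mhz=norm_corrected.frequencies_mhz,
        bsc=ref_bsc.bsc * 10.0 ** (norm_corrected.power_db / 10.0),
        provenance="estimated",
    )


def _model_log_bsc(f_mhz: np.ndarray, a_um: float, aac_db: float, c: float) -> np.ndarray:
    k2a2 = (2.0 * np.pi * f_mhz * 1e6 / c * a_um * 1e-6) ** 2
    return (
        np.log(BSC_PREFACTOR)
        + aac_db * np.log(10.0) / 10.0
        + 4.0 * np.log(f_mhz)
        - GAUSSIAN_FF_COEF * k2a2
    )


def fit_gaussian_form_factor(
    curve: BSCCurve,
    band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ,
    sound_speed: float = 1540.0,
    method: str = "linearized",
) -> FormFactorFit:
    """Fit the Gaussian form-factor model to a BSC curve -> (ASD, AAC, r^2).

    ``ln(BSC/f^4)`` is linear in ``f^2`` with slope ``-0.827 (2 pi / c)^2
    a_eff^2``; the linear fit seeds one nonlinear refinement pass in the log
    domain.  A non-negative fitted slope (no measurable form-factor roll-off)
    reports ASD at its lower bound 0 with a warning flag.  Fits with
    ``k a_eff > 1.2`` at the top of the band are outside the model's validity
    range and are flagged.
    """
    lo, hi = band_mhz
    m = (curve.frequencies_mhz >= lo) & (curve.frequencies_mhz <= hi)
    f = curve.frequencies_mhz[m]
    b = curve.bsc[m]
    if f.size < 5:
        raise ValueError("need >= 5 frequency points in the band")
    if np.any(b <= 0):
        raise ValueError("BSC must be positive over the fit band")

    y = np.log(b) - 4.0 * np.log(f)
    x = f**2
    slope, intercept = np.polyfit(x, y, 1)
    kc = 2.0 * np.pi * 1e6 / sound_speed  # rad/m per MHz
    at_bound = slope >= 0
    if at_bound:
        warnings.warn("non-negative log-BSC slope: ASD at lower bound 0", stacklevel=2)
        a_um = 0.0
    else:
        a_um = np.sqrt(-slope / GAUSSIAN_FF_COEF) / kc * 1e6
    aac_db = 10.0 * (intercept - np.log(BSC_PREFACTOR)) / np.log(10.0)

    if not at_bound:
        p0 = (a_um, aac_db) if method != "nonlinear" else (20.0, aac_db)
        try:
            popt, _ = optimize.curve_fit(
                lambda ff, a, aac: _model_log_bsc(ff, a, aac, sound_speed),
                f,
                np.log(b),
                p0=p0,
                bounds=([0.0, -np.inf], [np.inf, np.inf]),
                maxfev=2000,
            )
            a_um, aac_db = float(popt[0]), float(popt[1])
        except RuntimeError:  # keep the linearized estimate
            pass

    fitted = _model_log_bsc(f, a_um, aac_db, sound_speed)
    logb = np.log(b)
    tss = np.sum((logb - logb.mean()) ** 2)
    r2 = 1.0 - np.sum((logb - fitted) ** 2) / tss if tss > 0 else 1.0

    ka_top = kc * hi * a_um * 1e-6
    ka_warning = bool(ka_top > 1.2)
    if ka_warning:
        warnings.warn(f"k*a_eff = {ka_top:.2f} at {hi} MHz exceeds model validity", stacklevel=2)
    return FormFactorFit(
        asd_um=float(2.0 * a_um),
        aac_db=float(aac_db),
        r_squared=float(r2),
        asd_at_lower_bound=bool(at_bound),
        ka_warning=ka_warning,
    )
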
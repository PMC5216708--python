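"""End-to-end QUS feature extraction: RF frame + ROI -> seven-parameter vector.

The :class:`QUSAnalyzer` encapsulates the references a clinical analysis needs
(reference-phantom frames with known attenuation/BSC, a planar-reflector bank
for SAS normalization) and runs the complete per-ROI pipeline:

1. partition the ROI into 2 x 2 mm blocks with 80% overlap;
2. per-block power spectra; reference spectra from the phantom frames at the
   matching depths (averaged laterally and across frames);
3. ACE by the reference-phantom spectral-difference method over the ROI;
4. per-block attenuation-corrected normalized spectra (sample corrected with
   intervening-tissue alpha0 over x0 and ACE over x1; reference corrected with
   its known 0.15 dB/cm-MHz) -> linear-fit maps of MBF / SS / SI;
5. per-block BSC via the reference-phantom technique and Gaussian form-factor
   fits -> ASD / AAC maps;
6. per-block Burg-AR spectra, planar-reflector normalization and spectral
   autocorrelation -> SAS map;
7. ROI summary (mean over non-missing blocks) -> :class:`FeatureVector`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backscatter import BSCCurve, estimate_bsc, fit_gaussian_form_factor
from .features import FeatureVector, summarize_roi
from .rf import RFBlock, RFFrame, ROI, partition_roi
from .simulate import REFERENCE_MEDIUM, MediumSpec, analytic_bsc
from .spacing import (
    DEFAULT_AR_ORDER,
    DEFAULT_SAS_SEARCH_MHZ,
    ar_power_spectrum,
    burg_coefficients,
    estimate_sas,
    planar_normalize,
    reflector_spectrum_bank,
)
from .spectral import (
    ANALYSIS_BAND_MHZ,
    AttenuationModel,
    Spectrum,
    attenuation_correct,
    block_power_spectrum,
    equalize_attenuation,
    estimate_ace,
    fit_spectral_line,
    normalize_spectrum,
)

__all__ = ["QUSAnalyzer", "ROIResult"]


@dataclass
class ROIResult:
    """Feature vector plus the per-block parametric maps it was computed from."""

    features: FeatureVector
    maps: dict[str, np.ndarray]
    n_blocks: int
    ace_db_cm_mhz: float


def _nearest(sorted_keys: np.ndarray, value: float) -> float:
    return float(sorted_keys[np.argmin(np.abs(sorted_keys - value))])


@dataclass
class QUSAnalyzer:
    """Reusable QUS feature extractor bound to a set of reference recordings.

    Parameters
    ----------
    reference_frames
        One or more frames of the reference phantom recorded with the same
        system settings as the samples.
    reflector_frames
        Planar-reflector frames keyed by depth (cm), nominally 1-6 cm.
    reference_medium
        Acoustic ground truth of the reference phantom (attenuation and BSC
        must be known for the reference-phantom method).
    alpha0
        Intervening-tissue attenuation above the ROI, dB/cm-MHz.  The
        clinical default is 1.0; for homogeneous phantoms/simulations pass
        None to reuse the ROI's own ACE for the overlying path.
    """

    reference_frames: list[RFFrame]
    reflector_frames: dict[float, RFFrame] | None = None
    reference_medium: MediumSpec = field(default_factory=lambda: REFERENCE_MEDIUM)
    alpha0: float | None = 1.0
    band_mhz: tuple[float, float] = ANALYSIS_BAND_MHZ
    block_size_mm: float = 2.0
    overlap_fraction: float = 0.8
    ar_order: int = DEFAULT_AR_ORDER
    sas_search_mhz: tuple[float, float] = DEFAULT_SAS_SEARCH_MHZ
    summary: str = "mean"

    def __post_init__(self) -> None:
        if not self.reference_frames:
            raise ValueError("at least one reference-phantom frame is required")
        self._ref_spectra_cache: dict = {}
        self._eq_reference_frames: list[RFFrame] | None = None
        self._reflector_bank = (
            reflector_spectrum_bank(self.reflector_frames) if self.reflector_frames else None
        )

    # ----- reference spectra ------------------------------------------------

    def _equalized_reference_frames(self) -> list[RFFrame]:
        """Reference frames with their known attenuation equalized away."""
        if self._eq_reference_frames is None:
            self._eq_reference_frames = [
                equalize_attenuation(f, self.reference_medium.attenuation)
                for f in self.reference_frames
            ]
        return self._eq_reference_frames

    def _reference_spectra(
        self, blocks: list[RFBlock], frames: list[RFFrame], tag: str
    ) -> dict[float, Spectrum]:
        """Depth-binned reference spectra matching the sample block grid.

        For every distinct sample-block depth, the reference frames are cut at
        the same axial position across their full width and the periodograms
        averaged (linear power) laterally and across frames — the reference
        phantom is homogeneous, so lateral averaging only reduces variance.
        """
        depths = sorted({round(b.center_depth_cm, 3) for b in blocks})
        n_samp = blocks[0].n_samples
        n_lines_blk = blocks[0].n_lines
        key = (tuple(depths), n_samp, n_lines_blk, tag)
        if key in self._ref_spectra_cache:
            return self._ref_spectra_cache[key]
        out: dict[float, Spectrum] = {}
        for depth in depths:
            lin_acc = []
            for ref in frames:
                j = int(round((depth / 100.0 - ref.depth_origin) / ref.axial_step - n_samp / 2.0))
                j = max(0, min(ref.n_samples - n_samp, j))
                for i in range(0, ref.n_lines - n_lines_blk + 1, max(1, n_lines_blk // 2)):
                    spec = block_power_spectrum(
                        ref.samples[i : i + n_lines_blk, j : j + n_samp],
                        sampling_rate=ref.sampling_rate,
                        center_depth_cm=depth,
                    )
                    lin_acc.append(spec.linear_power())
            freqs = np.fft.rfftfreq(
                int(2 ** np.ceil(np.log2(4 * n_samp))), d=1.0 / frames[0].sampling_rate
            ) / 1e6
            out[depth] = Spectrum(
                frequencies_mhz=freqs,
                power_db=10.0 * np.log10(np.mean(lin_acc, axis=0)),
                center_depth_cm=depth,
            )
        self._ref_spectra_cache[key] = out
        return out

    # ----- main entry point -------------------------------------------------

    def analyze(self, frame: RFFrame, roi: ROI) -> ROIResult:
        """Run the full pipeline on one frame/ROI.

        Two correction modes:

        * ``alpha0 is None`` (homogeneous medium): ACE is estimated against
          attenuation-equalized reference spectra, the sample RF is then
          equalized with the ACE (see :func:`equalize_attenuation`), and the
          equalized spectra are normalized directly — short-gate window bias
          from steep spectral tilts is avoided.
        * ``alpha0`` given (layered clinical path): classical point attenuation
          compensation in the spectral domain with the two-segment model
          (alpha0 over the intervening tissue, ACE inside the ROI).
        """
        blocks = partition_roi(frame, roi, self.block_size_mm, self.overlap_fraction)
        if not blocks:
            raise ValueError("ROI produced no analysis blocks")
        raw_blocks = blocks  # SAS always runs on the native RF
        raw_spectra = [block_power_spectrum(b) for b in blocks]

        homogeneous = self.alpha0 is None
        if homogeneous:
            ref_by_depth = self._reference_spectra(
                blocks, self._equalized_reference_frames(), "eq"
            )
            ace = estimate_ace(
                raw_spectra, list(ref_by_depth.values()), band_mhz=self.band_mhz, alpha_ref=0.0
            )
            ace = max(0.0, ace)
            eq_frame = equalize_attenuation(frame, ace)
            blocks = partition_roi(eq_frame, roi, self.block_size_mm, self.overlap_fraction)
            sample_spectra = [block_power_spectrum(b) for b in blocks]
        else:
            ref_by_depth = self._reference_spectra(blocks, self.reference_frames, "raw")
            ace = estimate_ace(
                raw_spectra,
                list(ref_by_depth.values()),
                band_mhz=self.band_mhz,
                alpha_ref=self.reference_medium.attenuation,
            )
            ace = max(0.0, ace)
            sample_spectra = raw_spectra
        ref_depths = np.array(sorted(ref_by_depth))

        roi_top_cm = max(
            0.0, min(s.center_depth_cm for s in sample_spectra) - self.block_size_mm / 20.0
        )

        ref_bsc_cache: dict[int, BSCCurve] = {}
        mbf, ss, si, asd, aac, sas = ([] for _ in range(6))
        bsc_curves: list[np.ndarray] = []

        # SAS machinery: batched Burg over all (raw) block lines
        do_sas = self._reflector_bank is not None
        if do_sas:
            all_lines = np.concatenate([b.samples for b in raw_blocks], axis=0)
            a, E = burg_coefficients(all_lines, self.ar_order)

        offset = 0
        for b, samp in zip(raw_blocks, sample_spectra):
            z = samp.center_depth_cm
            ref_spec = ref_by_depth[_nearest(ref_depths, z)]
            if homogeneous:
                corrected = normalize_spectrum(samp, ref_spec)
            else:
                x1 = max(0.0, z - roi_top_cm)
                model_s = AttenuationModel(
                    alpha0=self.alpha0, x0_cm=z - x1, alpha1=ace, x1_cm=x1
                )
                model_r = AttenuationModel(
                    alpha0=self.reference_medium.attenuation, x0_cm=z, alpha1=0.0, x1_cm=0.0
                )
                corrected = normalize_spectrum(
                    attenuation_correct(samp, model_s),
                    attenuation_correct(ref_spec, model_r, depth_tol_cm=np.inf),
                )
            fit = fit_spectral_line(corrected, self.band_mhz)
            mbf.append(fit.mbf_dbr)
            ss.append(fit.ss_dbr_mhz)
            si.append(fit.si_dbr)

            n_grid = corrected.frequencies_mhz.size
            if n_grid not in ref_bsc_cache:
                ref_bsc_cache[n_grid] = BSCCurve(
                    frequencies_mhz=corrected.frequencies_mhz,
                    bsc=analytic_bsc(self.reference_medium, corrected.frequencies_mhz),
                    provenance="analytic",
                )
            bsc = estimate_bsc(corrected, ref_bsc_cache[n_grid], self.band_mhz)
            bsc_curves.append(bsc.bsc)
            with warnings.catch_warnings():
                # single-block fits are noisy; validity flags are kept per block
                warnings.simplefilter("ignore")
                ff = fit_gaussian_form_factor(bsc, self.band_mhz, frame.sound_speed)
            asd.append(ff.asd_um if not ff.asd_at_lower_bound else np.nan)
            aac.append(ff.aac_db)

            if do_sas:
                rows = slice(offset, offset + b.n_lines)
                ar_spec = ar_power_spectrum(
                    a[rows], E[rows], frame.sampling_rate, center_depth_cm=z
                )
                norm = planar_normalize(ar_spec, z, self._reflector_bank)
                sas.append(
                    estimate_sas(norm, frame.sound_speed, self.sas_search_mhz, self.band_mhz)
                )
            offset += b.n_lines

        maps = {
            "MBF": np.array(mbf),
            "SS": np.array(ss),
            "SI": np.array(si),
            "ASD": np.array(asd),
            "AAC": np.array(aac),
            "SAS": np.array(sas) if do_sas else np.full(len(blocks), np.nan),
        }
        # tumor-level ASD/AAC from the ROI-mean BSC curve: averaging the
        # per-block fits instead would bias ASD upward (noisy blocks whose
        # log-slope goes positive drop out at the a=0 bound, the rest skew big)
        grid = next(iter(ref_bsc_cache.values())).frequencies_mhz
        mean_curve = BSCCurve(frequencies_mhz=grid, bsc=np.mean(bsc_curves, axis=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roi_ff = fit_gaussian_form_factor(mean_curve, self.band_mhz, frame.sound_speed)
        features = FeatureVector(
            MBF=summarize_roi(maps["MBF"], how=self.summary),
            SS=summarize_roi(maps["SS"], how=self.summary),
            SI=summarize_roi(maps["SI"], how=self.summary),
            SAS=summarize_roi(maps["SAS"], how="median"),
            ACE=ace,
            ASD=np.nan if roi_ff.asd_at_lower_bound else roi_ff.asd_um,
            AAC=roi_ff.aac_db,
        )
        return ROIResult(features=features, maps=maps, n_blocks=len(blocks), ace_db_cm_mhz=ace)
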
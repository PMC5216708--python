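# Methods

`qustools` re-implements a multi-parameter quantitative-ultrasound (QUS)
pipeline for monitoring breast-tumor response to neoadjuvant chemotherapy:
seven tumor-level parameters are estimated from raw beamformed RF data, their
changes from the pre-treatment scan feed a KNN response classifier with
leave-one-patient-out evaluation, and predicted response groups are compared
by recurrence-free survival. Because clinical RF recordings of this kind are
not publicly available, the package includes a point-scatterer RF simulator
and a synthetic-cohort generator with known ground truth; every estimator is
validated by parameter recovery rather than by comparison to any fixed
waveform.

## Signal model and dB conventions

All power spectra are `10·log10(power)`. A one-way amplitude attenuation
coefficient `α` (dB/cm-MHz) removes `α·f·d` dB of pressure amplitude over a
path `d`; an echo from depth `z` travels `2z`, so its amplitude — and
therefore its power, since dB are dB — is down `2·α·f·z` dB. Consequently:

* `attenuation_correct` adds `2·A(f)` dB to a power spectrum, where
  `A(f) = (α₀·x₀ + α₁·x₁)·f` is the one-way amplitude loss along the
  two-segment path (intervening tissue `x₀` at `α₀`, default 1 dB/cm-MHz from
  published breast tomography values; intratumoral path `x₁` at the tumor's
  own ACE).
* `estimate_ace` regresses the reference-normalized power (dB) on depth (cm)
  at each frequency and converts the slope `s(f)` with the round-trip factor
  2: `ACE = α_ref − mean_f [s(f) / (2f)]`. On noiseless spectra constructed
  from the attenuation law this is exact (unit tests assert 1e-9).

## Block processing

Tumor ROIs are tiled with 2 × 2 mm blocks at 80% overlap in both directions
(stride 20% of the block size, rounded to whole samples/lines; at 40 MHz and
1540 m/s a 2 mm gate is 104 samples, about ten spatial pulse lengths). A
candidate grid position is kept only when ≥ 90% of its area lies inside the
ROI mask — interior-only blocks, mirroring center-of-tumor ROI selection.
Block spectra are Hann-windowed per-line periodograms, zero-padded to ≥ 4×
the gate length (grid ≤ 0.1 MHz), averaged across lines in linear power.
The analysis band is the −6 dB transducer band, 3–8 MHz; the spectral-fit
midband frequency is its midpoint, 5.5 MHz, so `MBF = SI + 5.5·SS` by
construction.

## Reference-phantom normalization

Sample spectra are normalized (dB subtraction) by spectra of a homogeneous
reference phantom with known properties (0.15 dB/cm-MHz, 1515 m/s, 18 µm
glass microspheres at 2.2 g/L ≈ 290 mm⁻³), cancelling the system transfer
function. Reference spectra are extracted at the same depths as the sample
blocks and averaged laterally and across frames. Reference averaging matters
more than sample averaging: reference-spectrum speckle error is a *fixed
systematic* for every sample analyzed against the same recordings. The
default analyzer therefore uses eight frames of a 132-line-wide phantom scan
with 50%-overlapping lateral cuts; with only two narrow frames we measured a
±0.02 dB/cm-MHz analyzer-specific ACE offset that propagated into the
backscatter fits.

## Attenuation handling: two modes

With `alpha0` given (layered clinical geometry), the classical route is used:
point attenuation compensation in the spectral domain with the two-segment
`A(f)` model for the sample and the known 0.15 dB/cm-MHz for the reference.

With `alpha0=None` (homogeneous media — phantoms and all simulations), the
pipeline instead equalizes the RF lines themselves by the estimated ACE
before gating (`equalize_attenuation`), and normalizes directly. The reason
is numerical: a 2 mm Hann gate has a ~0.5 MHz spectral kernel, and convolving
that kernel with a spectrum tilted by tens of dB across the band inflates the
band edges (Jensen effect on the local exponential slope). Left uncorrected,
this flattened the measured BSC frequency dependence enough to bias the
fitted scatterer size by ~40% at small radii. Equalizing before gating
removes the tilt at its source; the spectral-domain operator remains
available and unit-tested. Equalization is exact: a loss linear in dB in
both frequency and depth is precisely a damped DFT, evaluated as a chirp
z-transform on a spiral contour (also how the simulator applies attenuation,
per scatterer, with no segmentation artifacts). The inverse gain grows
without bound in `f·z`, so the equalized signal is band-limited at 12 MHz;
high-frequency content at depth below the electronic noise floor is
unrecoverable either way.

## Backscatter model (ASD / AAC)

The block BSC is `BSC_ref(f)·10^(dBr(f)/10)` with the reference's analytic
BSC `C·n·γ²·f⁴·exp(−0.827·k²·a_eff²)` (Gaussian form factor; fixed prefactor
`C = 1e-5`, a unit convention that cancels in normalization — AAC is a
*relative* concentration in dB). Fitting is a linearized regression of
`ln(BSC/f⁴)` on `f²` (convex, with the exact closed-form inverse on
noiseless model curves) followed by one nonlinear refinement pass in the log
domain. Tumor-level ASD/AAC are fitted on the ROI-mean BSC curve: averaging
per-block fits instead biases ASD upward, because noisy blocks whose log-BSC
slope turns positive are truncated at the `a_eff = 0` bound (reported as
missing) while the remainder skew large. Fits with `k·a_eff > 1.2` at 8 MHz
are outside the Gaussian model's validity range and flagged.

## Scatterer spacing (SAS)

Each block's lines are modeled with an order-50 Burg AR process (gate length
104 samples > 2·order); line spectra are averaged in linear power, normalized
(dB) by a planar-reflector spectrum at the nearest of six depths (1–6 cm,
ties toward the shallower), and the spectral autocorrelation of the
mean-subtracted linear power over 3–8 MHz is searched for its dominant local
peak at lags 0.2–2.5 MHz (lag-0 exclusion: two grid cells). `SAS =
c/(2·Δf_peak)`; blocks without a peak report missing, never zero. SAS runs
on the native (un-equalized) RF: the planar reflector encodes the system's
raw spectral shape. The ROI summary for SAS is the median over blocks
(robust to the missing/dispersed blocks a diffuse medium produces); other
parameters summarize by the mean.

## Simulator

2-D (axial × lateral) line-wise synthesis: scatterers are assigned to the
nearest scan line, placed as impulse trains at round-trip delays, filtered by
the per-scatterer response `f²·√F(k·a_eff)` so simulated backscatter power
follows the same `f⁴`-times-form-factor law the fitting assumes, attenuated
exactly via the chirp z-transform, convolved with a Gaussian-modulated 6 MHz
pulse (fractional −6 dB bandwidth 1.0, covering 3–9 MHz), and given white
electronic noise 60 dB below frame RMS (a deliberately clean acquisition;
noisier settings degrade the deep high-frequency corner first). Diffuse
scatterer amplitudes are constant-magnitude with random sign — identical
scatterers, as for monodisperse microspheres — which reaches Gaussian field
statistics at realistic densities much faster than Gaussian amplitudes. A
2-D plane has a far smaller resolution-cell volume than a real beam, so
volumetric densities are mapped to areal ones through an effective 8 mm
elevational integration length, chosen so the reference phantom's realization
exhibits fully developed speckle (envelope SNR ≈ 1.91, the Rayleigh value);
this factor cancels between sample and reference in every normalized
quantity. No diffraction, elevational focusing, or nonlinear propagation is
simulated — the reference-phantom method removes system/beam effects, and
recovery of planted parameters (not waveform fidelity) is the validation
target. What passing tests therefore show is that the estimators are correct
under the stated scattering model; they do not certify performance against
beam-diffraction or aberration effects present in clinical data.

## Synthetic cohort

Each patient receives a baseline tumor medium: attenuation U(0.5, 0.9)
dB/cm-MHz, effective radius N(25, 2) µm, density 60 mm⁻³, patient-specific
echogenicity `γ²` log-normal with 1.5 dB SD (this inter-patient spread is
why features are baseline-normalized), and a coherent lattice N(1.0, 0.05) mm
at 2.5× the diffuse RMS amplitude (weaker or wider lattices are unmeasurable
with 2 mm gates, which need ~2 lattice scatterers per gate). Responders
drift with treatment week — echogenicity +1.5/+3.0/+3.5 dB at weeks 1/4/8
(driving MBF/SI/AAC) and attenuation +0.15/+0.25/+0.10 dB/cm-MHz — while
non-responders stay flat; both groups get per-week biological noise (2 dB on
echogenicity, 0.18 on attenuation). Magnitudes were set for roughly 80%
week-4 single-feature separability so pipeline regressions are detectable
without being trivial; directions follow the reported treatment-response
pattern (backscatter and attenuation rise with response; scatterer size and
spacing carry no planted effect). Recurrence-free survival is exponential
with responder/non-responder hazard ratio 0.3 (non-responder median 20
months) under uniform censoring on 6–40 months. Everything is deterministic
given the master seed, with per-patient and per-week streams spawned from it.

## Classification

KNN with k = 2 and Euclidean distance. Features are z-scored per LOOCV
training fold (distances across dBr, mm and dB/cm-MHz are meaningless
unscaled). A k = 2 split vote falls back to the nearest neighbor's class;
exact-distance ties break toward the lower training index. Class imbalance
is handled by resampling the majority class with replacement down to the
minority count (N = 16 for the 42/16 clinical cohort) and repeating 10 times;
during LOOCV *all* resampled copies of the held-out patient leave the
training fold (the optimistic variant is available behind
`remove_duplicates=False` for comparison). Exhaustive feature selection
enumerates all subsets of sizes 2–7 of the seven features — 120 subsets —
maximizing mean accuracy with ties to the smaller subset, then
lexicographic; with pre-treatment values included, each (week-0, Δ) pair is
one selectable unit so the enumeration is unchanged.

## Survival statistics

Kaplan–Meier product-limit and the 1-df log-rank test (hypergeometric
variance with ties) are implemented directly and cross-checked against
`lifelines` in the test suite; group-mean comparisons use the pooled-variance
unpaired t-test, right-tailed at 95% (Welch available via a flag).

## Clinical table

The packaged 58-patient table stores, per patient: age, initial and residual
foci dimensions, the study-adjudicated bulk tumor shrinkage (BTS, %), a
residual-cellularity note, and the response label. `BTS = 100·(1 −
Σresidual/Σinitial)` over all printed foci diameters; "no residual" is 100%.
A handful of stored BTS values are not exactly reproducible from the printed
dimensions (focal sums and rounding are under-specified), so the stored BTS
is authoritative. Labeling: pathology override > cellularity note (low →
responder, high → non-responder) > BTS > 30%. Applying the rule reproduces
the stored response column for all 58 patients (one pathology-override case
is flagged as such).

## Problem sizes

Default validation geometry: 44-line (11 mm) frames, 1664 samples (~3.2 cm)
at 40 MHz, ROI 10 mm × 1.0–2.8 cm (≈ 680 blocks). Recovery ensembles use 20
seeds per condition; the end-to-end demonstration uses the reduced cohort (20
patients, weeks 0 and 4). These sizes give stable ensemble means while
keeping a full validation run in minutes on one core.

## Known limitations

* The homogeneous-mode residual biases are not zero: ACE carries ≈ +0.01
  dB/cm-MHz and small-radius ASD ≈ −13% under the default geometry (within
  the ±15%/±20% recovery tolerances, dominated by short-gate spectral
  smearing).
* The two-segment layered mode inherits the textbook point-compensation
  bias that the homogeneous mode avoids.
* AAC is relative (normalization destroys absolute backscatter units);
  comparisons are only meaningful within one reference configuration.
* SAS requires a genuinely periodic scatterer component with ≥ ~2 lattice
  scatterers per 2 mm gate; purely diffuse media yield dispersed or missing
  estimates by design.
* Follow-up times for the real cohort are not part of the clinical table;
  survival analyses run on synthetic cohorts with a configurable hazard
  ratio.
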
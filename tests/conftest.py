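"""Shared fixtures: simulated reference recordings and a reusable analyzer.

The heavier parameter-recovery and end-to-end tests share one simulated
reference-phantom / planar-reflector set so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qustools as q

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Standard simulation geometry used throughout the suite: 11 mm wide,
#: ~3.2 cm deep at 40 MHz.
ACQ = q.AcquisitionSpec(n_lines=44, n_samples=1664, line_pitch=0.25e-3)


@pytest.fixture(scope="session")
def pulse() -> q.PulseSpec:
    return q.PulseSpec()


@pytest.fixture(scope="session")
def acq() -> q.AcquisitionSpec:
    return ACQ


@pytest.fixture(scope="session")
def reference_frames(pulse):
    """Wide reference-phantom frames: generous lateral averaging keeps the
    (systematic-per-analyzer) reference speckle error small."""
    from dataclasses import replace

    ref_acq = replace(ACQ, n_lines=132)
    return [q.synthesize_reference(ref_acq, 1000 + i, pulse=pulse) for i in range(8)]


@pytest.fixture(scope="session")
def reflector_bank_frames(pulse):
    return q.planar_reflector_bank(ACQ, pulse=pulse)


@pytest.fixture(scope="session")
def analyzer(reference_frames, reflector_bank_frames):
    """Full analyzer (with SAS path) for homogeneous simulated media."""
    return q.QUSAnalyzer(
        reference_frames=reference_frames,
        reflector_frames=reflector_bank_frames,
        alpha0=None,
    )


@pytest.fixture(scope="session")
def fast_analyzer(reference_frames):
    """Analyzer without the SAS path (no reflector bank) for spectral recoveries."""
    return q.QUSAnalyzer(reference_frames=reference_frames, alpha0=None)


def standard_roi(frame: q.RFFrame) -> q.ROI:
    return q.ROI.from_depth_range(frame, 1.0, 2.8, line_start=2, line_stop=42)


@pytest.fixture(scope="session")
def radius_ladder(fast_analyzer, pulse):
    """Recovery ensemble: media with a_eff in {15, 25, 40} um, 20 seeds each.

    All media carry a planted attenuation of 1.0 dB/cm-MHz, so the a=25 rung
    doubles as the ACE-recovery ensemble.  Returns
    {radius: {"ASD": [...], "SS": [...], "ACE": [...]}}.
    """
    out: dict[float, dict[str, list[float]]] = {}
    for radius in (15.0, 25.0, 40.0):
        medium = q.MediumSpec(
            attenuation=1.0, scatterer_radius_um=radius, number_density=60.0
        )
        vals = {"ASD": [], "SS": [], "ACE": []}
        for seed in range(20):
            frame = q.simulate_medium_frame(medium, ACQ, 7000 + seed, pulse=pulse)
            res = fast_analyzer.analyze(frame, standard_roi(frame))
            vals["ASD"].append(res.features.ASD)
            vals["SS"].append(res.features.SS)
            vals["ACE"].append(res.ace_db_cm_mhz)
        out[radius] = vals
    return out


@pytest.fixture(scope="session")
def sas_recovery(analyzer, pulse):
    """Recovery ensemble for a planted 1.0 mm scatterer lattice, 20 seeds."""
    medium = q.MediumSpec(
        attenuation=0.5,
        number_density=60.0,
        regular_spacing_mm=1.0,
        regular_fraction=3.0,
    )
    medians = []
    for seed in range(20):
        frame = q.simulate_medium_frame(medium, ACQ, 8800 + seed, pulse=pulse)
        res = analyzer.analyze(frame, standard_roi(frame))
        medians.append(float(np.nanmedian(res.maps["SAS"])))
    return medians


@pytest.fixture(scope="session")
def reduced_cohort_run(analyzer):
    """End-to-end run of the reduced (20-patient, weeks 0/4) synthetic cohort."""
    cohort = q.generate_cohort(q.CohortSpec.reduced(seed=42))
    feats = q.extract_cohort_features(cohort, analyzer)
    table = q.build_feature_table(feats, week=4, labels=cohort.labels())
    return cohort, feats, table
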
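"""Per-patient-week QUS feature vectors and baseline-normalized feature tables.

Each imaging session yields one :class:`FeatureVector` of seven tumor-level
QUS parameters (MBF, SS, SI, SAS, ACE, ASD, AAC).  Classification uses the
change relative to the pre-treatment scan (week 0), denoted with a ``d``
prefix (dMBF = MBF(week w) - MBF(week 0)); this baseline normalization absorbs
inter-patient differences in breast echogenicity.  Optionally the week-0
absolute values are concatenated as ``<name>_wk0`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FeatureVector", "FEATURE_NAMES", "summarize_roi", "build_feature_table"]

#: Canonical feature order used throughout the package.
FEATURE_NAMES = ("MBF", "SS", "SI", "SAS", "ACE", "ASD", "AAC")


@dataclass
class FeatureVector:
    """Tumor-level QUS parameters for one patient at one scan week.

    Units: MBF/SI in dBr, SS in dBr/MHz, SAS in mm, ACE in dB/cm-MHz, ASD in
    um, AAC in dB relative concentration.  Missing estimates are NaN.
    """

    MBF: float
    SS: float
    SI: float
    SAS: float
    ACE: float
    ASD: float
    AAC: float
    week: int | str = 0

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self) if f.name != "week"})


def summarize_roi(parametric_map: np.ndarray, max_missing: float = 0.5, how: str = "mean") -> float:
    """Collapse a per-block parametric map to one tumor-level scalar.

    Arithmetic mean (or median with ``how="median"``) over non-missing blocks;
    NaN when more than ``max_missing`` of the blocks are missing.
    """
    values = np.asarray(parametric_map, dtype=float).ravel()
    if values.size == 0:
        return float("nan")
    missing = np.isnan(values)
    if missing.mean() > max_missing:
        return float("nan")
    good = values[~missing]
    return float(np.median(good) if how == "median" else np.mean(good))


def build_feature_table(
    vectors: dict[str, dict[int | str, FeatureVector]],
    week: int | str,
    include_baseline: bool = False,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the classification feature table for one scan week.

    Rows are patients; columns are the seven ``d``-prefixed change features
    (value at ``week`` minus value at week 0), optionally preceded by the
    seven week-0 absolute features.  Patients missing the week-0 scan or the
    requested week are excluded (logged).  When ``labels`` is given, a
    ``label`` column is attached.
    """
    rows = {}
    for pid, by_week in vectors.items():
        if 0 not in by_week:
            logger.info("patient %s excluded: no week-0 (baseline) feature vector", pid)
            continue
        if week not in by_week:
            logger.info("patient %s excluded from week %s: no scan", pid, week)
            continue
        base = by_week[0].as_series()
        cur = by_week[week].as_series()
        delta = (cur - base).rename(lambda name: f"d{name}")
        if include_baseline:
            base_cols = base.rename(lambda name: f"{name}_wk0")
            rows[pid] = pd.concat([base_cols, delta])
        else:
            rows[pid] = delta
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    if labels is not None:
        table.insert(0, "label", [labels.get(pid) for pid in table.index])
    return table
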
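"""Clinical response table: bulk tumor shrinkage, response labeling, cohort summary.

The package bundles a 58-patient clinical response table (plain CSV) with the
columns of a typical neoadjuvant-chemotherapy study record: age, initial and
residual tumor dimensions (possibly multifocal), printed bulk tumor shrinkage
(BTS, %), residual-cellularity pathology note, and the adjudicated response.

Labeling follows the combined RECIST + residual-cellularity rule: a patient is
a responder when the summed diameters of the tumor foci shrank by more than
30%, or when pathology found low residual cellularity in the non-mass-
enhancing area; high residual cellularity marks a non-responder regardless of
shrinkage.  An explicit pathology override (rare, e.g. a mid-course therapy
switch) wins over the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "RESPONDER",
    "NON_RESPONDER",
    "parse_dimensions",
    "compute_bts",
    "label_response",
    "load_clinical_table",
    "records_from_table",
    "cohort_summary",
]

RESPONDER = "Responder"
NON_RESPONDER = "Non-Responder"

#: BTS threshold (%): more than 30% reduction in summed foci diameters.
BTS_RESPONSE_THRESHOLD = 30.0


@dataclass
class PatientRecord:
    """One patient's clinical fields relevant to response adjudication."""

    patient_id: str
    age: float
    initial_dimensions_cm: list[float]
    residual_dimensions_cm: list[float] | None  # None = not measurable (e.g. diffuse)
    bts_percent: float | None
    cellularity: str = "none"  # {"low", "high", "none"}
    pathology_override: str | None = None
    response: str | None = None  # printed label, if any
    followup_months: float | None = None
    recurrence_event: bool | None = None


def parse_dimensions(text: str | float | None) -> list[float] | None:
    """Parse a dimensions cell like ``"2 x 1 x 1; 1.6 x 1 x 0.5"`` to a flat list (cm).

    ``"No residual"`` maps to an empty list; non-numeric descriptions such as
    ``"whole breast"`` map to None (diameters not measurable).
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if not s:
        return None
    if s.lower().startswith("no residual"):
        return []
    dims: list[float] = []
    for focus in s.split(";"):
        for part in focus.replace("×", "x").split("x"):
            part = part.strip()
            if not part:
                continue
            try:
                dims.append(float(part))
            except ValueError:
                return None
    return dims or None


def compute_bts(initial_cm: list[float], residual_cm: list[float]) -> float:
    """Bulk tumor shrinkage, %: 100 * (1 - sum(residual) / sum(initial)).

    An empty residual list (no residual tumor) is complete shrinkage, 100%.
    """
    total_initial = float(np.sum(initial_cm))
    if total_initial <= 0:
        raise ValueError("initial tumor dimensions must sum to a positive length")
    if not residual_cm:
        return 100.0
    return 100.0 * (1.0 - float(np.sum(residual_cm)) / total_initial)


def label_response(record: PatientRecord) -> str | None:
    """Adjudicate responder / non-responder for one patient.

    Precedence: explicit pathology override, then the cellularity note (low ->
    responder, high -> non-responder), then BTS > 30%.  The record's stored
    ``bts_percent`` (the study-adjudicated value) is preferred; when absent it
    is recomputed from the dimensions.  Returns None when neither shrinkage
    nor cellularity information exists (patient excluded from analysis).
    """
    if record.pathology_override:
        return record.pathology_override
    if record.cellularity == "low":
        return RESPONDER
    if record.cellularity == "high":
        return NON_RESPONDER
    bts = record.bts_percent
    if bts is None:
        if record.residual_dimensions_cm is None or not record.initial_dimensions_cm:
            return None
        bts = compute_bts(record.initial_dimensions_cm, record.residual_dimensions_cm)
    return RESPONDER if bts > BTS_RESPONSE_THRESHOLD else NON_RESPONDER


def load_clinical_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a clinical CSV (defaults to the packaged 58-patient table)."""
    if path is None:
        with resources.as_file(
            resources.files("qustools.data") / "clinical_response.csv"
        ) as p:
            df = pd.read_csv(p, dtype={"patient_id": str})
    else:
        df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "age", "initial_dimensions_cm", "residual_dimensions_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns: {sorted(missing)}")
    return df


def records_from_table(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a clinical table to typed records."""
    records = []
    for _, row in df.iterrows():
        override = row.get("pathology_override")
        if isinstance(override, float) and np.isnan(override):
            override = None
        bts = row.get("bts_percent")
        bts = None if bts is None or (isinstance(bts, float) and np.isnan(bts)) else float(bts)
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                initial_dimensions_cm=parse_dimensions(row["initial_dimensions_cm"]) or [],
                residual_dimensions_cm=parse_dimensions(row["residual_dimensions_cm"]),
                bts_percent=bts,
                cellularity=str(row.get("cellularity", "none")),
                pathology_override=override or None,
                response=row.get("response"),
                followup_months=row.get("followup_months"),
                recurrence_event=row.get("recurrence_event"),
            )
        )
    return records


def cohort_summary(df: pd.DataFrame) -> dict[str, float]:
    """Recompute headline cohort numbers from a clinical table.

    Labels come from :func:`label_response` applied to each record (not from
    the printed response column), so this doubles as a consistency check.
    """
    records = records_from_table(df)
    labels = [label_response(r) for r in records]
    n = len(records)
    n_resp = sum(1 for lab in labels if lab == RESPONDER)
    n_non = sum(1 for lab in labels if lab == NON_RESPONDER)
    return {
        "n_patients": float(n),
        "n_responders": float(n_resp),
        "n_non_responders": float(n_non),
        "response_rate_percent": 100.0 * n_resp / n if n else float("nan"),
        "mean_age_years": float(np.mean([r.age for r in records])) if n else float("nan"),
    }
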
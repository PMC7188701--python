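"""The tabular patient cohort: survival endpoints, covariates, PET parameters.

A cohort is a CSV with one row per patient.  Survival times are months from
neuropathological diagnosis to death (OS) or progression (PFS); event flags
are 1 for an observed event and 0 for censoring.  Molecular and clinical
covariates enter as given labels — no assays are modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = ["PatientRecord", "read_cohort", "write_cohort", "cohort_to_frame"]

IDH_LEVELS = ("mutant", "wildtype")
MGMT_LEVELS = ("methylated", "unmethylated")
RESECTION_LEVELS = ("biopsy", "partial", "complete")
WHO_LEVELS = ("III", "IV")

#: the five PET parameters carried per patient
PET_PARAMETERS = ("tbr_max", "tbr_mean", "mtv_ml", "ttp_min", "slope_suv_per_h")

COHORT_COLUMNS = (
    "patient_id",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "idh",
    "mgmt",
    "kps",
    "resection",
    "age_years",
    "who_grade",
) + PET_PARAMETERS


@dataclass
class PatientRecord:
    """One patient: endpoints, covariates, and quantified PET parameters.

    ``tbr_mean`` may be NaN when no tumour was detected (no voxel reaches
    the TBR threshold); all other PET parameters are then conventionally
    0 (MTV) or still defined (TBR_max, TTP, slope).
    """

    patient_id: str
    os_months: float
    os_event: int
    pfs_months: float
    pfs_event: int
    idh: str
    mgmt: str
    kps: int
    resection: str
    age_years: float
    who_grade: str
    tbr_max: float = math.nan
    tbr_mean: float = math.nan
    mtv_ml: float = math.nan
    ttp_min: float = math.nan
    slope_suv_per_h: float = math.nan

    def validate(self) -> None:
        if self.os_months < 0:
            raise ValidationError(f"os_months must be >= 0, got {self.os_months}")
        if self.pfs_months < 0:
            raise ValidationError(f"pfs_months must be >= 0, got {self.pfs_months}")
        if self.pfs_months > self.os_months:
            raise ValidationError(
                f"pfs_months ({self.pfs_months}) exceeds os_months ({self.os_months})"
            )
        for name in ("os_event", "pfs_event"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1, got {v!r}")
        for name, levels in (
            ("idh", IDH_LEVELS),
            ("mgmt", MGMT_LEVELS),
            ("resection", RESECTION_LEVELS),
            ("who_grade", WHO_LEVELS),
        ):
            v = getattr(self, name)
            if v not in levels:
                raise ValidationError(
                    f"{name} must be one of {levels}, got {v!r}"
                )
        if not (0 <= self.kps <= 100):
            raise ValidationError(f"kps must be in 0-100, got {self.kps}")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; errors carry the offending row index."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    missing = set(COHORT_COLUMNS[:11]) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                os_months=float(row["os_months"]),
                os_event=int(row["os_event"]),
                pfs_months=float(row["pfs_months"]),
                pfs_event=int(row["pfs_event"]),
                idh=str(row["idh"]),
                mgmt=str(row["mgmt"]),
                kps=int(row["kps"]),
                resection=str(row["resection"]),
                age_years=float(row["age_years"]),
                who_grade=str(row["who_grade"]),
                **{
                    p: float(row[p]) if p in df.columns and pd.notna(row[p])
                    else math.nan
                    for p in PET_PARAMETERS
                },
            )
            rec.validate()
        except (ValidationError, ValueError, KeyError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with the canonical column order."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df[list(COHORT_COLUMNS)]


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)
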
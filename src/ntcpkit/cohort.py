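"""Patient records, CTCAE endpoint derivation and covariate encoding.

The toxicity endpoint is acute salivary dysfunction (dry mouth) of CTCAE
grade >= 2 at any weekly on-treatment assessment.  Patients with salivary
symptoms before radiotherapy (non-zero baseline grade) are excluded, so the
weekly grade series starts at the first on-treatment week.  A longitudinal
alternative flags patients whose mean weekly grade reaches 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import DoseVolumeHistogram

__all__ = [
    "PatientRecord",
    "EndpointResult",
    "COMORBIDITIES",
    "FEATURE_COLUMNS",
    "derive_endpoint",
    "actuarial_incidence",
    "encode_covariates",
    "cohort_to_frame",
    "frame_to_records",
    "load_cohort_csv",
    "save_cohort_csv",
]

COMORBIDITIES = ("hypertension", "diabetes", "cardiological", "haematological", "oncological")

GRADE_MAX = 3


@dataclass
class PatientRecord:
    """One patient's covariates, weekly toxicity grades and organ DVHs."""

    patient_id: str
    cohort: str = "development"  # development | npc_validation | hnc_validation
    sex: str = "M"  # F | M
    age: float = 50.0  # years
    bmi: float = 25.0  # kg/m^2
    smoking: bool = False
    comorbidities: dict = field(default_factory=dict)  # flags per COMORBIDITIES
    histology: str = "undifferentiated"  # undifferentiated | SCC | other
    stage_group: str = "high"  # low-intermediate | high
    t_high: bool = False
    n_positive: bool = True
    treatment: str = "RT-CHT"  # RT-CHT | iCHT+RT-CHT | RT alone
    technique: str = "IMRT"  # IMRT | VMAT
    fraction_dose_class: str = "2.00"  # 2.00 | >=2.12 (Gy per fraction)
    overall_treatment_time: float = 50.0  # days
    weekly_grades: list = field(default_factory=list)  # CTCAE 0-3, week 1..k
    baseline_grade: int = 0  # pre-RT grade; must be 0 (exclusion criterion)
    organ_dvhs: dict = field(default_factory=dict)  # organ label -> DVH
    dose_metrics: dict = field(default_factory=dict)  # e.g. cpg_d98, oc_eud

    def __post_init__(self) -> None:
        if not 18.0 <= self.age <= 100.0:
            raise ValueError(f"age {self.age} outside the adult range [18, 100]")
        for g in self.weekly_grades:
            if g not in (0, 1, 2, 3):
                raise ValueError(f"weekly grade {g!r} outside CTCAE 0-3")


@dataclass(frozen=True)
class EndpointResult:
    event: bool
    first_event_week: int | None
    mean_grade: float
    longitudinal_event: bool  # mean weekly grade >= 1.5

    def __post_init__(self) -> None:
        if self.event != (self.first_event_week is not None):
            raise ValueError("event flag and first_event_week must agree")
        if not 0.0 <= self.mean_grade <= GRADE_MAX:
            raise ValueError("mean grade must lie in [0, 3]")


def derive_endpoint(
    weekly_grades: Sequence[int], baseline_grade: int = 0
) -> EndpointResult:
    """Derive the grade >= 2 endpoint from a weekly CTCAE grade series.

    ``weekly_grades[0]`` is week 1 (first on-treatment assessment).  The mean
    grade is taken over all on-treatment weeks; the separate pre-treatment
    baseline must be grade 0 (symptomatic patients are excluded from the
    analysis before modelling).
    """
    if len(weekly_grades) == 0:
        raise ValueError("weekly grade series is empty")
    if baseline_grade != 0:
        raise ValueError(
            "non-zero baseline grade: patients with salivary symptoms before "
            "radiotherapy are excluded"
        )
    grades = np.asarray(weekly_grades, dtype=float)
    if not np.all(np.isin(grades, [0, 1, 2, 3])):
        bad = grades[~np.isin(grades, [0, 1, 2, 3])][0]
        raise ValueError(f"grade {bad} outside CTCAE 0-3")
    hits = np.nonzero(grades >= 2)[0]
    first_week = int(hits[0]) + 1 if hits.size else None
    mean_grade = float(grades.mean())
    return EndpointResult(
        event=hits.size > 0,
        first_event_week=first_week,
        mean_grade=mean_grade,
        longitudinal_event=mean_grade >= 1.5,
    )


def actuarial_incidence(cohort: Sequence[PatientRecord], week: int) -> float:
    """Cumulative incidence of the endpoint by ``week`` over the risk set.

    A patient contributes to the week-``week`` risk set if their treatment
    spans that week or they evented on or before it; patients whose treatment
    ended earlier without an event leave the risk set.  With no early exits
    this is the crude cumulative event proportion.
    """
    if week < 1:
        raise ValueError("week index starts at 1")
    events = 0
    at_risk = 0
    for p in cohort:
        ep = derive_endpoint(p.weekly_grades, p.baseline_grade)
        evented = ep.event and ep.first_event_week <= week
        if evented:
            events += 1
            at_risk += 1
        elif len(p.weekly_grades) >= week:
            at_risk += 1
    if at_risk == 0:
        raise ValueError(f"no patients under observation at week {week}")
    return events / at_risk


#: encoded clinical feature names, in emission order
FEATURE_COLUMNS = (
    "age_5y",
    "sex_male",
    "bmi",
    "bmi_ge25",
    "bmi_ge30",
    "smoking",
    "comorb_hypertension",
    "comorb_diabetes",
    "comorb_cardiological",
    "comorb_haematological",
    "comorb_oncological",
    "histology_scc",
    "histology_other",
    "stage_high",
    "t_high",
    "n_positive",
    "treat_icht",
    "treat_rt_alone",
    "technique_vmat",
    "fraction_ge212",
    "overall_treatment_time",
)

_MANDATORY = (
    "age",
    "bmi",
    "sex",
    "smoking",
    "histology",
    "stage_group",
    "treatment",
    "technique",
    "fraction_dose_class",
)


def encode_covariates(record: PatientRecord) -> dict[str, float]:
    """Encode a record into the model design conventions.

    Age enters continuously in 5-year units (one coefficient per 5-year
    increase); BMI is emitted continuously plus overweight (>=25) and obese
    (>=30) indicators; everything else is 0/1 indicators.
    """
    missing = [f for f in _MANDATORY if getattr(record, f, None) is None]
    if missing:
        raise ValueError(f"record {record.patient_id}: missing fields {missing}")
    c = record.comorbidities
    return {
        "age_5y": record.age / 5.0,
        "sex_male": float(record.sex == "M"),
        "bmi": float(record.bmi),
        "bmi_ge25": float(record.bmi >= 25.0),
        "bmi_ge30": float(record.bmi >= 30.0),
        "smoking": float(record.smoking),
        **{f"comorb_{k}": float(bool(c.get(k, False))) for k in COMORBIDITIES},
        "histology_scc": float(record.histology == "SCC"),
        "histology_other": float(record.histology == "other"),
        "stage_high": float(record.stage_group == "high"),
        "t_high": float(record.t_high),
        "n_positive": float(record.n_positive),
        "treat_icht": float(record.treatment == "iCHT+RT-CHT"),
        "treat_rt_alone": float(record.treatment == "RT alone"),
        "technique_vmat": float(record.technique == "VMAT"),
        "fraction_ge212": float(record.fraction_dose_class == ">=2.12"),
        "overall_treatment_time": float(record.overall_treatment_time),
    }


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Wide per-patient table: covariates, dose metrics and week_1..week_k grades."""
    rows = []
    max_weeks = max((len(p.weekly_grades) for p in cohort), default=0)
    for p in cohort:
        row: dict = {
            "patient_id": p.patient_id,
            "cohort": p.cohort,
            "sex": p.sex,
            "age": p.age,
            "bmi": p.bmi,
            "smoking": int(p.smoking),
            "histology": p.histology,
            "stage_group": p.stage_group,
            "t_high": int(p.t_high),
            "n_positive": int(p.n_positive),
            "treatment": p.treatment,
            "technique": p.technique,
            "fraction_dose_class": p.fraction_dose_class,
            "overall_treatment_time": p.overall_treatment_time,
        }
        for k in COMORBIDITIES:
            row[f"comorb_{k}"] = int(bool(p.comorbidities.get(k, False)))
        for name, value in p.dose_metrics.items():
            row[name] = value
        for w in range(1, max_weeks + 1):
            row[f"week_{w}"] = (
                int(p.weekly_grades[w - 1]) if w <= len(p.weekly_grades) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Rebuild PatientRecords from a cohort table (inverse of cohort_to_frame)."""
    required = {
        "patient_id", "sex", "age", "bmi", "smoking", "histology",
        "stage_group", "treatment", "technique", "fraction_dose_class",
    }
    missing = sorted(required - set(frame.columns))
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    week_cols = sorted(
        (c for c in frame.columns if c.startswith("week_")),
        key=lambda c: int(c.split("_")[1]),
    )
    meta_cols = required | {"cohort", "t_high", "n_positive", "overall_treatment_time"}
    meta_cols |= {f"comorb_{k}" for k in COMORBIDITIES} | set(week_cols)
    metric_cols = [c for c in frame.columns if c not in meta_cols]
    records = []
    for _, row in frame.iterrows():
        grades = [int(row[c]) for c in week_cols if pd.notna(row[c])]
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                cohort=str(row.get("cohort", "development")),
                sex=str(row["sex"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                smoking=bool(int(row["smoking"])),
                comorbidities={
                    k: bool(int(row.get(f"comorb_{k}", 0))) for k in COMORBIDITIES
                },
                histology=str(row["histology"]),
                stage_group=str(row["stage_group"]),
                t_high=bool(int(row.get("t_high", 0))),
                n_positive=bool(int(row.get("n_positive", 1))),
                treatment=str(row["treatment"]),
                technique=str(row["technique"]),
                fraction_dose_class=str(row["fraction_dose_class"]),
                overall_treatment_time=float(row.get("overall_treatment_time", 50.0)),
                weekly_grades=grades,
                dose_metrics={
                    c: float(row[c]) for c in metric_cols if pd.notna(row[c])
                },
            )
        )
    return records


def save_cohort_csv(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path))
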
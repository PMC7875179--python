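"""Weekly automatic screening loop over an EHR intake stream.

Eligibility: individuals aged 14 or older, entering secondary mental
healthcare during the study window with a first non-organic, non-psychotic
index diagnosis (the eleven calculator clusters, including ARMS) and with
contact details on record.  Eligible patients are screened once, at the
first week at which every model predictor is present in the record; until
then the loop re-checks availability every week.  A screening raises a
detection when the predicted two-year psychosis risk reaches the study
threshold (5% by default, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .risk_model import DIAGNOSES, ETHNICITIES, GENDERS, RiskModel

__all__ = [
    "INELIGIBLE_DIAGNOSES",
    "PREDICTORS",
    "PatientRecord",
    "StudyConfig",
    "ScreeningLogEntry",
    "Detection",
    "check_eligibility",
    "screen_patient",
    "run_weekly_screening",
    "apply_diagnostic_lag_filter",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_screening_log_csv",
]

#: Index-diagnosis classes that fail eligibility (the screening population
#: is restricted to first NON-organic, NON-psychotic diagnoses).
INELIGIBLE_DIAGNOSES = ("Organic", "Psychotic")

#: Model predictors tracked by the weekly availability re-check.
PREDICTORS = ("age", "gender", "ethnicity", "diagnosis")

BOROUGHS = ("Lambeth", "Croydon", "Lewisham", "Southwark")

NEVER = math.inf


@dataclass(frozen=True)
class PatientRecord:
    """One patient intake as the screening loop sees it.

    ``predictor_available_week`` gives, per predictor, the week offset from
    the patient's entry week at which the predictor first appears in the
    record (0 = present at entry, ``math.inf`` = never recorded).
    ``event_time_days``/``censor_time_days`` encode the outcome process:
    exactly one of transition to psychosis or end of follow-up terminates
    observation; ``censor_time_days`` always holds the last follow-up day.
    """

    patient_id: str
    index_date: date
    age_at_index: float
    gender: str
    ethnicity: str | None
    index_diagnosis: str
    patient_contact_available: bool = True
    clinician_contact: str = "valid"  # valid | incorrect | absent
    borough: str = "Southwark"
    predictor_available_week: dict[str, float] = field(
        default_factory=lambda: {p: 0 for p in PREDICTORS}
    )
    event_time_days: int | None = None
    censor_time_days: int | None = None

    def __post_init__(self) -> None:
        if self.age_at_index < 0:
            raise ValueError(f"age_at_index must be >= 0, got {self.age_at_index}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.index_diagnosis not in DIAGNOSES + INELIGIBLE_DIAGNOSES:
            raise ValueError(f"unknown index_diagnosis {self.index_diagnosis!r}")
        if self.clinician_contact not in ("valid", "incorrect", "absent"):
            raise ValueError(f"unknown clinician_contact {self.clinician_contact!r}")
        if self.borough not in BOROUGHS:
            raise ValueError(f"unknown borough {self.borough!r}")
        if self.censor_time_days is not None and self.censor_time_days < 0:
            raise ValueError("censor_time_days must be >= 0")

    @property
    def observed_time_days(self) -> int | None:
        """Observed time under the one-terminator convention."""
        if self.event_time_days is not None:
            return self.event_time_days
        return self.censor_time_days

    @property
    def had_event(self) -> bool:
        return self.event_time_days is not None


@dataclass(frozen=True)
class StudyConfig:
    start_date: date
    end_date: date
    threshold: float = 0.05
    horizon_days: int = 730
    min_age: float = 14.0

    def __post_init__(self) -> None:
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def n_weeks(self) -> int:
        """Number of 7-day screening weeks covering the study window."""
        return (self.end_date - self.start_date).days // 7 + 1

    def week_of(self, d: date) -> int:
        """Index of the 7-day block (from start_date) containing ``d``."""
        return (d - self.start_date).days // 7


# screening statuses
INELIGIBLE = "INELIGIBLE"
AWAITING_PREDICTORS = "AWAITING_PREDICTORS"
SCREENED = "SCREENED"


@dataclass(frozen=True)
class ScreeningLogEntry:
    patient_id: str
    week_index: int
    status: str
    reason: str | None = None  # ineligibility reason
    risk: float | None = None  # present iff SCREENED
    detected: bool = False


@dataclass(frozen=True)
class Detection:
    patient_id: str
    week_index: int
    risk: float


def check_eligibility(record: PatientRecord, config: StudyConfig) -> str | None:
    """``None`` when eligible, else the first failing reason.

    Reasons: ``age`` (under 14 by default), ``diagnosis`` (organic or
    psychotic index class), ``contact`` (no patient contact details),
    ``window`` (index date outside the study period).
    """
    if record.age_at_index < config.min_age:
        return "age"
    if record.index_diagnosis in INELIGIBLE_DIAGNOSES:
        return "diagnosis"
    if not record.patient_contact_available:
        return "contact"
    if not (config.start_date <= record.index_date <= config.end_date):
        return "window"
    return None


def _predictors_complete(record: PatientRecord, weeks_since_entry: int) -> bool:
    if record.ethnicity is None:
        return False
    return all(
        record.predictor_available_week.get(p, 0) <= weeks_since_entry
        for p in PREDICTORS
    )


def screen_patient(
    record: PatientRecord, week_index: int, model: RiskModel, config: StudyConfig
) -> ScreeningLogEntry:
    """One screening attempt at study week ``week_index``.

    Risk is computed from covariates at the index date; the detection flag
    compares it (inclusively) against the study threshold.
    """
    reason = check_eligibility(record, config)
    if reason is not None:
        raise ValueError(f"record {record.patient_id} is ineligible ({reason})")
    entry_week = config.week_of(record.index_date)
    if week_index < entry_week:
        raise ValueError("cannot screen before the patient's entry week")
    if not _predictors_complete(record, week_index - entry_week):
        return ScreeningLogEntry(record.patient_id, week_index, AWAITING_PREDICTORS)
    pred = model.predict(
        record.age_at_index, record.gender, record.ethnicity, record.index_diagnosis
    )
    risk = pred.risk
    return ScreeningLogEntry(
        record.patient_id,
        week_index,
        SCREENED,
        risk=risk,
        detected=risk >= config.threshold,
    )


def run_weekly_screening(
    cohort: Sequence[PatientRecord], model: RiskModel, config: StudyConfig
) -> tuple[list[ScreeningLogEntry], list[Detection]]:
    """Iterate the weekly loop over the whole study window.

    Each eligible patient enters at the week containing their index date and
    is re-checked every subsequent week until screened or until the study
    window closes; each patient is screened at most once.  Ineligible
    patients receive a single INELIGIBLE entry at their entry week.  The log
    is append-only and a pure function of its inputs.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    log: list[ScreeningLogEntry] = []
    detections: list[Detection] = []
    pending: dict[str, PatientRecord] = {}
    by_entry_week: dict[int, list[PatientRecord]] = {}
    for rec in cohort:
        reason = check_eligibility(rec, config)
        wk = min(max(config.week_of(rec.index_date), 0), config.n_weeks - 1)
        if reason is not None:
            log.append(
                ScreeningLogEntry(rec.patient_id, wk, INELIGIBLE, reason=reason)
            )
            continue
        by_entry_week.setdefault(config.week_of(rec.index_date), []).append(rec)

    for week in range(config.n_weeks):
        for rec in by_entry_week.get(week, ()):
            pending[rec.patient_id] = rec
        for pid in list(pending):
            rec = pending[pid]
            entry = screen_patient(rec, week, model, config)
            log.append(entry)
            if entry.status == SCREENED:
                del pending[pid]
                if entry.detected:
                    detections.append(Detection(pid, week, entry.risk))
    return log, detections


def apply_diagnostic_lag_filter(
    cohort: Iterable[PatientRecord], lag_days: int = 90
) -> list[PatientRecord]:
    """Drop observed early converters (event before ``lag_days``).

    Reconstructs the retrospective model variant that excluded individuals
    transitioning within three months of the index diagnosis.  Patients
    censored early without an event are retained.
    """
    if lag_days < 0:
        raise ValueError("lag_days must be non-negative")
    return [
        rec
        for rec in cohort
        if rec.event_time_days is None or rec.event_time_days >= lag_days
    ]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id",
    "index_date",
    "age_at_index",
    "gender",
    "ethnicity",
    "index_diagnosis",
    "patient_contact",
    "clinician_contact",
    "borough",
    "avail_week_age",
    "avail_week_gender",
    "avail_week_ethnicity",
    "avail_week_diagnosis",
    "event_day",
    "censor_day",
]


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    rows = []
    for r in cohort:
        avail = r.predictor_available_week
        rows.append(
            {
                "patient_id": r.patient_id,
                "index_date": r.index_date.isoformat(),
                "age_at_index": r.age_at_index,
                "gender": r.gender,
                "ethnicity": "" if r.ethnicity is None else r.ethnicity,
                "index_diagnosis": r.index_diagnosis,
                "patient_contact": str(r.patient_contact_available).lower(),
                "clinician_contact": r.clinician_contact,
                "borough": r.borough,
                **{
                    f"avail_week_{p}": (
                        "" if math.isinf(avail.get(p, 0)) else int(avail.get(p, 0))
                    )
                    for p in PREDICTORS
                },
                "event_day": "" if r.event_time_days is None else r.event_time_days,
                "censor_day": "" if r.censor_time_days is None else r.censor_time_days,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        avail = {
            p: (NEVER if getattr(row, f"avail_week_{p}") == "" else int(getattr(row, f"avail_week_{p}")))
            for p in PREDICTORS
        }
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                index_date=date.fromisoformat(row.index_date),
                age_at_index=float(row.age_at_index),
                gender=row.gender,
                ethnicity=None if row.ethnicity == "" else row.ethnicity,
                index_diagnosis=row.index_diagnosis,
                patient_contact_available=row.patient_contact == "true",
                clinician_contact=row.clinician_contact,
                borough=row.borough,
                predictor_available_week=avail,
                event_time_days=None if row.event_day == "" else int(row.event_day),
                censor_time_days=None if row.censor_day == "" else int(row.censor_day),
            )
        )
    return records


def write_screening_log_csv(log: Sequence[ScreeningLogEntry], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in log],
            "week": [e.week_index for e in log],
            "status": [
                e.status if e.reason is None else f"{e.status}({e.reason})" for e in log
            ],
            "risk": ["" if e.risk is None else f"{e.risk:.6f}" for e in log],
            "detected": [str(e.detected).lower() for e in log],
        }
    )
    df.to_csv(path, index=False)
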
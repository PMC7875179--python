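"""Synthetic EHR cohort generation.

The generator emulates the intake stream the screening loop consumed:
demographic and index-diagnosis marginals matching the screened
population (n = 3722) of the deployment, entry dates spread over the study
window, roughly 35% of patients with at least one model predictor missing
at entry (completed by a weekly memoryless process), time-to-psychosis
outcomes drawn from the risk calculator itself by inverse-transform
sampling, administrative censoring plus exponential attrition, and
clinician response behaviour parameterised per alert channel.

Only marginal frequencies are published, so factors are sampled
independently (a joint table can be supplied instead).  The default
baseline hazard is calibrated so the synthetic screened population's
six-month psychosis incidence matches the observed 1.04%; the detected
stratum's incidence then emerges from the model rather than being set.

A deterministic fixture reproducing every printed alert-funnel count
(117 detections through to 39 referrals, channel distribution 33/20/6/30,
both odds-ratio tables, and the six-month follow-up strata) is also built
here; it backs regression tests and the report demo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alert_workflow import AlertCase, WorkflowConfig
from .risk_model import (
    BaselineSurvival,
    ModelCoefficients,
    RiskModel,
    linear_predictor,
)
from .screening_engine import PREDICTORS, PatientRecord

__all__ = [
    "SCREENED_POPULATION_COUNTS",
    "CohortConfig",
    "generate_cohort",
    "sample_event_times",
    "calibrate_baseline_to_incidence",
    "PublishedFunnelFixture",
    "make_published_funnel_fixture",
]

#: Screened-population counts (n = 3722) behind the default sampling
#: frequencies.  The diagnosis counts sum exactly to 3722; ARMS has no
#: screened count and so defaults to frequency 0.
SCREENED_POPULATION_COUNTS = {
    "gender": {"male": 1412, "female": 3722 - 1412},
    "ethnicity": {"White": 2249, "Black": 660, "Asian": 249, "Mixed": 166, "Other": 398},
    "diagnosis": {
        "ARMS": 0,
        "Acute-transient-psychotic": 46,
        "Bipolar-mood": 99,
        "Non-bipolar-mood": 1076,
        "Personality": 181,
        "Developmental": 57,
        "Childhood-adolescence-onset": 240,
        "Physiological-syndromes": 237,
        "Mental-retardation": 43,
        "Substance-use": 545,
        "Anxiety": 1198,
    },
}


def _freq(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 3722
    gender_freq: dict[str, float] = field(
        default_factory=lambda: _freq(SCREENED_POPULATION_COUNTS["gender"])
    )
    ethnicity_freq: dict[str, float] = field(
        default_factory=lambda: _freq(SCREENED_POPULATION_COUNTS["ethnicity"])
    )
    diagnosis_freq: dict[str, float] = field(
        default_factory=lambda: _freq(SCREENED_POPULATION_COUNTS["diagnosis"])
    )
    age_mean: float = 37.5
    age_sd: float = 18.4
    min_age: float = 14.0
    entry_start: date = date(2018, 1, 1)
    entry_end: date = date(2018, 12, 31)
    missing_fraction: float = 0.35  # incomplete predictors at entry
    weekly_completion_prob: float = 0.25  # memoryless weekly completion
    contact_available_frac: float = 1.0
    clinician_absent_frac: float = 2 / 117
    clinician_incorrect_frac: float = 0.05
    borough_freq: dict[str, float] = field(
        default_factory=lambda: {
            "Lambeth": 34 / 115,
            "Croydon": 27 / 115,
            "Lewisham": 27 / 115,
            "Southwark": 27 / 115,
        }
    )
    true_betas: ModelCoefficients = field(default_factory=ModelCoefficients.published)
    baseline: BaselineSurvival | None = None  # None -> calibrated (see below)
    target_six_month_incidence: float = 0.0104  # calibration anchor
    followup_days: int = 730  # administrative censoring after entry
    attrition_hazard: float = 1.2e-4  # per-day loss to follow-up
    behaviour: WorkflowConfig = field(default_factory=WorkflowConfig)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, freqs in (
            ("gender_freq", self.gender_freq),
            ("ethnicity_freq", self.ethnicity_freq),
            ("diagnosis_freq", self.diagnosis_freq),
            ("borough_freq", self.borough_freq),
        ):
            if any(v < 0 for v in freqs.values()) or abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for name, frac in (
            ("missing_fraction", self.missing_fraction),
            ("weekly_completion_prob", self.weekly_completion_prob),
            ("contact_available_frac", self.contact_available_frac),
            ("clinician_absent_frac", self.clinician_absent_frac),
            ("clinician_incorrect_frac", self.clinician_incorrect_frac),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.entry_start > self.entry_end:
            raise ValueError("entry_start must not follow entry_end")
        if self.missing_fraction > 0 and self.weekly_completion_prob <= 0:
            raise ValueError("weekly_completion_prob must be positive with missingness")

    def resolved_baseline(self) -> BaselineSurvival:
        if self.baseline is not None:
            return self.baseline
        return calibrate_baseline_to_incidence(self)


def calibrate_baseline_to_incidence(
    config: "CohortConfig",
    at_days: int = 183,
    n_quadrature: int = 100_000,
) -> BaselineSurvival:
    """Exponential baseline matched to a population incidence anchor.

    Solves for the rate at which the expected event proportion of the
    configured covariate mixture at ``at_days`` equals
    ``config.target_six_month_incidence``.  The expectation uses a fixed
    internal quasi-sample of the mixture, so the result is deterministic
    for a given configuration.
    """
    rng = np.random.default_rng(170_504_033)  # fixed internal stream
    n = n_quadrature
    ages = _truncated_normal(rng, config.age_mean, config.age_sd, config.min_age, n)
    male = rng.random(n) < config.gender_freq.get("male", 0.0)
    eth = rng.choice(
        list(config.ethnicity_freq), p=list(config.ethnicity_freq.values()), size=n
    )
    dia = rng.choice(
        list(config.diagnosis_freq), p=list(config.diagnosis_freq.values()), size=n
    )
    c = config.true_betas
    lp = (
        c.beta_age * ages
        + np.where(male, c.beta_male + c.beta_age_male * ages, 0.0)
        + np.vectorize(c.beta_ethnicity.get)(eth)
        + np.vectorize(c.beta_diagnosis.get)(dia)
    )
    elp = np.exp(lp)
    target = config.target_six_month_incidence

    def gap(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * at_days * elp))) - target

    rate = brentq(gap, 1e-10, 1.0)
    return BaselineSurvival(form="exponential", rate=rate)


def _truncated_normal(rng, mean, sd, lower, n) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def generate_cohort(config: CohortConfig, seed: int) -> list[PatientRecord]:
    """Sample a cohort of patient intakes (outcomes not yet assigned).

    Factors are sampled independently from the configured marginals; ages
    from a normal truncated below at ``min_age``.  With probability
    ``missing_fraction`` an intake is incomplete at entry: ethnicity and/or
    the index-diagnosis cluster (the two fields that arrive late in real
    records) become available after a geometric number of weeks with weekly
    completion probability ``weekly_completion_prob``.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = config.n_patients
    ages = _truncated_normal(rng, config.age_mean, config.age_sd, config.min_age, n)
    genders = rng.choice(list(config.gender_freq), p=list(config.gender_freq.values()), size=n)
    eths = rng.choice(
        list(config.ethnicity_freq), p=list(config.ethnicity_freq.values()), size=n
    )
    dias = rng.choice(
        list(config.diagnosis_freq), p=list(config.diagnosis_freq.values()), size=n
    )
    boroughs = rng.choice(
        list(config.borough_freq), p=list(config.borough_freq.values()), size=n
    )
    span = (config.entry_end - config.entry_start).days
    entry_offsets = rng.integers(0, span + 1, size=n)
    contact = rng.random(n) < config.contact_available_frac
    u_clin = rng.random(n)
    incomplete = rng.random(n) < config.missing_fraction
    which = rng.random(n)  # which late field(s): eth / diag / both
    delays_eth = rng.geometric(config.weekly_completion_prob or 1.0, size=n)
    delays_dia = rng.geometric(config.weekly_completion_prob or 1.0, size=n)

    records = []
    width = len(str(max(n, 1)))
    for i in range(n):
        if u_clin[i] < config.clinician_absent_frac:
            clin = "absent"
        elif u_clin[i] < config.clinician_absent_frac + config.clinician_incorrect_frac:
            clin = "incorrect"
        else:
            clin = "valid"
        avail = {p: 0 for p in PREDICTORS}
        if incomplete[i]:
            if which[i] < 0.5:
                avail["ethnicity"] = int(delays_eth[i])
            elif which[i] < 0.8:
                avail["diagnosis"] = int(delays_dia[i])
            else:
                avail["ethnicity"] = int(delays_eth[i])
                avail["diagnosis"] = int(delays_dia[i])
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                index_date=config.entry_start + timedelta(days=int(entry_offsets[i])),
                age_at_index=float(ages[i]),
                gender=str(genders[i]),
                ethnicity=str(eths[i]),
                index_diagnosis=str(dias[i]),
                patient_contact_available=bool(contact[i]),
                clinician_contact=clin,
                borough=str(boroughs[i]),
                predictor_available_week=avail,
            )
        )
    return records


def sample_event_times(
    cohort: Sequence[PatientRecord],
    model: RiskModel,
    config: CohortConfig,
    seed: int,
) -> list[PatientRecord]:
    """Attach outcomes drawn from the model's own survival process.

    For each patient, a latent transition time T with survivor function
    S0(t)^exp(lp) is drawn by inverse transform (exponential baseline:
    T = -ln U / (rate * e^lp)); censoring is the earlier of administrative
    follow-up end and an exponential attrition draw.  Whichever of T and
    the censoring time comes first terminates follow-up.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    baseline = model.baseline
    out = []
    n = len(cohort)
    u_event = rng.random(n)
    u_attr = rng.random(n)
    for i, rec in enumerate(cohort):
        lp = linear_predictor(
            rec.age_at_index, rec.gender, rec.ethnicity, rec.index_diagnosis, model.coeffs
        )
        elp = math.exp(lp)
        if baseline.form == "exponential":
            lam = baseline.rate * elp
            t_event = math.inf if lam == 0 else -math.log(u_event[i]) / lam
        else:
            # smallest step time with S0(t)^elp <= U; beyond last step: no event
            t_event = math.inf
            for st, ss in baseline.steps:
                if ss**elp <= u_event[i]:
                    t_event = st
                    break
        if config.attrition_hazard > 0:
            t_attr = -math.log(u_attr[i]) / config.attrition_hazard
        else:
            t_attr = math.inf
        t_cens = min(config.followup_days, t_attr)
        if t_event <= t_cens:
            day = max(1, math.ceil(t_event))
            out.append(replace(rec, event_time_days=day, censor_time_days=day))
        else:
            day = max(1, math.floor(min(t_cens, config.followup_days)))
            out.append(replace(rec, event_time_days=None, censor_time_days=day))
    return out


# ---------------------------------------------------------------------------
# Deterministic funnel fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PublishedFunnelFixture:
    """The published alert funnel, frozen as data.

    ``cases``: 117 detections — 2 without clinician contact, 115 prompted,
    89 responses over channels (33, 20, 6, 30), 18 exclusions, 39 referrals
    among 71 decisions; personalization and outreach flags reproduce both
    published response 2x2 tables.  ``screened_followup`` and
    ``detected_followup`` carry the six-month follow-up strata (3640 of
    3722 followed with 38 transitions; 101 of 115 followed with 9; 49
    followed among the not-referred with 3).  ``age_summary`` holds the
    published screened/detected age summaries for the t-test block.
    """

    cases: list[AlertCase]
    cohort: list[PatientRecord]
    screened_followup: pd.DataFrame
    detected_followup: pd.DataFrame
    age_summary: dict[str, tuple[float, float, int]]


def _fixture_channel_blocks():
    # per channel: (n, named, lambeth, response_week)
    return [
        ("EMAIL1", 33, 25, 11, 0),
        ("EMAIL2", 20, 14, 7, 1),
        ("EMAIL3", 6, 5, 2, 2),
        ("PHONE", 30, 17, 9, 3),
        ("NONE", 26, 14, 5, None),  # never responded
    ]


def make_published_funnel_fixture() -> PublishedFunnelFixture:
    """Build the deterministic 117-case funnel fixture (seed independent)."""
    from . import alert_workflow as aw

    cases: list[AlertCase] = []
    pid = 0

    def next_id() -> str:
        nonlocal pid
        pid += 1
        return f"D{pid:03d}"

    for _ in range(2):  # no clinician contact: never prompted
        cases.append(
            AlertCase(patient_id=next_id(), detection_week=0, state=aw.NO_CONTACT)
        )
    responded_cases: list[AlertCase] = []
    nonresponded: list[AlertCase] = []
    for channel, n, n_named, n_lambeth, week in _fixture_channel_blocks():
        for j in range(n):
            personal = "patient_name" if j < n_named else "trust_id"
            outreach = j < n_lambeth
            if channel == "NONE":
                nonresponded.append(
                    AlertCase(
                        patient_id=next_id(),
                        detection_week=0,
                        state=aw.NO_RESPONSE,
                        personalization=personal,
                        outreach=outreach,
                    )
                )
            else:
                responded_cases.append(
                    AlertCase(
                        patient_id=next_id(),
                        detection_week=0,
                        state=aw.RESPONDED,
                        personalization=personal,
                        outreach=outreach,
                        response_channel=channel,
                        response_week=week,
                    )
                )

    # 18 exclusions among the 89 responses, then 39 referrals of 71 decisions
    exclusions = (
        ["moved_out"] * 10
        + ["organic_condition"] * 4
        + ["language"] * 2
        + ["psychosis_from_collateral"]
        + ["declined"]
    )
    resolved: list[AlertCase] = []
    for i, case in enumerate(responded_cases):
        if i % 5 == 0 and exclusions:  # spread exclusions across channels
            resolved.append(
                replace(case, exclusion_reason=exclusions.pop(0), referral=aw.NA)
            )
        else:
            resolved.append(case)
    still_open = [c for c in resolved if c.exclusion_reason == "none"]
    referred_ids = {c.patient_id for c in still_open[:39]}
    final_cases = []
    n_not_ref = 0
    for c in resolved:
        if c.exclusion_reason != "none":
            final_cases.append(c)
        elif c.patient_id in referred_ids:
            final_cases.append(replace(c, referral=aw.REFERRED))
        else:
            n_not_ref += 1
            reason = "acute_phase" if n_not_ref <= 22 else "other"
            final_cases.append(
                replace(c, referral=aw.NOT_REFERRED, nonreferral_reason=reason)
            )
    cases.extend(final_cases)
    cases.extend(nonresponded)

    # --- six-month follow-up strata -----------------------------------
    # screened: 3722 patients, 3640 followed, 38 transitions by day 183
    n_scr, n_scr_fu, n_scr_ev = 3722, 3640, 38
    screened = pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:04d}" for i in range(n_scr)],
            "followed": [True] * n_scr_fu + [False] * (n_scr - n_scr_fu),
            "event": [True] * n_scr_ev + [False] * (n_scr - n_scr_ev),
            "time_days": [90] * n_scr_ev + [183] * (n_scr_fu - n_scr_ev) + [0] * (n_scr - n_scr_fu),
        }
    )

    # detected: the 115 prompted; 101 followed, 9 transitions.  Referral
    # strata conserve the printed 3-of-49 not-referred transitions.
    prompted = [c for c in cases if c.state != aw.NO_CONTACT]
    groups = {"referred": [], "excluded": [], "not_referred": []}
    for c in prompted:
        if c.exclusion_reason != "none":
            groups["excluded"].append(c.patient_id)
        elif c.referral == aw.REFERRED:
            groups["referred"].append(c.patient_id)
        else:  # NOT_REFERRED decisions and never-responded cases
            groups["not_referred"].append(c.patient_id)
    plan = {  # group -> (n_followed, n_events)
        "referred": (36, 3),
        "excluded": (16, 3),
        "not_referred": (49, 3),
    }
    rows = []
    for grp, ids in groups.items():
        n_fu, n_ev = plan[grp]
        for k, pid_ in enumerate(ids):
            followed = k < n_fu
            event = k < n_ev
            rows.append(
                {
                    "patient_id": pid_,
                    "group": grp,
                    "followed": followed,
                    "event": event and followed,
                    "time_days": 90 if (event and followed) else (183 if followed else 0),
                }
            )
    detected = pd.DataFrame(rows)

    cohort = _fixture_cohort(cases, detected)
    return PublishedFunnelFixture(
        cases=cases,
        cohort=cohort,
        screened_followup=screened,
        detected_followup=detected,
        age_summary={
            "screened": (37.51, 18.44, 3722),
            "detected": (39.05, 18.27, 88),
        },
    )


def _fixture_cohort(cases, detected: pd.DataFrame) -> list[PatientRecord]:
    """Synthetic patient records backing the fixture cases (deterministic)."""
    followup = detected.set_index("patient_id")
    records = []
    for i, c in enumerate(cases):
        if c.patient_id in followup.index:
            row = followup.loc[c.patient_id]
            event = bool(row["event"])
            t = int(row["time_days"])
            event_day = t if event else None
            censor_day = t
        else:  # the two no-contact detections carry no follow-up
            event_day, censor_day = None, 0
        records.append(
            PatientRecord(
                patient_id=c.patient_id,
                index_date=date(2018, 1, 1) + timedelta(days=7 * (i % 10)),
                age_at_index=25.0 + (i % 30),
                gender="male" if i % 2 else "female",
                ethnicity=("Black", "White", "Asian", "Mixed", "Other")[i % 5],
                index_diagnosis="Acute-transient-psychotic",
                patient_contact_available=True,
                clinician_contact="absent" if c.state == "NO_CONTACT" else "valid",
                borough="Lambeth" if c.outreach else "Croydon",
                predictor_available_week={p: 0 for p in PREDICTORS},
                event_time_days=event_day,
                censor_time_days=censor_day,
            )
        )
    return records
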
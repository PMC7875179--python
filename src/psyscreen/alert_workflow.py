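"""Clinician alert-escalation state machine.

Every detection opens a case against the patient's responsible clinician.
If the EHR holds no clinician contact the case terminates immediately
(NO_CONTACT, no prompt sent).  Otherwise prompts escalate through four
sequential channels at one-week gaps — a first email, a reminder email, a
third email to the alternate contact (care coordinator or GP), then phone
calls — and the case closes at the first response or, after the phone
stage, as NO_RESPONSE.  Responded cases are then resolved: the clinician
may report the patient as excluded (moved out of catchment, organic
condition, insufficient English, psychosis evident from collateral
information, declined), and surviving cases get a referral decision.

Response behaviour is Bernoulli per stage; alert personalization (patient
name vs anonymised trust identifier in the email) and borough outreach act
as multiplicative odds modifiers on every stage's response probability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screening_engine import Detection, PatientRecord

__all__ = [
    "CHANNELS",
    "EXCLUSION_REASONS",
    "AlertCase",
    "WorkflowConfig",
    "FunnelCounts",
    "open_case",
    "advance_case",
    "resolve_case",
    "run_alert_workflow",
    "funnel_summary",
    "effective_response_prob",
    "write_case_log_csv",
    "read_case_log_csv",
]

#: Escalation order; one stage per ``step_gap_weeks``.
CHANNELS = ("EMAIL1", "EMAIL2", "EMAIL3", "PHONE")

# case states
NO_CONTACT = "NO_CONTACT"
EMAIL1_SENT = "EMAIL1_SENT"
EMAIL2_SENT = "EMAIL2_SENT"
EMAIL3_SENT = "EMAIL3_SENT"
PHONE_STAGE = "PHONE_STAGE"
RESPONDED = "RESPONDED"
NO_RESPONSE = "NO_RESPONSE"

_STAGE_STATE = {
    "EMAIL1": EMAIL1_SENT,
    "EMAIL2": EMAIL2_SENT,
    "EMAIL3": EMAIL3_SENT,
    "PHONE": PHONE_STAGE,
}
_TERMINAL = (NO_CONTACT, RESPONDED, NO_RESPONSE)

EXCLUSION_REASONS = (
    "none",
    "moved_out",
    "organic_condition",
    "language",
    "psychosis_from_collateral",
    "declined",
    "other",
)

REFERRED = "REFERRED"
NOT_REFERRED = "NOT_REFERRED"
NA = "NA"


@dataclass(frozen=True)
class AlertCase:
    patient_id: str
    detection_week: int
    state: str = EMAIL1_SENT
    personalization: str = "patient_name"  # patient_name | trust_id
    outreach: bool = False  # borough-level clinician outreach (Lambeth)
    response_channel: str = "NONE"
    response_week: int | None = None
    exclusion_reason: str = "none"
    referral: str = NA
    nonreferral_reason: str = ""

    def __post_init__(self) -> None:
        if self.personalization not in ("patient_name", "trust_id"):
            raise ValueError(f"unknown personalization {self.personalization!r}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")
        if self.state == RESPONDED and self.response_channel == "NONE":
            raise ValueError("a RESPONDED case must record its channel")
        if self.exclusion_reason != "none" and self.referral != NA:
            raise ValueError("excluded cases receive no referral decision")

    @property
    def prompted(self) -> bool:
        return self.state != NO_CONTACT

    @property
    def current_channel(self) -> str | None:
        for ch, st in _STAGE_STATE.items():
            if st == self.state:
                return ch
        return None

    @property
    def is_terminal(self) -> bool:
        return self.state in _TERMINAL


# Per-channel base response probabilities (trust-id alert, no outreach),
# solved so that — with the deployed naming/outreach mix (75/115 named,
# 34/115 Lambeth) and the published odds effects — the expected responder
# counts per channel among 115 prompts equal the observed 33/20/6/30.
_DEFAULT_RESPONSE_PROB = {
    "EMAIL1": 0.1504,
    "EMAIL2": 0.1314,
    "EMAIL3": 0.0490,
    "PHONE": 0.3883,
}

# Exclusion mix scaled from the reported exclusion-category breakdown to a
# total exclusion probability of 18/89 among responded cases.
_DEFAULT_EXCLUSION_PROBS = {
    "moved_out": 18 / 89 * 10 / 18,
    "organic_condition": 18 / 89 * 4 / 18,
    "language": 18 / 89 * 2 / 18,
    "psychosis_from_collateral": 18 / 89 * 1 / 18,
    "declined": 18 / 89 * 1 / 18,
}


@dataclass(frozen=True)
class WorkflowConfig:
    step_gap_weeks: int = 1
    response_prob: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RESPONSE_PROB)
    )
    personalization_effect: float = 2.35  # odds multiplier, patient_name alerts
    outreach_effect: float = 2.02  # odds multiplier, outreach boroughs
    referral_prob: float = 39 / 71
    exclusion_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSION_PROBS)
    )
    acute_phase_frac: float = 0.7  # share of non-referrals tagged acute_phase
    personalization_name_frac: float = 75 / 115  # share of alerts using names

    def __post_init__(self) -> None:
        if self.step_gap_weeks < 1:
            raise ValueError("step_gap_weeks must be >= 1")
        if set(self.response_prob) != set(CHANNELS):
            raise ValueError(f"response_prob must cover exactly {CHANNELS}")
        for name, p in {
            **self.response_prob,
            "referral_prob": self.referral_prob,
            **self.exclusion_probs,
            "acute_phase_frac": self.acute_phase_frac,
            "personalization_name_frac": self.personalization_name_frac,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.personalization_effect <= 0 or self.outreach_effect <= 0:
            raise ValueError("odds modifiers must be positive")
        if sum(self.exclusion_probs.values()) > 1.0:
            raise ValueError("exclusion probabilities sum past 1")
        unknown = set(self.exclusion_probs) - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown exclusion categories {sorted(unknown)}")


def effective_response_prob(case: AlertCase, channel: str, config: WorkflowConfig) -> float:
    """Channel response probability with odds modifiers applied."""
    p = config.response_prob[channel]
    odds = p / (1.0 - p) if p < 1.0 else np.inf
    if case.personalization == "patient_name":
        odds *= config.personalization_effect
    if case.outreach:
        odds *= config.outreach_effect
    return 1.0 if np.isinf(odds) else odds / (1.0 + odds)


def open_case(
    detection: Detection,
    record: PatientRecord,
    personalization: str = "patient_name",
) -> AlertCase:
    """Open the escalation for one detection.

    No clinician contact on the EHR means no prompt is ever sent; an
    ``incorrect`` contact still receives the first email (the third email is
    routed to the alternate contact, which the state machine treats
    identically).
    """
    state = NO_CONTACT if record.clinician_contact == "absent" else EMAIL1_SENT
    return AlertCase(
        patient_id=detection.patient_id,
        detection_week=detection.week_index,
        state=state,
        personalization=personalization,
        outreach=record.borough == "Lambeth",
    )


def advance_case(
    case: AlertCase, current_week: int, response_draw: float, config: WorkflowConfig
) -> AlertCase:
    """Resolve one escalation stage with a uniform draw in [0, 1)."""
    if case.is_terminal:
        raise ValueError(f"case {case.patient_id} is terminal ({case.state})")
    channel = case.current_channel
    if response_draw < effective_response_prob(case, channel, config):
        return replace(
            case, state=RESPONDED, response_channel=channel, response_week=current_week
        )
    nxt = CHANNELS.index(channel) + 1
    if nxt == len(CHANNELS):
        return replace(case, state=NO_RESPONSE)
    return replace(case, state=_STAGE_STATE[CHANNELS[nxt]])


def resolve_case(
    case: AlertCase,
    exclusion_draw: float,
    referral_draw: float,
    reason_draw: float = 1.0,
    config: WorkflowConfig | None = None,
) -> AlertCase:
    """Exclusion check, then the referral decision, for a responded case."""
    if case.state != RESPONDED:
        raise ValueError("only RESPONDED cases can be resolved")
    config = config or WorkflowConfig()
    cum = 0.0
    for reason in EXCLUSION_REASONS:
        p = config.exclusion_probs.get(reason, 0.0)
        if p and exclusion_draw < cum + p:
            return replace(case, exclusion_reason=reason, referral=NA)
        cum += p
    if referral_draw < config.referral_prob:
        return replace(case, referral=REFERRED)
    reason = "acute_phase" if reason_draw < config.acute_phase_frac else "other"
    return replace(case, referral=NOT_REFERRED, nonreferral_reason=reason)


def run_alert_workflow(
    detections: Sequence[Detection],
    records_by_id: dict[str, PatientRecord],
    config: WorkflowConfig,
    rng: np.random.Generator,
) -> list[AlertCase]:
    """Walk every detection through escalation and resolution.

    Alert personalization is assigned per case with probability
    ``personalization_name_frac`` (the deployment switched from trust
    identifiers to patient names part-way through); outreach follows the
    patient's borough.  Draws are consumed in detection order, one stream.
    """
    cases = []
    for det in detections:
        rec = records_by_id[det.patient_id]
        use_name = rng.random() < config.personalization_name_frac
        case = open_case(
            det, rec, personalization="patient_name" if use_name else "trust_id"
        )
        week = det.week_index
        while not case.is_terminal:
            case = advance_case(case, week, rng.random(), config)
            week += config.step_gap_weeks
        if case.state == RESPONDED:
            case = resolve_case(
                case, rng.random(), rng.random(), rng.random(), config
            )
        cases.append(case)
    return cases


@dataclass(frozen=True)
class FunnelCounts:
    detected: int
    no_contact: int
    prompted: int
    responded: int
    excluded: int
    decisions: int
    referred: int

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.detected,
            self.no_contact,
            self.prompted,
            self.responded,
            self.excluded,
            self.decisions,
            self.referred,
        )


def funnel_summary(cases: Iterable[AlertCase]) -> tuple[FunnelCounts, dict[str, int]]:
    """Stage-by-stage counts plus the per-channel response distribution."""
    cases = list(cases)
    no_contact = sum(c.state == NO_CONTACT for c in cases)
    responded = [c for c in cases if c.state == RESPONDED]
    excluded = sum(c.exclusion_reason != "none" for c in responded)
    referred = sum(c.referral == REFERRED for c in responded)
    channels = Counter(c.response_channel for c in responded)
    counts = FunnelCounts(
        detected=len(cases),
        no_contact=no_contact,
        prompted=len(cases) - no_contact,
        responded=len(responded),
        excluded=excluded,
        decisions=len(responded) - excluded,
        referred=referred,
    )
    return counts, {ch: channels.get(ch, 0) for ch in CHANNELS}


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CASE_COLUMNS = [
    "patient_id",
    "state",
    "response_channel",
    "response_week",
    "personalization",
    "outreach",
    "exclusion_reason",
    "referral",
    "nonreferral_reason",
    "detection_week",
]


def write_case_log_csv(cases: Sequence[AlertCase], path) -> None:
    rows = [
        {
            "patient_id": c.patient_id,
            "state": c.state,
            "response_channel": c.response_channel,
            "response_week": "" if c.response_week is None else c.response_week,
            "personalization": c.personalization,
            "outreach": str(c.outreach).lower(),
            "exclusion_reason": c.exclusion_reason,
            "referral": c.referral,
            "nonreferral_reason": c.nonreferral_reason,
            "detection_week": c.detection_week,
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=_CASE_COLUMNS).to_csv(path, index=False)


def read_case_log_csv(path) -> list[AlertCase]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        AlertCase(
            patient_id=row.patient_id,
            detection_week=int(row.detection_week),
            state=row.state,
            personalization=row.personalization,
            outreach=row.outreach == "true",
            response_channel=row.response_channel,
            response_week=None if row.response_week == "" else int(row.response_week),
            exclusion_reason=row.exclusion_reason,
            referral=row.referral,
            nonreferral_reason=row.nonreferral_reason,
        )
        for row in df.itertuples(index=False)
    ]
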
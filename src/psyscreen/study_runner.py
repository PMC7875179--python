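"""End-to-end study orchestration.

``run_study`` wires cohort generation (or a supplied cohort CSV, or the
packaged funnel fixture) through the weekly screening loop, the alert
workflow and the feasibility statistics into one reproducible run: a
screening log, a case log, a report JSON and a run manifest, all
deterministic given the master seed.  ``replicate_study`` repeats the
simulation under per-replicate seeds derived from the master seed and
summarises the distribution of each feasibility metric.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .alert_workflow import WorkflowConfig, funnel_summary, run_alert_workflow, write_case_log_csv
from .cohort_synth import (
    CohortConfig,
    PublishedFunnelFixture,
    generate_cohort,
    make_published_funnel_fixture,
    sample_event_times,
)
from .feasibility_stats import (
    adherence_proportion,
    channel_distribution,
    cumulative_incidence_at,
    fisher_exact_2x2,
    km_curve,
    logrank_test,
    outreach_table,
    personalization_table,
    t_from_summary,
)
from .risk_model import (
    BaselineSurvival,
    ModelCoefficients,
    RiskModel,
    default_model,
    load_model,
)
from .screening_engine import (
    StudyConfig,
    read_cohort_csv,
    run_weekly_screening,
    write_cohort_csv,
    write_screening_log_csv,
)

__all__ = ["StudySpec", "load_study_spec", "run_study", "replicate_study"]

log = logging.getLogger("psyscreen")

REPORT_SCHEMA_VERSION = 1

SIX_MONTHS_DAYS = 183


@dataclass(frozen=True)
class StudySpec:
    """Parsed study configuration: study window + model + cohort + workflow."""

    study: StudyConfig
    model: RiskModel
    cohort: CohortConfig
    workflow: WorkflowConfig
    cohort_csv: str | None = None  # load instead of simulate
    fixture: str | None = None  # "published-funnel" replaces simulation entirely


def _dates(obj, *names):
    return {n: date.fromisoformat(obj[n]) for n in names}


def load_study_spec(path) -> StudySpec:
    """Parse and validate the YAML study configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return study_spec_from_dict(raw)


def study_spec_from_dict(raw: dict) -> StudySpec:
    study_raw = dict(raw.get("study", {}))
    fixture = study_raw.pop("fixture", None)
    cohort_csv = study_raw.pop("cohort_csv", None)
    study = StudyConfig(
        **_dates(study_raw, "start_date", "end_date"),
        **{
            k: v
            for k, v in study_raw.items()
            if k in ("threshold", "horizon_days", "min_age")
        },
    )
    model_raw = raw.get("model", {}) or {}
    if "path" in model_raw:
        model = load_model(model_raw["path"])
    else:
        model = default_model()
    if "baseline_rate" in model_raw:
        model = dataclasses.replace(
            model,
            baseline=BaselineSurvival(
                form="exponential", rate=float(model_raw["baseline_rate"])
            ),
        )

    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("entry_start", "entry_end"):
        if key in cohort_raw:
            cohort_raw[key] = date.fromisoformat(cohort_raw[key])
    if "true_betas" in cohort_raw:
        cohort_raw["true_betas"] = ModelCoefficients.from_vector(cohort_raw["true_betas"])
    if "baseline_rate" in cohort_raw:
        cohort_raw["baseline"] = BaselineSurvival(
            form="exponential", rate=float(cohort_raw.pop("baseline_rate"))
        )
    workflow = WorkflowConfig(**raw.get("workflow", {}))
    cohort_raw.pop("behaviour", None)
    cohort = CohortConfig(**cohort_raw, behaviour=workflow)
    if model_raw.get("baseline") == "cohort":
        # score with the same baseline the outcome generator is calibrated
        # to, making absolute risks and simulated outcomes self-consistent
        model = dataclasses.replace(model, baseline=cohort.resolved_baseline())
    return StudySpec(
        study=study,
        model=model,
        cohort=cohort,
        workflow=workflow,
        cohort_csv=cohort_csv,
        fixture=fixture,
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def _or_block(table: np.ndarray) -> dict:
    try:
        res = fisher_exact_2x2(table)
    except ValueError:
        return {"table": table.tolist(), "odds_ratio": None, "ci95": None, "p_value": None}
    return {
        "table": table.tolist(),
        "odds_ratio": None if res.estimate is None else round(res.estimate, 2),
        "ci95": [res.ci_low, res.ci_high] if res.estimate is not None else None,
        "p_value": res.p_value,
    }


def _incidence_block(times, events, t_days=SIX_MONTHS_DAYS) -> dict:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    keep = times > 0
    times, events = times[keep], events[keep]
    if times.size == 0 or not events.any():
        return {"n": int(times.size), "undefined": True}
    curve = km_curve(times, events)
    inc = cumulative_incidence_at(curve, t_days, all_times=times)
    return {
        "n": int(times.size),
        "t_days": t_days,
        "incidence": inc.incidence,
        "ci95": [inc.ci_low, inc.ci_high],
        "n_at_risk": inc.n_at_risk,
        "extrapolated": inc.extrapolated,
    }


def _followup_blocks(screened_times, screened_events, followed_mask) -> dict:
    n = len(screened_times)
    n_followed = int(np.sum(followed_mask))
    ev = np.asarray(screened_events, dtype=bool) & np.asarray(followed_mask, dtype=bool)
    block = {
        "n": n,
        "n_followed": n_followed,
        "followup_proportion": n_followed / n if n else None,
        "n_events_six_months": int(ev.sum()),
        "six_month_proportion": float(ev.sum() / n_followed) if n_followed else None,
    }
    return block


def build_report_from_fixture(fix: PublishedFunnelFixture) -> dict:
    """Feasibility report computed from the packaged funnel fixture."""
    counts, channels = funnel_summary(fix.cases)
    adherence = adherence_proportion(fix.cases)
    dist = channel_distribution(fix.cases)

    scr = fix.screened_followup
    det = fix.detected_followup
    det_fu = det[det["followed"]]
    scr_fu = scr[scr["followed"]]
    notref = det[det["group"] == "not_referred"]
    notref_fu = notref[notref["followed"]]

    m1, s1, n1 = fix.age_summary["screened"]
    m2, s2, n2 = fix.age_summary["detected"]
    t_res = t_from_summary(m1, s1, n1, m2, s2, n2)

    lr = logrank_test(
        scr_fu["time_days"].to_numpy(),
        scr_fu["event"].to_numpy(),
        det_fu["time_days"].to_numpy(),
        det_fu["event"].to_numpy(),
    )

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": "published-funnel-fixture",
        "funnel": {**dataclasses.asdict(counts), "channels": channels},
        "adherence": adherence,
        "channel_distribution": {
            ch: {"count": n, "share": share} for ch, (n, share) in dist.items()
        },
        "odds_ratios": {
            "personalization": _or_block(personalization_table(fix.cases)),
            "outreach": _or_block(outreach_table(fix.cases)),
        },
        "followup": {
            "screened": _followup_blocks(
                scr["time_days"], scr["event"], scr["followed"]
            ),
            "detected": _followup_blocks(
                det["time_days"], det["event"], det["followed"]
            ),
            "detected_not_referred": _followup_blocks(
                notref["time_days"], notref["event"], notref["followed"]
            ),
        },
        "incidence": {
            "screened": _incidence_block(
                scr_fu["time_days"].to_numpy(), scr_fu["event"].to_numpy()
            ),
            "detected": _incidence_block(
                det_fu["time_days"].to_numpy(), det_fu["event"].to_numpy()
            ),
        },
        "logrank_screened_vs_detected": {"statistic": lr.statistic, "p_value": lr.p_value},
        "t_test_age": {
            "t": round(t_res.statistic, 2),
            "p_value": t_res.p_value,
            "df": t_res.df,
        },
    }


def build_report_from_simulation(cohort, screening_log, detections, cases) -> dict:
    """Feasibility report computed from simulated stage outputs."""
    counts, channels = funnel_summary(cases)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source": "simulation",
        "funnel": {**dataclasses.asdict(counts), "channels": channels},
    }
    try:
        report["adherence"] = adherence_proportion(cases)
    except ValueError:
        report["adherence"] = None
    try:
        dist = channel_distribution(cases)
        report["channel_distribution"] = {
            ch: {"count": n, "share": share} for ch, (n, share) in dist.items()
        }
    except ValueError:
        report["channel_distribution"] = None
    report["odds_ratios"] = {
        "personalization": _or_block(personalization_table(cases)),
        "outreach": _or_block(outreach_table(cases)),
    }

    by_id = {r.patient_id: r for r in cohort}
    detected_ids = {d.patient_id for d in detections}
    screened_ids = {
        e.patient_id for e in screening_log if e.status == "SCREENED"
    }

    def outcome_arrays(ids):
        times, events = [], []
        for pid in ids:
            r = by_id[pid]
            t = r.observed_time_days
            if t is not None and t > 0:
                times.append(t)
                events.append(r.had_event)
        return np.asarray(times, float), np.asarray(events, bool)

    st, se = outcome_arrays(screened_ids)
    dt, de = outcome_arrays(detected_ids)
    report["incidence"] = {
        "screened": _incidence_block(st, se),
        "detected": _incidence_block(dt, de),
    }
    report["six_month_proportions"] = {
        "screened": float(np.mean(se & (st <= SIX_MONTHS_DAYS))) if st.size else None,
        "detected": float(np.mean(de & (dt <= SIX_MONTHS_DAYS))) if dt.size else None,
    }
    if st.size and dt.size and (se.any() or de.any()):
        lr = logrank_test(st, se, dt, de)
        report["logrank_screened_vs_detected"] = {
            "statistic": lr.statistic,
            "p_value": lr.p_value,
        }
    return report


def render_report_text(report: dict) -> str:
    """Plain-text rendering of a report (percentages to 1 dp)."""
    f = report["funnel"]
    lines = [
        f"psyscreen feasibility report (schema v{report['schema_version']}, "
        f"source: {report['source']})",
        f"funnel: detected={f['detected']} no_contact={f['no_contact']} "
        f"prompted={f['prompted']} responded={f['responded']} "
        f"excluded={f['excluded']} decisions={f['decisions']} referred={f['referred']}",
    ]
    if report.get("adherence") is not None:
        lines.append(f"adherence: {100 * report['adherence']:.1f}%")
    if report.get("channel_distribution"):
        parts = [
            f"{ch} {v['count']} ({100 * v['share']:.1f}%)"
            for ch, v in report["channel_distribution"].items()
        ]
        lines.append("responses by channel: " + ", ".join(parts))
    for name, block in report.get("odds_ratios", {}).items():
        if block["odds_ratio"] is not None:
            lines.append(
                f"{name}: OR {block['odds_ratio']:.2f} "
                f"(95%CI {block['ci95'][0]:.2f}-{block['ci95'][1]:.2f}), "
                f"p = {block['p_value']:.3f}"
            )
    for stratum, block in report.get("incidence", {}).items():
        if not block.get("undefined"):
            lines.append(
                f"six-month cumulative incidence, {stratum}: "
                f"{block['incidence']:.3f} (95%CI {block['ci95'][0]:.3f}-"
                f"{block['ci95'][1]:.3f}; {block['n_at_risk']} still at risk)"
            )
    if "t_test_age" in report:
        tt = report["t_test_age"]
        lines.append(f"age, screened vs detected: t = {tt['t']:.2f}, p = {tt['p_value']:.3f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# run / replicate
# ---------------------------------------------------------------------------


def _config_hash(spec: StudySpec) -> str:
    # stable-ish digest of the run conditions
    def default(o):
        if isinstance(o, (date,)):
            return o.isoformat()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(spec), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(
    spec: StudySpec | str | Path,
    seed: int = 0,
    out_dir: str | Path | None = None,
    run_alerts: bool = True,
) -> dict:
    """Execute generation -> screening -> alerts -> statistics once.

    Returns the report dict; when ``out_dir`` is given also writes
    ``cohort.csv``, ``screening_log.csv``, ``case_log.csv``,
    ``report.json``, ``report.txt`` and ``manifest.json``.  Fully
    deterministic for a given (spec, seed).
    """
    if not isinstance(spec, StudySpec):
        spec = load_study_spec(spec)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage_counts: dict[str, int] = {}
    artifacts: dict[str, str] = {}
    try:
        if spec.fixture == "published-funnel":
            fix = make_published_funnel_fixture()
            report = build_report_from_fixture(fix)
            cohort, screening_log, cases = fix.cohort, [], fix.cases
            stage_counts = {"cohort": len(cohort), "cases": len(cases)}
        elif spec.fixture is not None:
            raise ValueError(f"unknown fixture {spec.fixture!r}")
        else:
            if spec.cohort_csv is not None:
                cohort = read_cohort_csv(spec.cohort_csv)
                log.info("stage=load cohort n=%d", len(cohort))
            else:
                if spec.cohort.n_patients == 0:
                    raise ValueError("cohort.n_patients must be positive")
                cohort = generate_cohort(spec.cohort, seed)
                gen_model = RiskModel(
                    coeffs=spec.cohort.true_betas,
                    baseline=spec.cohort.resolved_baseline(),
                    horizon_days=spec.study.horizon_days,
                )
                cohort = sample_event_times(cohort, gen_model, spec.cohort, seed)
                log.info("stage=simulate cohort n=%d", len(cohort))
            stage_counts["cohort"] = len(cohort)

            screening_log, detections = run_weekly_screening(
                cohort, spec.model, spec.study
            )
            stage_counts["screening_log"] = len(screening_log)
            stage_counts["detections"] = len(detections)
            log.info(
                "stage=screen entries=%d detections=%d",
                len(screening_log),
                len(detections),
            )

            cases = []
            if run_alerts:
                rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
                by_id = {r.patient_id: r for r in cohort}
                cases = run_alert_workflow(detections, by_id, spec.workflow, rng)
                stage_counts["cases"] = len(cases)
                log.info("stage=alerts cases=%d", len(cases))

            report = build_report_from_simulation(
                cohort, screening_log, detections, cases
            )

        if out is not None:
            write_cohort_csv(cohort, out / "cohort.csv")
            artifacts["cohort"] = str(out / "cohort.csv")
            if screening_log:
                write_screening_log_csv(screening_log, out / "screening_log.csv")
                artifacts["screening_log"] = str(out / "screening_log.csv")
            if cases:
                write_case_log_csv(cases, out / "case_log.csv")
                artifacts["case_log"] = str(out / "case_log.csv")
            (out / "report.json").write_text(json.dumps(report, indent=2))
            (out / "report.txt").write_text(render_report_text(report))
            artifacts["report"] = str(out / "report.json")
            manifest = {
                "config_hash": _config_hash(spec),
                "master_seed": seed,
                "package_version": __version__,
                "schema_version": REPORT_SCHEMA_VERSION,
                "stage_counts": stage_counts,
                "artifacts": artifacts,
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        if out is not None:  # remove partial outputs; a run is all-or-nothing
            for p in artifacts.values():
                Path(p).unlink(missing_ok=True)
        raise
    return report


def expected_adherence(workflow: WorkflowConfig, cohort: CohortConfig) -> float:
    """Closed-form expected response probability across the four stages.

    Averages 1 - prod_c (1 - p_c) over the personalization assignment and
    the borough-outreach mixture implied by the configs.
    """
    from .alert_workflow import CHANNELS, AlertCase, effective_response_prob

    p_name = workflow.personalization_name_frac
    p_lam = cohort.borough_freq.get("Lambeth", 0.0)
    total = 0.0
    for named, w1 in ((True, p_name), (False, 1 - p_name)):
        for lam, w2 in ((True, p_lam), (False, 1 - p_lam)):
            case = AlertCase(
                patient_id="x",
                detection_week=0,
                personalization="patient_name" if named else "trust_id",
                outreach=lam,
            )
            no_resp = 1.0
            for ch in CHANNELS:
                no_resp *= 1.0 - effective_response_prob(case, ch, workflow)
            total += w1 * w2 * (1.0 - no_resp)
    return total


def replicate_study(
    spec: StudySpec | str | Path, n_replicates: int, seed: int = 0
) -> dict:
    """Repeat the simulated study and summarise feasibility metrics.

    Per-replicate seeds derive from the master seed.  Returns per-metric
    arrays plus median and 2.5/97.5 percentile summaries for adherence and
    the two response odds ratios.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not isinstance(spec, StudySpec):
        spec = load_study_spec(spec)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_replicates)
    ]
    metrics: dict[str, list] = {"adherence": [], "or_personalization": [], "or_outreach": []}
    for s in child_seeds:
        rep = run_study(spec, seed=s)
        metrics["adherence"].append(rep.get("adherence"))
        metrics["or_personalization"].append(
            rep["odds_ratios"]["personalization"]["odds_ratio"]
        )
        metrics["or_outreach"].append(rep["odds_ratios"]["outreach"]["odds_ratio"])

    def summarise(values):
        vals = np.asarray([v for v in values if v is not None], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return {"n": 0}
        return {
            "n": int(vals.size),
            "median": float(np.median(vals)),
            "p2.5": float(np.percentile(vals, 2.5)),
            "p97.5": float(np.percentile(vals, 97.5)),
        }

    return {
        "n_replicates": n_replicates,
        "metrics": {k: summarise(v) for k, v in metrics.items()},
        "values": metrics,
    }
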
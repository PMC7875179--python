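"""Transdiagnostic psychosis risk calculator.

A Cox proportional-hazards risk score over routinely collected EHR
predictors: age at index diagnosis, gender, an age-by-gender interaction,
self-assigned ethnicity and the ICD-10 index-diagnosis cluster.  The linear
predictor is measured against the reference subject (age 0, female, White,
ARMS), and absolute risk at a horizon follows the usual survivor transform

    risk(t | x) = 1 - S0(t) ** exp(lp(x))

where ``S0`` is the baseline survivor function of the reference subject.
The published coefficient table does not come with a baseline survivor
function, so ``S0`` is configurable (exponential by default, calibrated to
a stated reference risk); absolute risks are therefore configuration
dependent while risk *rankings* are fully determined by the coefficients.

The module also provides Harrell's concordance index for censored survival
scores and a Cox partial-likelihood fitter (Efron or Breslow ties) used to
validate that synthetic cohorts generated from the model give the
coefficients back.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GENDERS",
    "ETHNICITIES",
    "DIAGNOSES",
    "ModelCoefficients",
    "BaselineSurvival",
    "RiskPrediction",
    "RiskModel",
    "linear_predictor",
    "risk_at_horizon",
    "calibrate_exponential_baseline",
    "harrells_c",
    "CoxFitResult",
    "fit_cox_partial_likelihood",
    "ConvergenceError",
    "SeparationError",
    "load_model",
    "default_model",
]

GENDERS = ("female", "male")

ETHNICITIES = ("White", "Black", "Asian", "Mixed", "Other")

#: ICD-10 index-diagnosis clusters of the calculator.  ARMS (the at-risk
#: mental state) is the reference category and carries coefficient 0.
DIAGNOSES = (
    "ARMS",
    "Acute-transient-psychotic",
    "Substance-use",
    "Bipolar-mood",
    "Non-bipolar-mood",
    "Anxiety",
    "Personality",
    "Developmental",
    "Childhood-adolescence-onset",
    "Physiological-syndromes",
    "Mental-retardation",
)


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximisation did not converge."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a coefficient diverges (separation)."""


@dataclass(frozen=True)
class ModelCoefficients:
    """Log-hazard coefficients of the risk calculator.

    Reference levels (female, White, ARMS) must carry coefficient exactly
    zero; they are stored explicitly so category membership is checkable.
    """

    beta_age: float
    beta_male: float
    beta_age_male: float
    beta_ethnicity: dict[str, float]
    beta_diagnosis: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.beta_ethnicity) != set(ETHNICITIES):
            raise ValueError(
                f"ethnicity coefficients must cover exactly {ETHNICITIES}, "
                f"got {sorted(self.beta_ethnicity)}"
            )
        if set(self.beta_diagnosis) != set(DIAGNOSES):
            raise ValueError(
                f"diagnosis coefficients must cover exactly {DIAGNOSES}, "
                f"got {sorted(self.beta_diagnosis)}"
            )
        if self.beta_ethnicity["White"] != 0.0:
            raise ValueError("reference ethnicity 'White' must have coefficient 0")
        if self.beta_diagnosis["ARMS"] != 0.0:
            raise ValueError("reference diagnosis 'ARMS' must have coefficient 0")

    @classmethod
    def published(cls) -> "ModelCoefficients":
        """The published coefficient table of the revised calculator."""
        return cls(
            beta_age=0.010,
            beta_male=0.457,
            beta_age_male=-0.009,
            beta_ethnicity={
                "White": 0.0,
                "Black": 0.995,
                "Asian": 0.487,
                "Mixed": 0.686,
                "Other": 0.340,
            },
            beta_diagnosis={
                "ARMS": 0.0,
                "Acute-transient-psychotic": 1.169,
                "Substance-use": -1.748,
                "Bipolar-mood": 0.003,
                "Non-bipolar-mood": -1.560,
                "Anxiety": -2.006,
                "Personality": -1.363,
                "Developmental": -3.337,
                "Childhood-adolescence-onset": -3.200,
                "Physiological-syndromes": -2.310,
                "Mental-retardation": -2.326,
            },
        )

    # -- flat vector view used by the fitter and by JSON I/O ---------------

    @staticmethod
    def term_names() -> list[str]:
        names = ["age", "male", "age_male"]
        names += [f"ethnicity.{e}" for e in ETHNICITIES if e != "White"]
        names += [f"diagnosis.{d}" for d in DIAGNOSES if d != "ARMS"]
        return names

    def to_vector(self) -> np.ndarray:
        vals = [self.beta_age, self.beta_male, self.beta_age_male]
        vals += [self.beta_ethnicity[e] for e in ETHNICITIES if e != "White"]
        vals += [self.beta_diagnosis[d] for d in DIAGNOSES if d != "ARMS"]
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_vector(cls, beta: Sequence[float]) -> "ModelCoefficients":
        beta = list(map(float, beta))
        if len(beta) != len(cls.term_names()):
            raise ValueError(f"expected {len(cls.term_names())} coefficients")
        eth = {"White": 0.0}
        eth.update(dict(zip([e for e in ETHNICITIES if e != "White"], beta[3:7])))
        dia = {"ARMS": 0.0}
        dia.update(dict(zip([d for d in DIAGNOSES if d != "ARMS"], beta[7:])))
        return cls(beta[0], beta[1], beta[2], eth, dia)


@dataclass(frozen=True)
class BaselineSurvival:
    """Baseline survivor function S0(t) of the reference subject.

    ``exponential`` form: S0(t) = exp(-rate * t), rate in events/day.
    ``step`` form: a right-continuous step function given as ordered
    (time-days, survival) pairs; no extrapolation past the last step.
    """

    form: Literal["exponential", "step"]
    rate: float | None = None
    steps: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.form == "exponential":
            if self.rate is None or self.rate < 0:
                raise ValueError("exponential baseline needs rate >= 0")
        elif self.form == "step":
            if not self.steps:
                raise ValueError("step baseline needs at least one step")
            ts = [t for t, _ in self.steps]
            ss = [s for _, s in self.steps]
            if any(t < 0 for t in ts) or ts != sorted(ts):
                raise ValueError("step times must be non-negative and ordered")
            if any(not (0.0 < s <= 1.0) for s in ss):
                raise ValueError("step survival values must lie in (0, 1]")
            if any(b > a for a, b in zip(ss, ss[1:])):
                raise ValueError("baseline survival must be non-increasing")
        else:
            raise ValueError(f"unknown baseline form {self.form!r}")

    def survival(self, t_days: float) -> float:
        """S0(t); t=0 always returns 1."""
        if t_days < 0:
            raise ValueError("time must be non-negative")
        if self.form == "exponential":
            return math.exp(-self.rate * t_days)
        last_t = self.steps[-1][0]
        if t_days > last_t:
            raise ValueError(
                f"horizon {t_days} days lies beyond the last baseline step "
                f"({last_t} days); step baselines are not extrapolated"
            )
        s = 1.0
        for step_t, step_s in self.steps:
            if step_t <= t_days:
                s = step_s
            else:
                break
        return s


@dataclass(frozen=True)
class RiskPrediction:
    lp: float
    horizon_days: int
    risk: float


def _check_category(value: str, allowed: Sequence[str], name: str) -> None:
    if value not in allowed:
        raise ValueError(f"unknown {name} {value!r}; expected one of {list(allowed)}")


def linear_predictor(
    age_years: float,
    gender: str,
    ethnicity: str,
    diagnosis: str,
    coeffs: ModelCoefficients,
) -> float:
    """Log-hazard of a subject relative to the reference subject.

    lp = b_age*age + b_male*[male] + b_age_male*age*[male]
         + b_ethnicity[e] + b_diagnosis[d]
    """
    if age_years < 0:
        raise ValueError(f"age_years must be non-negative, got {age_years}")
    _check_category(gender, GENDERS, "gender")
    _check_category(ethnicity, ETHNICITIES, "ethnicity")
    _check_category(diagnosis, DIAGNOSES, "diagnosis")
    male = gender == "male"
    lp = coeffs.beta_age * age_years
    if male:
        lp += coeffs.beta_male + coeffs.beta_age_male * age_years
    lp += coeffs.beta_ethnicity[ethnicity]
    lp += coeffs.beta_diagnosis[diagnosis]
    return lp


def risk_at_horizon(lp: float, baseline: BaselineSurvival, horizon_days: int) -> float:
    """Absolute event probability by ``horizon_days``: 1 - S0(t)^exp(lp)."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    s0 = baseline.survival(horizon_days)
    return 1.0 - s0 ** math.exp(lp)


def calibrate_exponential_baseline(
    coeffs: ModelCoefficients,
    reference_risk: float = 0.20,
    horizon_days: int = 730,
    age_years: float = 25.0,
    gender: str = "female",
    ethnicity: str = "White",
    diagnosis: str = "ARMS",
) -> BaselineSurvival:
    """Exponential baseline whose rate gives a stated subject a stated risk.

    By default: a 25-year-old female, White, ARMS subject has a 20% risk of
    transition to psychosis at two years.  Solving
    1 - exp(-rate*h)^exp(lp) = risk for the rate is closed form.
    """
    if not 0.0 < reference_risk < 1.0:
        raise ValueError("reference_risk must lie in (0, 1)")
    lp = linear_predictor(age_years, gender, ethnicity, diagnosis, coeffs)
    rate = -math.log(1.0 - reference_risk) / (horizon_days * math.exp(lp))
    return BaselineSurvival(form="exponential", rate=rate)


@dataclass(frozen=True)
class RiskModel:
    """Coefficients + baseline + evaluation horizon, bundled."""

    coeffs: ModelCoefficients
    baseline: BaselineSurvival
    horizon_days: int = 730

    def predict(
        self, age_years: float, gender: str, ethnicity: str, diagnosis: str
    ) -> RiskPrediction:
        lp = linear_predictor(age_years, gender, ethnicity, diagnosis, self.coeffs)
        risk = risk_at_horizon(lp, self.baseline, self.horizon_days)
        return RiskPrediction(lp=lp, horizon_days=self.horizon_days, risk=risk)

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        betas = dict(zip(ModelCoefficients.term_names(), self.coeffs.to_vector()))
        if self.baseline.form == "exponential":
            base = {"form": "exponential", "rate": self.baseline.rate}
        else:
            base = {"form": "step", "steps": [list(p) for p in self.baseline.steps]}
        return {"betas": betas, "baseline": base, "horizon_days": self.horizon_days}

    @classmethod
    def from_dict(cls, obj: dict) -> "RiskModel":
        names = ModelCoefficients.term_names()
        betas = obj["betas"]
        unknown = set(betas) - set(names)
        if unknown:
            raise ValueError(f"unknown coefficient names in model file: {sorted(unknown)}")
        missing = set(names) - set(betas)
        if missing:
            raise ValueError(f"model file is missing coefficients: {sorted(missing)}")
        coeffs = ModelCoefficients.from_vector([betas[n] for n in names])
        b = obj["baseline"]
        if b["form"] == "exponential":
            baseline = BaselineSurvival(form="exponential", rate=float(b["rate"]))
        else:
            baseline = BaselineSurvival(
                form="step", steps=tuple((float(t), float(s)) for t, s in b["steps"])
            )
        return cls(coeffs=coeffs, baseline=baseline, horizon_days=int(obj["horizon_days"]))


def load_model(path) -> RiskModel:
    """Read a RiskModel from a JSON model file."""
    with open(path) as fh:
        return RiskModel.from_dict(json.load(fh))


def default_model() -> RiskModel:
    """The packaged default: published betas, calibrated exponential baseline."""
    ref = resources.files("psyscreen.data").joinpath("published_model.json")
    return RiskModel.from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


def harrells_c(times, event_flags, scores) -> float:
    """Harrell's C for right-censored data.

    A pair is comparable when the shorter observed time is an event (ties in
    time are comparable only when exactly one member is an event).  A pair is
    concordant when the member with the earlier event has the higher score;
    pairs tied on score contribute 1/2.  Raises ``ValueError`` when no pair
    is comparable.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (t.shape == e.shape == s.shape) or t.ndim != 1:
        raise ValueError("times, event_flags and scores must be equal-length 1-d")
    if np.any(t <= 0):
        raise ValueError("times must be positive")

    dt = t[:, None] - t[None, :]          # t_i - t_j
    # i is the earlier event of the pair: t_i < t_j, or t_i == t_j with
    # i an event and j censored.
    earlier = (dt < 0) | ((dt == 0) & e[:, None] & ~e[None, :])
    comparable = earlier & e[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs; concordance is undefined")
    ds = s[:, None] - s[None, :]
    concordant = (comparable & (ds > 0)).sum()
    tied = (comparable & (ds == 0)).sum()
    return float((concordant + 0.5 * tied) / n_comp)


# ---------------------------------------------------------------------------
# Cox partial-likelihood fitter
# ---------------------------------------------------------------------------


@dataclass
class CoxFitResult:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    n_events: int
    term_names: list[str] | None = None

    def wald_ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.coef - z * self.se, self.coef + z * self.se

    def as_coefficients(self) -> ModelCoefficients:
        if self.term_names != ModelCoefficients.term_names():
            raise ValueError("fit design does not match the calculator's terms")
        return ModelCoefficients.from_vector(self.coef)


def _partial_loglik_terms(X, w, order, event_groups, ties):
    """Negative-log-likelihood pieces shared by value/gradient/hessian.

    ``order`` sorts times descending so risk-set sums are cumulative sums.
    ``event_groups`` maps positions (in sorted order) of tied event blocks.
    """
    Xs = X[order]
    ws = w[order]
    n, p = Xs.shape
    c0 = np.cumsum(ws)
    c1 = np.cumsum(ws[:, None] * Xs, axis=0)
    c2 = np.cumsum(ws[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    eta_s = np.log(ws)
    for last_pos, idx in event_groups:
        d = len(idx)
        S0 = c0[last_pos]
        S1 = c1[last_pos]
        S2 = c2[last_pos]
        xd = Xs[idx]
        loglik += float(eta_s[idx].sum())
        grad += xd.sum(axis=0)
        if ties == "breslow" or d == 1:
            loglik -= d * math.log(S0)
            grad -= d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        else:  # efron
            wd = ws[idx]
            s0d = wd.sum()
            s1d = (wd[:, None] * xd).sum(axis=0)
            s2d = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            for ell in range(d):
                f = ell / d
                a0 = S0 - f * s0d
                a1 = S1 - f * s1d
                a2 = S2 - f * s2d
                loglik -= math.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
    return loglik, grad, hess


def fit_cox_partial_likelihood(
    covariate_rows,
    times,
    event_flags,
    ties: Literal["efron", "breslow"] = "efron",
    term_names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    max_abs_coef: float = 20.0,
) -> CoxFitResult:
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Efron's approximation (default) or Breslow's is used for tied event
    times.  Standard errors come from the inverse observed information.
    Separation (a monotone likelihood driving a coefficient beyond
    ``max_abs_coef``) raises ``SeparationError``; non-convergence raises
    ``ConvergenceError`` carrying the iteration count.
    """
    X = np.asarray(covariate_rows, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if X.ndim != 2 or X.shape[0] != t.shape[0] or t.shape != e.shape:
        raise ValueError("covariate_rows must be (n, p) matching times/event_flags")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("at least one event is required")
    n, p = X.shape

    # Descending time order; within a time, events placed last so the tied
    # event block ends each risk set (risk set = everyone with t_i >= t).
    order = np.lexsort((e, -t))
    ts = t[order]
    es = e[order]
    event_groups = []
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        idx = np.arange(i, j)[es[i:j]]
        if idx.size:
            event_groups.append((j - 1, idx))
        i = j

    def weights(b):
        return np.exp(np.clip(X @ b, -500.0, 500.0))

    step_cap = 2.0  # damp raw Newton steps; sparse dummies overshoot badly
    beta = np.zeros(p)
    loglik_prev = -np.inf
    for it in range(1, max_iter + 1):
        loglik, grad, hess = _partial_loglik_terms(
            X, weights(beta), order, event_groups, ties
        )
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}", it)
        biggest = np.max(np.abs(step))
        if biggest > step_cap:
            step *= step_cap / biggest
        # step-halving keeps the likelihood increasing
        new_beta = beta + step
        flat = False
        halves = 0
        while True:
            ll_new, _, _ = _partial_loglik_terms(
                X, weights(new_beta), order, event_groups, ties
            )
            if ll_new >= loglik - 1e-12:
                break
            if halves >= 30:
                # no ascent direction left; a numerically flat likelihood
                # means we are at the optimum, anything else is a failure
                if abs(ll_new - loglik) <= 1e-7 * (abs(loglik) + 1.0):
                    flat = True
                    break
                raise ConvergenceError("step-halving failed to improve likelihood", it)
            step *= 0.5
            new_beta = beta + step
            halves += 1
        beta = new_beta
        if np.max(np.abs(beta)) > max_abs_coef:
            raise SeparationError(
                "monotone partial likelihood: a coefficient exceeded "
                f"{max_abs_coef}; the data are separated"
            )
        if flat or (
            np.abs(loglik - loglik_prev) < tol and np.max(np.abs(step)) < 1e-6
        ):
            break
        loglik_prev = loglik
    else:
        raise ConvergenceError("partial likelihood did not converge", max_iter)

    loglik, grad, hess = _partial_loglik_terms(
        X, weights(beta), order, event_groups, ties
    )
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFitResult(
        coef=beta,
        se=se,
        loglik=float(loglik),
        n_iter=it,
        n_events=n_events,
        term_names=term_names,
    )


def design_matrix(ages, genders, ethnicities, diagnoses) -> np.ndarray:
    """Covariate rows in the calculator's coding (17 columns)."""
    ages = np.asarray(ages, dtype=float)
    male = np.asarray([g == "male" for g in genders], dtype=float)
    cols = [ages, male, ages * male]
    for e in ETHNICITIES:
        if e != "White":
            cols.append(np.asarray([x == e for x in ethnicities], dtype=float))
    for d in DIAGNOSES:
        if d != "ARMS":
            cols.append(np.asarray([x == d for x in diagnoses], dtype=float))
    return np.column_stack(cols)
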
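import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyscreen.risk_model import (
    DIAGNOSES,
    ETHNICITIES,
    BaselineSurvival,
    ModelCoefficients,
    SeparationError,
    calibrate_exponential_baseline,
    default_model,
    design_matrix,
    fit_cox_partial_likelihood,
    harrells_c,
    linear_predictor,
    risk_at_horizon,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


class TestLinearPredictor:
    @pytest.mark.parametrize(
        "age, gender, ethnicity, diagnosis, expected",
        [
            (0, "female", "White", "ARMS", 0.0),
            (25, "male", "Black", "Acute-transient-psychotic", 2.646),
            (40, "female", "White", "Anxiety", -1.606),
        ],
    )
    def test_hand_sums(self, coeffs, age, gender, ethnicity, diagnosis, expected):
        lp = linear_predictor(age, gender, ethnicity, diagnosis, coeffs)
        assert lp == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(gender="m"), "gender"),
            (dict(ethnicity="Caucasian"), "ethnicity"),
            (dict(diagnosis="Mood"), "diagnosis"),
        ],
    )
    def test_unknown_categories_name_the_field(self, coeffs, kwargs, fragment):
        args = dict(age_years=30, gender="male", ethnicity="White", diagnosis="ARMS")
        args.update(kwargs)
        with pytest.raises(ValueError, match=fragment):
            linear_predictor(coeffs=coeffs, **args)

    def test_negative_age_rejected(self, coeffs):
        with pytest.raises(ValueError, match="age"):
            linear_predictor(-1, "female", "White", "ARMS", coeffs)

    @given(
        age=st.floats(0, 100),
        eth1=st.sampled_from(ETHNICITIES),
        eth2=st.sampled_from(ETHNICITIES),
        dia=st.sampled_from(DIAGNOSES),
        gender=st.sampled_from(["female", "male"]),
    )
    def test_additive_in_ethnicity(self, age, eth1, eth2, dia, gender):
        """Swapping one categorical level shifts lp by the coefficient delta."""
        c = ModelCoefficients.published()
        d = linear_predictor(age, gender, eth1, dia, c) - linear_predictor(
            age, gender, eth2, dia, c
        )
        assert d == pytest.approx(
            c.beta_ethnicity[eth1] - c.beta_ethnicity[eth2], abs=1e-12
        )


class TestRiskAtHorizon:
    def test_no_baseline_risk(self):
        base = BaselineSurvival(form="exponential", rate=0.0)
        assert risk_at_horizon(5.0, base, 730) == 0.0

    def test_reference_subject_risk_is_one_minus_s0(self, flat_baseline):
        assert risk_at_horizon(0.0, flat_baseline, 730) == pytest.approx(0.01)

    def test_doubled_hazard_closed_form(self, flat_baseline):
        assert risk_at_horizon(math.log(2), flat_baseline, 730) == pytest.approx(
            1 - 0.99**2
        )

    @given(lp1=st.floats(-5, 5), lp2=st.floats(-5, 5))
    def test_monotone_in_lp(self, lp1, lp2):
        baseline = BaselineSurvival(form="exponential", rate=-math.log(0.99) / 730)
        r1 = risk_at_horizon(lp1, baseline, 730)
        r2 = risk_at_horizon(lp2, baseline, 730)
        assert (lp1 <= lp2) == (r1 <= r2) or r1 == r2
        assert 0.0 <= r1 <= 1.0

    def test_step_baseline_no_extrapolation(self):
        base = BaselineSurvival(form="step", steps=((365.0, 0.98), (730.0, 0.95)))
        assert risk_at_horizon(0.0, base, 730) == pytest.approx(0.05)
        assert risk_at_horizon(0.0, base, 400) == pytest.approx(0.02)
        with pytest.raises(ValueError, match="beyond"):
            risk_at_horizon(0.0, base, 800)

    def test_invalid_baselines_rejected(self):
        with pytest.raises(ValueError):
            BaselineSurvival(form="step", steps=((10.0, 0.5), (20.0, 0.6)))
        with pytest.raises(ValueError):
            BaselineSurvival(form="step", steps=((10.0, 1.5),))
        with pytest.raises(ValueError):
            BaselineSurvival(form="exponential", rate=-1.0)


class TestDefaultModel:
    def test_reference_subject_two_year_risk(self):
        model = default_model()
        assert model.horizon_days == 730
        pred = model.predict(25, "female", "White", "ARMS")
        assert pred.risk == pytest.approx(0.20, abs=1e-9)

    def test_calibration_is_closed_form(self, coeffs):
        base = calibrate_exponential_baseline(coeffs, reference_risk=0.1)
        lp = linear_predictor(25, "female", "White", "ARMS", coeffs)
        assert risk_at_horizon(lp, base, 730) == pytest.approx(0.1)

    def test_reference_levels_are_zero(self):
        c = default_model().coeffs
        assert c.beta_ethnicity["White"] == 0.0
        assert c.beta_diagnosis["ARMS"] == 0.0

    def test_roundtrip(self, model, tmp_path):
        import json

        from psyscreen.risk_model import RiskModel, load_model

        p = tmp_path / "m.json"
        p.write_text(json.dumps(model.to_dict()))
        again = load_model(p)
        assert again == model

    def test_unknown_coefficient_names_rejected(self, model):
        obj = model.to_dict()
        obj["betas"]["diagnosis.Mood"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            type(model).from_dict(obj)


def brute_force_c(times, events, scores):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            earlier = times[i] < times[j] or (
                times[i] == times[j] and events[i] and not events[j]
            )
            if earlier and events[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den if den else None


class TestHarrellsC:
    @pytest.mark.parametrize(
        "times, events, scores, expected",
        [
            ((1, 2, 3, 4), (1, 1, 1, 1), (4, 3, 2, 1), 1.0),
            ((1, 2, 3, 4), (1, 1, 1, 1), (1, 2, 3, 4), 0.0),
            ((2, 4, 5, 7), (1, 0, 1, 1), (0.9, 0.1, 0.2, 0.3), 0.75),
        ],
    )
    def test_known_values(self, times, events, scores, expected):
        assert harrells_c(times, events, scores) == pytest.approx(expected)

    def test_all_censored_is_undefined(self):
        with pytest.raises(ValueError, match="comparable"):
            harrells_c([1, 2, 3], [0, 0, 0], [0.1, 0.2, 0.3])

    @given(
        data=st.lists(
            st.tuples(
                st.integers(1, 20),
                st.booleans(),
                st.integers(0, 5),
            ),
            min_size=2,
            max_size=40,
        )
    )
    def test_matches_pair_enumeration(self, data):
        times = [d[0] for d in data]
        events = [d[1] for d in data]
        scores = [d[2] for d in data]
        expected = brute_force_c(times, events, scores)
        if expected is None:
            with pytest.raises(ValueError):
                harrells_c(times, events, scores)
        else:
            assert harrells_c(times, events, scores) == pytest.approx(expected)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(5)
        t = rng.exponential(10, 150)
        e = rng.random(150) < 0.7
        s = rng.normal(size=150)
        ours = harrells_c(t, e, s)
        # lifelines orders by predicted survival time (higher = later event)
        theirs = concordance_index(t, -s, e)
        assert ours == pytest.approx(theirs, abs=1e-12)


def _partial_loglik_1d(beta, x, times, events):
    """Independent brute-force Cox partial log-likelihood (distinct times)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxFitter:
    def test_null_effect_on_balanced_sample(self):
        rng = np.random.default_rng(11)
        n = 4000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0, n)
        res = fit_cox_partial_likelihood(x[:, None], t, np.ones(n, bool))
        assert abs(res.coef[0]) < 3 * res.se[0]
        assert abs(res.coef[0]) < 0.1

    def test_matches_grid_search_on_toy_data(self):
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        t = np.array([3.0, 1.0, 4.0, 6.0, 2.0, 5.0])
        e = np.array([1, 1, 0, 1, 1, 1], bool)
        grid = np.arange(-5, 5, 1e-3)
        lls = [_partial_loglik_1d(b, x, t, e) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        res = fit_cox_partial_likelihood(x[:, None], t, e)
        assert res.coef[0] == pytest.approx(b_star, abs=1e-3)

    def test_agrees_with_lifelines_under_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 300
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(20, n) * np.exp(-0.3 * X[:, 0]))  # day ties
        e = rng.random(n) < 0.8
        res = fit_cox_partial_likelihood(X, t, e, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(res.coef, cph.params_.values, atol=1e-4)
        assert np.allclose(res.se, cph.standard_errors_.values, atol=1e-4)

    def test_breslow_option_close_to_efron_without_ties(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1, n)  # continuous: no ties, methods coincide
        e = np.ones(n, bool)
        r1 = fit_cox_partial_likelihood(x, t, e, ties="efron")
        r2 = fit_cox_partial_likelihood(x, t, e, ties="breslow")
        assert r1.coef[0] == pytest.approx(r2.coef[0], abs=1e-8)

    def test_separation_reported(self):
        # covariate perfectly orders the outcomes: monotone likelihood
        x = np.arange(8.0)[:, None]
        t = np.arange(1.0, 9.0)[::-1]
        e = np.ones(8, bool)
        with pytest.raises(SeparationError):
            fit_cox_partial_likelihood(x, t, e)

    def test_requires_an_event(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox_partial_likelihood(np.zeros((3, 1)), [1, 2, 3], [0, 0, 0])


def test_design_matrix_matches_linear_predictor(coeffs):
    ages = [20, 35, 60]
    genders = ["male", "female", "male"]
    eths = ["Black", "White", "Other"]
    dias = ["ARMS", "Anxiety", "Bipolar-mood"]
    X = design_matrix(ages, genders, eths, dias)
    lps = X @ coeffs.to_vector()
    for i in range(3):
        assert lps[i] == pytest.approx(
            linear_predictor(ages[i], genders[i], eths[i], dias[i], coeffs)
        )
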
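"""ARDL risk-factor transition models."""

import math

import numpy as np
import pandas as pd
import pytest

import microhealth as mh
from microhealth.covariates import RISK_FACTORS


from helpers import make_state


def scalar_probability(params, row, duration=1):
    """Independent scalar re-implementation of the transition probability."""
    eta = params.beta0 + params.beta1_duration * (duration - 1)
    eta += params.beta2_lag * float(row[params.factor])
    for name, beta in params.covariate_betas.items():
        if name in RISK_FACTORS:
            x = float(row[name])
        elif name == "inactive":
            x = 1.0 - float(row["active"])
        elif name in ("female", "male"):
            x = 1.0 if row["sex"] == name else 0.0
        elif name.startswith("education_"):
            x = 1.0 if row["education"] == name.split("_", 1)[1] else 0.0
        elif name == "age_c50":
            x = float(row["age"]) - 50.0
        elif name == "age":
            x = float(row["age"])
        else:
            raise AssertionError(name)
        eta += beta * x
    if params.age_spline is not None:
        eta += float(params.age_spline(float(row["age"])))
    return 1.0 / (1.0 + math.exp(-eta))


def test_probability_matches_scalar_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        params = mh.TransitionParams(
            factor="obese",
            beta0=rng.normal(), beta1_duration=rng.normal(),
            beta2_lag=rng.normal(scale=2),
            covariate_betas={"female": rng.normal(), "education_low": rng.normal(),
                             "smoker": rng.normal(), "age_c50": rng.normal(scale=0.05)},
            age_spline=mh.AgeSpline(knots=[50, 70, 90], values=list(rng.normal(size=3))),
        )
        state = make_state(
            age=float(rng.uniform(50, 95)),
            sex=rng.choice(["male", "female"]),
            education=rng.choice(["low", "medium", "high"]),
            smoker=int(rng.integers(2)), obese=int(rng.integers(2)))
        d = int(rng.integers(1, 4))
        p = mh.transition_probability(params, state, duration_years=d)[0]
        assert p == pytest.approx(scalar_probability(params, state.iloc[0], d), abs=1e-10)
        assert 0.0 < p < 1.0


def test_duration_term_vanishes_at_one_year():
    params = mh.TransitionParams(factor="smoker", beta0=-1.0, beta1_duration=5.0,
                                 beta2_lag=2.0)
    state = make_state(smoker=1)
    p1 = mh.transition_probability(params, state, duration_years=1)[0]
    no_duration = mh.TransitionParams(factor="smoker", beta0=-1.0, beta2_lag=2.0)
    assert p1 == pytest.approx(mh.transition_probability(no_duration, state)[0], abs=1e-15)
    # and at a=3 the shift is exactly 2*beta1 on the logit scale
    p3 = mh.transition_probability(params, state, duration_years=3)[0]
    assert math.log(p3 / (1 - p3)) - math.log(p1 / (1 - p1)) == pytest.approx(10.0, abs=1e-9)


def logit(p):
    return math.log(p / (1 - p))


def test_default_education_effect_on_obesity(bundle):
    """Low vs high (reference) education shifts the obesity logit by 0.692."""
    params = bundle.transitions["obese"]
    low = make_state(education="low")
    high = make_state(education="high")
    shift = (logit(mh.transition_probability(params, low)[0])
             - logit(mh.transition_probability(params, high)[0]))
    assert shift == pytest.approx(0.692, abs=1e-9)


@pytest.mark.parametrize("lagged, expected", [
    ("smoker", -0.261), ("obese", -0.333), ("depressed", -0.399)])
def test_default_cross_effects_on_physical_activity(bundle, lagged, expected):
    params = bundle.transitions["active"]
    with_factor = make_state(**{lagged: 1})
    without = make_state()
    shift = (logit(mh.transition_probability(params, with_factor)[0])
             - logit(mh.transition_probability(params, without)[0]))
    assert shift == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("lagged, expected", [
    ("smoker", 0.197), ("obese", 0.125), ("active", -0.234)])
def test_default_cross_effects_on_depression(bundle, lagged, expected):
    params = bundle.transitions["depressed"]
    with_factor = make_state(**{lagged: 1})
    without = make_state()
    shift = (logit(mh.transition_probability(params, with_factor)[0])
             - logit(mh.transition_probability(params, without)[0]))
    assert shift == pytest.approx(expected, abs=1e-9)


def test_default_smoking_model_is_purely_autoregressive(bundle):
    """No other risk factor and no education level enters the smoking model."""
    covs = set(bundle.transitions["smoker"].covariate_betas)
    assert not covs & set(RISK_FACTORS)
    assert not covs & {"inactive", "education_low", "education_medium"}


def test_zero_coefficients_give_bernoulli_half():
    params = {f: mh.TransitionParams(factor=f) for f in RISK_FACTORS}
    pop = make_state(n=40_000, smoker=1, depressed=1)
    mh.update_risk_factors(pop, params, master_seed=3, year=2011)
    for f in RISK_FACTORS:
        assert abs(pop[f].mean() - 0.5) < 3 * 0.5 / math.sqrt(len(pop))


def test_empirical_frequencies_match_probabilities(bundle):
    """100k draws in one covariate cell land within 3 binomial SE of the
    model probability, for each factor."""
    pop = make_state(n=100_000, education="low", smoker=1, obese=1, active=0,
                     hypertension=0, depressed=1, age=70.0)
    expected = {f: mh.transition_probability(bundle.transitions[f], pop)[0]
                for f in RISK_FACTORS}
    mh.update_risk_factors(pop, bundle.transitions, master_seed=17, year=2020)
    for f in RISK_FACTORS:
        p = expected[f]
        se = math.sqrt(p * (1 - p) / len(pop))
        assert abs(pop[f].mean() - p) < 3 * se


def test_update_is_order_stable_under_row_permutation(bundle, small_pop):
    a = small_pop.copy()
    b = small_pop.sample(frac=1.0, random_state=1).copy()
    mh.update_risk_factors(a, bundle.transitions, master_seed=5, year=2012)
    mh.update_risk_factors(b, bundle.transitions, master_seed=5, year=2012)
    b = b.sort_values("id").reset_index(drop=True)
    for f in RISK_FACTORS:
        assert (a[f].to_numpy() == b[f].to_numpy()).all()


def test_update_reads_the_prestep_snapshot_synchronously(bundle, small_pop):
    """Every factor's draw equals a Bernoulli on the probability computed
    from the pre-step snapshot — no sequential contamination between
    factors within the year."""
    pop = small_pop.copy()
    snapshot = pop.copy()
    mh.update_risk_factors(pop, bundle.transitions, master_seed=9, year=2013)
    from microhealth.rng import substream_uniforms
    ids = snapshot["id"].to_numpy()
    for f in RISK_FACTORS:
        p = mh.transition_probability(bundle.transitions[f], snapshot)
        u = substream_uniforms(9, 2013, f, ids)
        assert (pop[f].to_numpy() == (u < p).astype(int)).all()


def test_dead_individuals_are_never_updated(bundle, small_pop):
    pop = small_pop.copy()
    pop.loc[pop.index[:50], "alive"] = False
    before = pop.loc[~pop["alive"], list(RISK_FACTORS)].copy()
    mh.update_risk_factors(pop, bundle.transitions, master_seed=5, year=2012)
    after = pop.loc[~pop["alive"], list(RISK_FACTORS)]
    pd.testing.assert_frame_equal(before, after)


def test_long_run_convergence_to_stationary_distribution():
    """Iterating one factor with frozen covariates converges to the
    closed-form stationary probability of the induced 2-state chain."""
    params = {f: mh.TransitionParams(factor=f) for f in RISK_FACTORS}
    params["smoker"] = mh.TransitionParams(
        factor="smoker", beta0=-2.0, beta2_lag=3.0,
        covariate_betas={"female": 0.4})
    pop = make_state(n=50_000, smoker=0)
    pinned = {f: 0 for f in RISK_FACTORS if f != "smoker"}
    for year in range(2011, 2071):
        mh.update_risk_factors(pop, params, master_seed=23, year=year, pinned=pinned)
    pi = mh.stationary_probability(params["smoker"], make_state(n=1))
    se = math.sqrt(pi * (1 - pi) / len(pop))
    assert abs(pop["smoker"].mean() - pi) < 4 * se


def test_unresolvable_covariate_raises_configuration_error():
    params = mh.TransitionParams(factor="obese", covariate_betas={"bmi": 1.0})
    with pytest.raises(mh.ConfigurationError, match="bmi"):
        mh.transition_probability(params, make_state())
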
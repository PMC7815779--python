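"""Panel-data model fitting and calibration checks."""

import numpy as np
import pandas as pd
import pytest

import microhealth as mh
from helpers import make_state


COVS = ["education_low", "education_medium", "female", "age_c50"]


def test_noiseless_health_panel_recovers_coefficients_exactly():
    params = mh.HealthChangeParams(
        beta0=-0.02, beta1=-0.05, beta2=0.03, beta3=-0.04,
        covariate_betas={"depressed": -0.015, "education_low": -0.03, "female": 0.004})
    records = mh.simulate_health_panel(params, n=5_000, seed=1, sigma=0.0)
    fit = mh.fit_health_change(records, ["depressed", "education_low", "female"])
    assert fit.params["const"] == pytest.approx(-0.02, abs=1e-8)
    assert fit.params["h"] == pytest.approx(-0.05, abs=1e-7)
    assert fit.params["h2"] == pytest.approx(0.03, abs=1e-7)
    assert fit.params["h3"] == pytest.approx(-0.04, abs=1e-7)
    assert fit.params["depressed"] == pytest.approx(-0.015, abs=1e-9)


def test_noisy_health_panel_recovers_within_three_robust_se():
    params = mh.HealthChangeParams(
        beta0=-0.02, beta1=-0.05, beta2=0.03, beta3=-0.04,
        covariate_betas={"depressed": -0.015, "education_low": -0.03})
    records = mh.simulate_health_panel(params, n=30_000, seed=2, sigma=0.2)
    fit = mh.fit_health_change(records, ["depressed", "education_low"])
    truth = {"const": -0.02, "h": -0.05, "h2": 0.03, "h3": -0.04,
             "depressed": -0.015, "education_low": -0.03}
    for name, value in truth.items():
        assert abs(fit.params[name] - value) < 3 * fit.bse[name]


def test_constant_hm_flags_collinearity_and_zeroes_polynomial_terms():
    records = mh.simulate_health_panel(mh.HealthChangeParams(beta0=-0.01),
                                       n=500, seed=3, sigma=0.1)
    records["hm"] = 50.0
    records["hm_t"] = 48.0
    fit = mh.fit_health_change(records, [])
    assert fit.dropped  # h2, h3 (and h) cannot be separated from the constant
    for term in fit.dropped:
        assert fit.params[term] == 0.0
    assert any("collinear" in f for f in fit.flags)


def test_transition_recovery_within_three_robust_se():
    params = mh.TransitionParams(
        factor="obese", beta0=-2.5, beta1_duration=0.15, beta2_lag=4.0,
        covariate_betas={"education_low": 0.692, "female": 0.05, "age_c50": -0.01})
    records = mh.simulate_transition_panel(params, n=30_000, seed=4, a_choices=(1, 2, 3))
    fit = mh.fit_transition(records, "obese",
                            ["education_low", "female", "age_c50"])
    truth = {"const": -2.5, "duration": 0.15, "lag": 4.0,
             "education_low": 0.692, "female": 0.05, "age_c50": -0.01}
    for name, value in truth.items():
        assert abs(fit.params[name] - value) < 3 * fit.bse[name]
    assert 0.5 < fit.c_statistic <= 1.0


def test_duration_term_dropped_and_flagged_when_all_gaps_equal_one():
    params = mh.TransitionParams(factor="smoker", beta0=-1.0, beta2_lag=2.0)
    records = mh.simulate_transition_panel(params, n=2_000, seed=5, a_choices=(1,))
    fit = mh.fit_transition(records, "smoker", [])
    assert "duration" not in fit.params.index
    assert any("not identifiable" in f for f in fit.flags)


def test_duplicated_records_expose_clustering_semantics():
    """Duplicating every record within its cluster leaves the point
    estimates unchanged and the cluster-robust SEs essentially unchanged,
    whereas naive (iid) SEs would shrink by √2 — the clustering absorbs the
    artificial doubling of information."""
    params = mh.TransitionParams(factor="smoker", beta0=-1.0, beta2_lag=2.0,
                                 covariate_betas={"female": 0.3})
    records = mh.simulate_transition_panel(params, n=4_000, seed=6)
    doubled = pd.concat([records, records], ignore_index=True)
    fit1 = mh.fit_transition(records, "smoker", ["female"])
    fit2 = mh.fit_transition(doubled, "smoker", ["female"])
    assert np.allclose(fit1.params, fit2.params, atol=1e-6)
    assert np.allclose(fit1.bse / fit2.bse, 1.0, atol=0.01)

    import statsmodels.api as sm
    X = pd.DataFrame({"const": 1.0, "lag": records["smoker"],
                      "female": (records["sex"] == "female").astype(float)})
    naive1 = sm.GLM(records["outcome"], X, family=sm.families.Binomial()).fit().bse
    X2 = pd.concat([X, X], ignore_index=True)
    naive2 = sm.GLM(doubled["outcome"], X2, family=sm.families.Binomial()).fit().bse
    assert np.allclose(naive1 / naive2, np.sqrt(2), atol=0.01)


def test_single_valued_outcome_rejected():
    params = mh.TransitionParams(factor="smoker", beta0=-30.0)
    records = mh.simulate_transition_panel(params, n=200, seed=7)
    with pytest.raises(mh.ValidationError):
        mh.fit_transition(records, "smoker", [])


def test_perfect_separation_names_the_offending_covariate():
    records = make_state(n=100)
    records["id"] = np.arange(100)
    records["a"] = 1
    records["sex"] = np.where(np.arange(100) < 50, "female", "male")
    records["outcome"] = (records["sex"] == "female").astype(int)
    with pytest.raises(mh.ConfigurationError, match="female"):
        mh.fit_transition(records, "smoker", ["female"])


def test_mortality_recovery_and_no_death_stratum_flag():
    raw = {"bad": 1.1, "medium": 0.45, "good": 0.0}
    records = mh.simulate_mortality_panel(raw, n=40_000, seed=8,
                                          covariate_betas={"education_low": 0.3})
    fit = mh.fit_mortality(records, ["education_low"])
    assert fit.raw_betas["good"] == 0.0
    assert abs(fit.raw_betas["bad"] - 1.1) < 3 * fit.bse["hm_bad"]
    assert abs(fit.raw_betas["medium"] - 0.45) < 3 * fit.bse["hm_medium"]
    assert abs(fit.params["education_low"] - 0.3) < 3 * fit.bse["education_low"]

    # no deaths in one category -> flagged
    records2 = records.copy()
    cats = mh.categorize_hm(records2["hm"].to_numpy())
    records2.loc[cats == "bad", "death"] = 0
    # keep overall variation
    fit2 = mh.fit_mortality(records2, ["education_low"]) if records2["death"].sum() else None
    if fit2 is not None:
        assert any("no deaths" in f for f in fit2.flags)


def test_fitted_raw_betas_flow_into_contrast_centring():
    raw = {"bad": 0.9, "medium": 0.4, "good": 0.0}
    records = mh.simulate_mortality_panel(raw, n=30_000, seed=9)
    fit = mh.fit_mortality(records, [])
    pop = make_state(n=300, hm=np.linspace(1, 99, 300))
    contrast = mh.center_contrasts(fit.raw_betas, pop)
    w = pd.Series(mh.categorize_hm(pop["hm"].to_numpy())).value_counts(normalize=True)
    mean = sum(w[c] * contrast.contrast_betas[c] for c in w.index)
    assert mean == pytest.approx(0.0, abs=1e-9)


def test_c_statistic_hand_examples():
    from microhealth.estimation import _c_statistic
    conc, c = _c_statistic(np.array([0, 1]), np.array([0.2, 0.8]))
    assert conc == 1.0 and c == 1.0
    conc, c = _c_statistic(np.array([0, 1]), np.array([0.5, 0.5]))
    assert conc == 0.0 and c == 0.5  # tie counted 1/2
    # pairs: (0.2 vs 0.8) discordant, (0.2 vs 0.1), (0.9 vs 0.8), (0.9 vs 0.1)
    conc, c = _c_statistic(np.array([0, 1, 0, 1]), np.array([0.8, 0.2, 0.1, 0.9]))
    assert c == pytest.approx(0.75)


def test_mincer_zarnowitz_identity_and_scaling():
    pred = np.linspace(0, 1, 50)
    mz = mh.mincer_zarnowitz(pred, pred)
    assert mz.slope == pytest.approx(1.0, abs=1e-12)
    assert mz.intercept == pytest.approx(0.0, abs=1e-12)
    mz2 = mh.mincer_zarnowitz(2 * pred, pred)
    assert mz2.slope == pytest.approx(2.0, abs=1e-12)


def test_mincer_zarnowitz_on_calibrated_predictions():
    rng = np.random.default_rng(10)
    p = rng.uniform(0.05, 0.95, size=100_000)
    y = (rng.random(100_000) < p).astype(float)
    mz = mh.mincer_zarnowitz(y, p)
    assert 0.95 < mz.slope < 1.05
    assert mz.joint_pvalue > 0.001


def test_simulator_closed_loop_with_fitted_transition_model(cfg):
    """Fitting a simulated panel and plugging the estimates back into the
    simulator reproduces the generating one-step prevalence within MC error."""
    truth = mh.TransitionParams(factor="depressed", beta0=-1.5, beta2_lag=2.5,
                                covariate_betas={"female": 0.45})
    records = mh.simulate_transition_panel(truth, n=40_000, seed=11, a_choices=(1,))
    fit = mh.fit_transition(records, "depressed", ["female"])
    fitted = mh.TransitionParams(factor="depressed",
                                 beta0=fit.params["const"],
                                 beta2_lag=fit.params["lag"],
                                 covariate_betas={"female": fit.params["female"]})
    state = make_state(n=1, sex="female", depressed=1)
    p_true = mh.transition_probability(truth, state)[0]
    p_fit = mh.transition_probability(fitted, state)[0]
    assert abs(p_true - p_fit) < 0.02
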
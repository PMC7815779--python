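"""Model estimation from two-wave panel data, plus calibration checks.

Fits the three model families the simulator consumes:

* risk-factor transitions — logistic ARDL: outcome at t on the duration
  term (a−1), the factor's own lag, and lagged covariates;
* health change — linear model of the per-year change in logit(hm/100) on
  the cubic in lagged health and lagged covariates;
* mortality — logistic model of death between waves on (a−1), the lagged
  health-metric category and sociodemographics, yielding raw category
  effects consumable by contrast centring.

Panels may contain several wave-pair records per individual, so inference
uses pooled estimation with cluster-robust (sandwich) standard errors
grouped by individual id — the independence-working-correlation GEE, whose
point estimates coincide with the ordinary GLM fit.

Record layout: one row per (individual, wave pair) carrying the *lagged*
state under the standard state column names (``age, sex, education,
country, hm, smoker, active, obese, hypertension, depressed``) plus ``id``,
``a`` (gap in years), and the outcome (``outcome`` for transitions,
``hm_t`` for health change, ``death`` for mortality).

The module also provides panel simulators drawing records from known
parameters (for parameter-recovery testing) and the Mincer–Zarnowitz
calibration regression (observed on predicted; unbiased predictions give
slope 1, intercept 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

from .covariates import covariate_vector
from .errors import ConfigurationError, ValidationError
from .health import HealthChangeParams
from .mortality import categorize_hm, category_labels
from .population import EPS_HM, PopulationSpec, generate_base_population
from .transitions import TransitionParams


@dataclass
class FitResult:
    """Coefficients, cluster-robust SEs and diagnostics of one model fit."""

    params: pd.Series
    bse: pd.Series
    model_type: str
    concordance: float | None = None
    c_statistic: float | None = None
    raw_betas: dict[str, float] | None = None  # mortality fits only
    dropped: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    n_records: int = 0
    n_clusters: int = 0


def _c_statistic(y: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """(percent concordant, C-statistic with ties counted 1/2)."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return np.nan, np.nan
    r = rankdata(p)
    c = (r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    p0 = np.sort(p[~y])
    concordant = np.searchsorted(p0, p[y], side="left").sum() / (n1 * n0)
    return float(concordant), float(c)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    """Reject binary covariates that perfectly predict the outcome."""
    for col in X.columns:
        x = X[col].to_numpy()
        if set(np.unique(x)) <= {0.0, 1.0} and x.std() > 0:
            for level in (0.0, 1.0):
                sub = y[x == level]
                if sub.size and (sub.min() == sub.max()) and X.shape[0] > sub.size:
                    other = y[x != level]
                    if other.size and (other.min() != other.max() or other[0] != sub[0]):
                        raise ConfigurationError(
                            f"perfect separation: covariate {col!r} (level {int(level)}) "
                            "fully determines the outcome")


def _duration_column(records: pd.DataFrame) -> tuple[pd.Series | None, list[str]]:
    dur = records["a"].astype(float) - 1.0
    if dur.nunique() <= 1:
        return None, ["duration term (a-1) has no variation at a="
                      f"{records['a'].iloc[0]}; beta1_duration not identifiable, dropped"]
    return dur, []


def _design(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    for name in covariates:
        X[name] = covariate_vector(records, name)
    return X


def fit_transition(records: pd.DataFrame, factor: str,
                   covariates: list[str] | None = None) -> FitResult:
    """Fit one risk factor's ARDL logit transition model.

    ``records[factor]`` is the lagged value; ``records['outcome']`` the
    value at t.  Cluster-robust SEs by ``records['id']``.
    """
    y = records["outcome"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValidationError(f"fit_transition({factor}): outcome has a single value")
    covariates = list(covariates or [])
    X = _design(records, covariates)
    dur, flags = _duration_column(records)
    if dur is not None:
        X.insert(1, "duration", dur)
    X.insert(1 if dur is None else 2, "lag", records[factor].to_numpy(dtype=float))
    _check_separation(X, y)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": records["id"].to_numpy()})
    conc, cstat = _c_statistic(y, res.fittedvalues.to_numpy())
    return FitResult(params=res.params, bse=res.bse, model_type=f"transition:{factor}",
                     concordance=conc, c_statistic=cstat, flags=flags,
                     n_records=len(records), n_clusters=records["id"].nunique())


def fit_health_change(records: pd.DataFrame,
                      covariates: list[str] | None = None) -> FitResult:
    """Fit the yearly logit-scale health-change model.

    Outcome: (logit(hm_t/100) − logit(hm/100)) / a, with ``hm`` the lagged
    value.  Rows with hm at the bounds are ε-clamped with a warning.
    Collinear polynomial terms (e.g. under constant hm) are dropped with a
    flag and reported as zero coefficients.
    """
    h_lag = records["hm"].to_numpy(dtype=float)
    h_t = records["hm_t"].to_numpy(dtype=float)
    at_bounds = (h_lag <= 0) | (h_lag >= 100) | (h_t <= 0) | (h_t >= 100)
    if at_bounds.any():
        warnings.warn(f"fit_health_change: {int(at_bounds.sum())} rows with hm at the "
                      "bounds were clamped to the open interval")
    h_lag = np.clip(h_lag, EPS_HM, 100 - EPS_HM) / 100.0
    h_t = np.clip(h_t, EPS_HM, 100 - EPS_HM) / 100.0
    a = records["a"].to_numpy(dtype=float)
    y = (logit(h_t) - logit(h_lag)) / a

    covariates = list(covariates or [])
    X = _design(records, covariates)
    X.insert(1, "h", h_lag)
    X.insert(2, "h2", h_lag ** 2)
    X.insert(3, "h3", h_lag ** 3)

    # drop columns that do not increase design rank (collinearity guard)
    kept, dropped = ["const"], []
    for col in X.columns[1:]:
        trial = X[kept + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(col)
        else:
            dropped.append(col)
    flags = [f"collinear terms dropped (coefficients reported as 0): {dropped}"] if dropped else []

    res = sm.OLS(y, X[kept]).fit(cov_type="cluster",
                                 cov_kwds={"groups": records["id"].to_numpy()})
    params = res.params.reindex(X.columns, fill_value=0.0)
    bse = res.bse.reindex(X.columns, fill_value=np.nan)
    return FitResult(params=params, bse=bse, model_type="health_change",
                     dropped=dropped, flags=flags,
                     n_records=len(records), n_clusters=records["id"].nunique())


def fit_mortality(records: pd.DataFrame, covariates: list[str] | None = None,
                  cutpoints=(30.0, 60.0)) -> FitResult:
    """Fit the logistic model of death between waves on the lagged
    hm category and sociodemographics.

    The top (healthiest) category is the reference; ``raw_betas`` maps every
    category to its logit effect (reference = 0), directly consumable by
    contrast centring.  Strata (categories) with no deaths are flagged.
    """
    if "death" not in records.columns or records["death"].isna().any():
        raise ValidationError("fit_mortality: death indicator must be defined for every record")
    y = records["death"].to_numpy(dtype=float)
    labels = category_labels(tuple(sorted(cutpoints)))
    cats = categorize_hm(records["hm"].to_numpy(dtype=float), cutpoints)

    flags = []
    for lab in labels:
        mask = cats == lab
        if mask.any() and y[mask].sum() == 0:
            flags.append(f"category {lab!r}: no deaths observed")

    covariates = list(covariates or [])
    X = _design(records, covariates)
    dur, dflags = _duration_column(records)
    flags += dflags
    if dur is not None:
        X.insert(1, "duration", dur)
    _check_separation(X, y)  # category dummies are flagged above, not rejected
    reference = labels[-1]
    for lab in labels[:-1]:
        X[f"hm_{lab}"] = (cats == lab).astype(float)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quasi-separation in a flagged category
        res = model.fit(cov_type="cluster", cov_kwds={"groups": records["id"].to_numpy()})
    conc, cstat = _c_statistic(y, res.fittedvalues.to_numpy())
    raw = {lab: float(res.params.get(f"hm_{lab}", 0.0)) for lab in labels[:-1]}
    raw[reference] = 0.0
    return FitResult(params=res.params, bse=res.bse, model_type="mortality",
                     concordance=conc, c_statistic=cstat, raw_betas=raw, flags=flags,
                     n_records=len(records), n_clusters=records["id"].nunique())


@dataclass
class MincerZarnowitz:
    slope: float
    intercept: float
    joint_stat: float
    joint_pvalue: float


def mincer_zarnowitz(observed, predicted) -> MincerZarnowitz:
    """Calibration regression of observed on predicted values.

    Unbiased predictions give slope 1 and intercept 0; the joint Wald test
    checks (intercept, slope) = (0, 1).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("mincer_zarnowitz: observed and predicted must have equal length")
    X = sm.add_constant(pred)
    res = sm.OLS(obs, X).fit()
    if res.ssr < 1e-24:  # exact fit: the joint test is degenerate
        stat, pvalue = np.inf if (abs(res.params[0]) > 1e-9 or abs(res.params[1] - 1) > 1e-9) else 0.0, 1.0
    else:
        test = res.f_test((np.eye(2), np.array([0.0, 1.0])))
        stat, pvalue = float(test.statistic), float(test.pvalue)
    return MincerZarnowitz(slope=float(res.params[1]), intercept=float(res.params[0]),
                           joint_stat=stat, joint_pvalue=pvalue)


# ---------------------------------------------------------------------------
# panel simulators (known-parameter generators for recovery testing)

def _covariate_frame(n: int, seed: int, records_per_id: int = 1) -> pd.DataFrame:
    """Lagged-state covariate draws: a synthetic cross-section reused as the
    state at t−a."""
    n_ids = n // records_per_id
    spec = PopulationSpec(n_individuals=n_ids, seed=seed)
    base = generate_base_population(spec)
    if records_per_id > 1:
        base = pd.concat([base] * records_per_id, ignore_index=True)
    return base


def simulate_transition_panel(params: TransitionParams, n: int, seed: int,
                              a_choices=(1, 2), records_per_id: int = 1) -> pd.DataFrame:
    """Draw a two-wave panel from a known transition model."""
    records = _covariate_frame(n, seed, records_per_id)
    rng = np.random.default_rng(seed + 1)
    records["a"] = rng.choice(a_choices, size=len(records))
    from .transitions import transition_probability
    eta = logit(np.clip(transition_probability(params, records, 1), 1e-12, 1 - 1e-12))
    eta += params.beta1_duration * (records["a"].to_numpy() - 1)
    records["outcome"] = (rng.random(len(records)) < expit(eta)).astype(int)
    return records


def simulate_health_panel(params: HealthChangeParams, n: int, seed: int,
                          sigma: float = 0.2, a_choices=(1, 2),
                          records_per_id: int = 1) -> pd.DataFrame:
    """Draw a two-wave panel from a known health-change model.

    Noise is Gaussian on the per-year rate of change of logit(hm/100);
    sigma = 0 gives a noiseless (deterministic) panel.
    """
    from .health import hm_delta
    records = _covariate_frame(n, seed, records_per_id)
    rng = np.random.default_rng(seed + 1)
    a = rng.choice(a_choices, size=len(records)).astype(float)
    rate = hm_delta(params, records)
    if sigma > 0:
        rate = rate + sigma * rng.standard_normal(len(records))
    h = np.clip(records["hm"].to_numpy(dtype=float), EPS_HM, 100 - EPS_HM) / 100.0
    records["a"] = a
    records["hm_t"] = 100.0 * expit(logit(h) + a * rate)
    return records


def simulate_mortality_panel(raw_betas: dict[str, float], n: int, seed: int,
                             beta0: float = -4.0, beta1_duration: float = 0.3,
                             covariate_betas: dict[str, float] | None = None,
                             cutpoints=(30.0, 60.0), a_choices=(1, 2),
                             records_per_id: int = 1) -> pd.DataFrame:
    """Draw a two-wave mortality panel from known category effects
    (reference category beta must be 0)."""
    from .covariates import linear_predictor
    records = _covariate_frame(n, seed, records_per_id)
    rng = np.random.default_rng(seed + 1)
    records["a"] = rng.choice(a_choices, size=len(records))
    cats = categorize_hm(records["hm"].to_numpy(dtype=float), cutpoints)
    eta = linear_predictor(records, beta0, covariate_betas or {})
    eta += beta1_duration * (records["a"].to_numpy() - 1)
    eta += np.vectorize(lambda c: raw_betas[c])(cats)
    records["death"] = (rng.random(len(records)) < expit(eta)).astype(int)
    return records
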
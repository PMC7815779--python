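"""Yearly stochastic risk-factor transitions.

Each of the five binary risk factors follows an autoregressive distributed
lag (ARDL) model on the logit scale: the probability of holding the factor
at time t is

    logit(p) = β0 + β1·(a−1) + β2·F_{t−a} + Σ_i β_i X_{i,t−a}

with a the gap in years between observations (a = 1 inside the simulator,
so the duration term vanishes), F_{t−a} the factor's own lag and X the
lagged covariates (other risk factors, sex, education, age).  This is a
*net* probability: entry and exit flows are absorbed into one logistic
model, so β0 + β2 at a = 1 is the probability of still holding a factor one
already has (all other covariates at reference).

Updates are synchronous: all five factors are redrawn as independent
Bernoulli trials whose probabilities are evaluated on the start-of-step
snapshot, each from its own per-individual random substream.  A factor may
be *pinned* to 0 or 1 by the scenario engine, in which case its draw is
skipped entirely (its substream is never consumed, so other factors' draws
are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import RISK_FACTORS, AgeSpline, linear_predictor
from .errors import ConfigurationError
from .rng import substream_uniforms


@dataclass
class TransitionParams:
    """Coefficients of one risk factor's ARDL logit transition model."""

    factor: str
    beta0: float = 0.0
    beta1_duration: float = 0.0
    beta2_lag: float = 0.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    age_spline: AgeSpline | None = None

    def __post_init__(self) -> None:
        if self.factor not in RISK_FACTORS:
            raise ConfigurationError(
                f"unknown risk factor {self.factor!r}; expected one of {RISK_FACTORS}")


def transition_probability(
    params: TransitionParams, state: pd.DataFrame, duration_years: int = 1
) -> np.ndarray:
    """P(factor = 1 at t) for each individual, evaluated on the lagged state.

    ``duration_years`` is the gap a between the lagged state and the
    prediction time; the duration term β1·(a−1) contributes exactly 0 at
    a = 1, the simulator's step length.
    """
    if duration_years < 1:
        raise ConfigurationError("duration_years must be >= 1")
    lag = state[params.factor].to_numpy(dtype=float)
    eta = linear_predictor(state, params.beta0, params.covariate_betas)
    eta += params.beta1_duration * (duration_years - 1) + params.beta2_lag * lag
    if params.age_spline is not None:
        eta += params.age_spline(state["age"].to_numpy(dtype=float))
    return expit(eta)


def update_risk_factors(
    population: pd.DataFrame,
    params_set: dict[str, TransitionParams],
    master_seed: int,
    year: int,
    pinned: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Redraw all five risk factors for alive individuals (in place).

    All transition probabilities are computed on the start-of-step snapshot
    before any factor is written back (synchronous update), so within-year
    ordering of the factors is irrelevant.  Dead individuals are untouched.
    """
    pinned = pinned or {}
    for factor in RISK_FACTORS:
        if factor not in pinned and factor not in params_set:
            raise ConfigurationError(f"no transition parameters for factor {factor!r}")

    alive = population["alive"].to_numpy()
    if not alive.any():
        return population
    snapshot = population.loc[alive]
    ids = snapshot["id"].to_numpy()

    new_values: dict[str, np.ndarray] = {}
    for factor in RISK_FACTORS:
        if factor in pinned:
            new_values[factor] = np.full(len(snapshot), pinned[factor], dtype=np.int8)
            continue
        p = transition_probability(params_set[factor], snapshot, duration_years=1)
        u = substream_uniforms(master_seed, year, factor, ids)
        new_values[factor] = (u < p).astype(np.int8)
    for factor, values in new_values.items():
        population.loc[alive, factor] = values
    return population


def stationary_probability(params: TransitionParams, state_row: pd.DataFrame) -> float:
    """Closed-form stationary P(factor = 1) of the induced 2-state chain.

    With fixed covariates the factor is a two-state Markov chain with
    p01 = P(1 | lag 0) and p11 = P(1 | lag 1); the stationary probability is
    p01 / (1 + p01 − p11).  Used as an independent check of long-run
    behaviour.
    """
    row = state_row.iloc[[0]].copy()
    row[params.factor] = 0
    p01 = float(transition_probability(params, row)[0])
    row[params.factor] = 1
    p11 = float(transition_probability(params, row)[0])
    return p01 / (1.0 + p01 - p11)
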
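"""Deterministic yearly update of the continuous health metric.

The health metric hm ∈ [0, 100] summarises functional health (higher is
healthier).  Its yearly change is modelled on the logit scale: with
h = hm/100, the one-year change in logit(h) is

    Δ = β0 + β1·h + β2·h² + β3·h³ + Σ_i β_i X_i

where the cubic in current health lets the decline rate depend on the
current level (empirically health declines faster from good health), and
the covariates X are the lagged risk factors, education, sex and age.  The
update composes on the logit scale,

    logit(h_{t+1}) = logit(h_t) + Δ,

then back-transforms and clamps to [ε, 100−ε], so hm can never leave its
bounds and the logit is always finite.  Given the covariates the step is
fully deterministic — all stochasticity in a trajectory enters through the
risk factors and survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .covariates import AgeSpline, linear_predictor
from .population import EPS_HM


@dataclass
class HealthChangeParams:
    """Coefficients of the yearly logit-scale health-change model."""

    beta0: float = 0.0
    beta1: float = 0.0  # on h = hm/100
    beta2: float = 0.0  # on h^2
    beta3: float = 0.0  # on h^3
    covariate_betas: dict[str, float] = field(default_factory=dict)
    age_spline: AgeSpline | None = None


def hm_delta(params: HealthChangeParams, state: pd.DataFrame) -> np.ndarray:
    """Yearly change in logit(hm/100), evaluated on the current snapshot."""
    h = state["hm"].to_numpy(dtype=float) / 100.0
    delta = linear_predictor(state, params.beta0, params.covariate_betas)
    delta += h * (params.beta1 + h * (params.beta2 + h * params.beta3))
    if params.age_spline is not None:
        delta += params.age_spline(state["age"].to_numpy(dtype=float))
    return delta


def update_hm(params: HealthChangeParams, state: pd.DataFrame) -> np.ndarray:
    """New hm values: 100·expit(logit(hm/100) + Δ), clamped to [ε, 100−ε]."""
    h = np.clip(state["hm"].to_numpy(dtype=float), EPS_HM, 100.0 - EPS_HM) / 100.0
    new = 100.0 * expit(logit(h) + hm_delta(params, state))
    return np.clip(new, EPS_HM, 100.0 - EPS_HM)
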
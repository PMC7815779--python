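"""Covariate resolution and age effects.

Model blocks (risk-factor transitions, health change, imputation) refer to
covariates by name.  A name must resolve to a field or derived term of the
individual state table; anything else is a configuration error raised before
simulation work starts.

Supported names
---------------
``smoker, active, obese, hypertension, depressed``
    the lagged (start-of-step) risk-factor flags;
``inactive``
    derived term ``1 - active`` — physical inactivity as a risk factor;
``female, male``
    sex indicators;
``education_low, education_medium, education_high``
    education-level indicators (high is the conventional reference);
``age, age_c50``
    age in years, raw or centred at 50;
``hm01``
    the health metric rescaled to [0, 1];
``country_<CODE>``
    indicator for country of residence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

RISK_FACTORS = ("smoker", "active", "obese", "hypertension", "depressed")


def covariate_vector(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a covariate name against a population snapshot."""
    if name in RISK_FACTORS:
        return df[name].to_numpy(dtype=float)
    if name == "inactive":
        return 1.0 - df["active"].to_numpy(dtype=float)
    if name in ("female", "male"):
        return (df["sex"].to_numpy() == name).astype(float)
    if name.startswith("education_"):
        level = name.removeprefix("education_")
        if level not in ("low", "medium", "high"):
            raise ConfigurationError(f"unknown education level in covariate {name!r}")
        return (df["education"].to_numpy() == level).astype(float)
    if name == "age":
        return df["age"].to_numpy(dtype=float)
    if name == "age_c50":
        return df["age"].to_numpy(dtype=float) - 50.0
    if name == "hm01":
        return df["hm"].to_numpy(dtype=float) / 100.0
    if name.startswith("country_"):
        return (df["country"].to_numpy() == name.removeprefix("country_")).astype(float)
    raise ConfigurationError(f"covariate {name!r} does not resolve to an individual-state field")


def linear_predictor(
    df: pd.DataFrame, intercept: float, covariate_betas: dict[str, float]
) -> np.ndarray:
    """``intercept + Σ beta * covariate`` evaluated on a snapshot."""
    eta = np.full(len(df), float(intercept))
    for name, beta in covariate_betas.items():
        if beta != 0.0:
            eta += float(beta) * covariate_vector(df, name)
    return eta


@dataclass
class AgeSpline:
    """Piecewise-linear age effect on the logit scale.

    Continuous by construction; constant extrapolation beyond the outer
    knots.  Knots must be strictly increasing.
    """

    knots: list[float] = field(default_factory=lambda: [50.0, 60.0, 75.0, 90.0])
    values: list[float] = field(default_factory=lambda: [0.0, 0.0, 0.0, 0.0])

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if k.ndim != 1 or k.size < 2 or not np.all(np.diff(k) > 0):
            raise ConfigurationError("age spline knots must be strictly increasing (>= 2 knots)")
        if v.shape != k.shape:
            raise ConfigurationError("age spline needs one value per knot")
        self._k, self._v = k, v

    def __call__(self, age: np.ndarray | float) -> np.ndarray | float:
        return np.interp(age, self._k, self._v)
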
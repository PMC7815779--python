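"""Base-population generation and loading.

The simulator starts from a closed cohort of individuals aged 50+ in the
start year (cohorts born before 1961; later cohorts are outside the observed
age range and are never simulated).  A base population can be loaded from a
CSV, or generated synthetically:

1. demographics (birth year, sex, country) are drawn from configurable
   marginal weights, with education drawn from a cohort-dependent
   composition in which the low-education share falls from about 70% in
   pre-1930 cohorts to below 30% in the 1956-60 cohorts — the educational
   expansion that drives cohort replacement ("demographic metabolism");
2. the five binary risk factors are imputed sequentially, each drawn from a
   logistic model conditioned on demographics and the factors drawn before
   it (a fixed-order analogue of chained-equation imputation: smoking →
   activity → obesity → hypertension → depression);
3. the continuous health metric hm ∈ [0, 100] is imputed from a linear model
   on logit(hm/100) with Gaussian noise, back-transformed and clamped to
   [ε, 100−ε] so the logit stays finite.

Everything is reproducible given ``PopulationSpec.seed``; draws use
per-individual id-indexed substreams (see :mod:`microhealth.rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import RISK_FACTORS, AgeSpline, linear_predictor
from .errors import ConfigurationError, ValidationError
from .rng import substream_normals, substream_uniforms

EPS_HM = 1e-3  # clamp on the 0-100 scale so logit(hm/100) is always finite
MAX_BIRTH_YEAR = 1960

POPULATION_COLUMNS = [
    "id", "birth_year", "age", "sex", "education", "country", "alive", "hm",
    "smoker", "active", "obese", "hypertension", "depressed",
]

IMPUTATION_ORDER = ("smoker", "active", "obese", "hypertension", "depressed")


@dataclass
class ImputationModel:
    """Logistic (or, for hm, linear-on-logit) imputation block."""

    intercept: float = 0.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    age_spline: AgeSpline | None = None

    def eta(self, df: pd.DataFrame) -> np.ndarray:
        out = linear_predictor(df, self.intercept, self.covariate_betas)
        if self.age_spline is not None:
            out = out + self.age_spline(df["age"].to_numpy(dtype=float))
        return out


@dataclass
class PopulationSpec:
    """Conditions the synthetic base population is drawn under."""

    n_individuals: int = 10_000
    start_year: int = 2011
    seed: int = 0
    # P(birth_year): weights over integer birth years
    cohort_weights: dict[int, float] = field(default_factory=dict)
    # P(male | birth_year) = expit(a + b * (start_age - 50)): female share
    # rises with age through differential survival
    sex_model: tuple[float, float] = (-0.05, -0.012)
    country_weights: dict[str, float] = field(default_factory=dict)
    # P(low | birth_year) = expit(a + b*(birth_year - ref)); medium takes a
    # fixed share of the non-low remainder
    education_low_intercept: float = -0.269
    education_low_slope: float = -0.0558
    education_ref_year: int = 1945
    education_medium_share: float = 0.55
    imputation_models: dict[str, ImputationModel] = field(default_factory=dict)
    hm_imputation: ImputationModel = field(default_factory=ImputationModel)
    hm_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not self.cohort_weights:
            self.cohort_weights = default_cohort_weights(self.start_year)
        if not self.country_weights:
            self.country_weights = dict(DEFAULT_COUNTRY_WEIGHTS)
        for factor in IMPUTATION_ORDER:
            self.imputation_models.setdefault(factor, ImputationModel())

    # -- conditional distributions -------------------------------------------------

    def education_probs(self, birth_year: np.ndarray) -> np.ndarray:
        """(n, 3) matrix of P(low, medium, high | cohort)."""
        by = np.asarray(birth_year, dtype=float)
        p_low = expit(self.education_low_intercept
                      + self.education_low_slope * (by - self.education_ref_year))
        p_med = (1.0 - p_low) * self.education_medium_share
        p_high = 1.0 - p_low - p_med
        return np.column_stack([p_low, p_med, p_high])

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("population: n_individuals must be >= 1")
        for name, table in (("cohort_weights", self.cohort_weights),
                            ("country_weights", self.country_weights)):
            vals = np.asarray(list(table.values()), dtype=float)
            if vals.size == 0 or np.any(vals < 0) or vals.sum() <= 0:
                raise ConfigurationError(f"population.{name}: weights must be non-negative and sum > 0")
        if any(int(by) > MAX_BIRTH_YEAR for by in self.cohort_weights):
            raise ConfigurationError(
                f"population.cohort_weights: birth years must be <= {MAX_BIRTH_YEAR}")
        if not 0.0 <= self.education_medium_share <= 1.0:
            raise ConfigurationError("population.education_medium_share must lie in [0, 1]")
        years = np.array(sorted(self.cohort_weights))
        p_low = self.education_probs(years)[:, 0]
        if np.any(np.diff(p_low) > 1e-12):
            raise ConfigurationError(
                "population: P(low education | cohort) must be non-increasing in birth year")
        if self.hm_sigma < 0:
            raise ConfigurationError("population.hm_sigma must be >= 0")


def default_cohort_weights(start_year: int = 2011) -> dict[int, float]:
    """Cohort sizes for birth years 1920-1960: larger recent cohorts thinned
    at old ages by past mortality (weight halves roughly every 17 years of
    age above 50)."""
    years = np.arange(1920, MAX_BIRTH_YEAR + 1)
    age = start_year - years
    w = np.exp(-0.04 * (age - 50.0))
    w /= w.sum()
    return {int(y): float(x) for y, x in zip(years, w)}


# Rough relative population sizes for the 14 study countries.
DEFAULT_COUNTRY_WEIGHTS = {
    "AT": 2.0, "BE": 2.6, "CZ": 2.5, "DE": 19.0, "DK": 1.3, "EE": 0.3,
    "ES": 11.0, "FR": 15.0, "GR": 2.6, "IT": 14.0, "NL": 4.0, "PL": 9.0,
    "SE": 2.2, "SI": 0.5,
}


def _weighted_choice(u: np.ndarray, keys: list, weights: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorical draw from per-individual uniforms."""
    p = np.asarray(weights, dtype=float)
    cdf = np.cumsum(p / p.sum())
    idx = np.searchsorted(cdf, u, side="right").clip(0, len(keys) - 1)
    return np.asarray(keys, dtype=object)[idx]


def generate_base_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a synthetic base population for the start year.

    Returns a DataFrame with one row per individual (columns
    ``POPULATION_COLUMNS``), reproducible given ``spec.seed``.
    """
    spec.validate()
    n = spec.n_individuals
    ids = np.arange(n, dtype=np.int64)
    seed = spec.seed

    # demographics share one substream; fixed draw order keeps replay stable
    demo = substream_uniforms(seed, 0, "demographics", ids)
    g = np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(0, 111))))
    u_sex, u_country, u_edu = g.random((3, n))

    cohort_years = sorted(spec.cohort_weights)
    birth_year = _weighted_choice(
        demo, cohort_years, np.array([spec.cohort_weights[y] for y in cohort_years])
    ).astype(np.int64)
    age = (spec.start_year - birth_year).astype(float)

    a, b = spec.sex_model
    p_male = expit(a + b * (age - 50.0))
    sex = np.where(u_sex < p_male, "male", "female")

    countries = sorted(spec.country_weights)
    country = _weighted_choice(
        u_country, countries, np.array([spec.country_weights[c] for c in countries])
    ).astype(str)

    probs = spec.education_probs(birth_year)
    edu_cdf = np.cumsum(probs, axis=1)
    edu_idx = (u_edu[:, None] >= edu_cdf).sum(axis=1).clip(0, 2)
    education = np.asarray(["low", "medium", "high"], dtype=object)[edu_idx]

    df = pd.DataFrame({
        "id": ids,
        "birth_year": birth_year,
        "age": age,
        "sex": sex,
        "education": education,
        "country": country,
        "alive": np.ones(n, dtype=bool),
        "hm": np.zeros(n, dtype=float),
        "smoker": np.zeros(n, dtype=np.int8),
        "active": np.zeros(n, dtype=np.int8),
        "obese": np.zeros(n, dtype=np.int8),
        "hypertension": np.zeros(n, dtype=np.int8),
        "depressed": np.zeros(n, dtype=np.int8),
    })

    # sequential conditional imputation, fixed visit order
    for factor in IMPUTATION_ORDER:
        model = spec.imputation_models[factor]
        p = expit(model.eta(df))
        u = substream_uniforms(seed, 0, f"impute_{factor}", ids)
        df[factor] = (u < p).astype(np.int8)

    eta = spec.hm_imputation.eta(df)
    if spec.hm_sigma > 0:
        eta = eta + spec.hm_sigma * substream_normals(seed, 0, "impute_hm", ids)
    df["hm"] = np.clip(100.0 * expit(eta), EPS_HM, 100.0 - EPS_HM)
    return df


def load_population(path) -> pd.DataFrame:
    """Load and validate a base population CSV.

    Rows violating structural invariants (hm outside [0, 100], birth year
    after 1960, non-binary factor flags) are reported with their row index;
    any violation aborts the load.
    """
    df = pd.read_csv(path)
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns and c != "alive"]
    if missing:
        raise ValidationError(f"population file {path}: missing columns {missing}")
    if "alive" not in df.columns:
        df["alive"] = True

    problems: list[str] = []

    def check(mask: np.ndarray, message: str) -> None:
        for i in np.flatnonzero(np.asarray(mask))[:20]:
            problems.append(f"row {i}: {message}")

    check(~df["hm"].between(0, 100), "hm outside [0, 100]")
    check(df["birth_year"] > MAX_BIRTH_YEAR, f"birth_year > {MAX_BIRTH_YEAR} (cohort outside observed range)")
    check(~df["sex"].isin(["male", "female"]), "sex must be 'male' or 'female'")
    check(~df["education"].isin(["low", "medium", "high"]), "education must be low/medium/high")
    check(df["id"].duplicated() | (df["id"] < 0), "id must be a unique non-negative integer")
    for factor in RISK_FACTORS:
        check(~df[factor].isin([0, 1]), f"{factor} must be 0 or 1")
    if problems:
        raise ValidationError(f"population file {path}: invalid rows", rows=problems)

    df = df[POPULATION_COLUMNS].copy()
    df["id"] = df["id"].astype(np.int64)
    df["age"] = df["age"].astype(float)
    df["alive"] = df["alive"].astype(bool)
    df["hm"] = df["hm"].astype(float).clip(EPS_HM, 100.0 - EPS_HM)
    for factor in RISK_FACTORS:
        df[factor] = df[factor].astype(np.int8)
    return df.reset_index(drop=True)
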
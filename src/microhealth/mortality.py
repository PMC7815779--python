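"""Health-modulated survival.

Each alive individual faces a baseline yearly death probability q looked up
(or computed from a Gompertz-type schedule) by age, sex, education, country
and calendar year, then shifted on the logit scale by a contrast effect for
the individual's health-metric category:

    q' = expit( logit(q) + β_c ),    c = category of start-of-year hm.

The category effects β_c come from a logistic model of death on the
categorised health metric; before use they are re-centred so that the whole
population is the reference ("contrast centring").  Two centrings are
available:

* arithmetic: subtract the population-share-weighted mean of the raw
  effects, so the weighted mean logit shift at baseline is exactly zero;
* death-calibrated: given each individual's baseline q, solve for the
  single offset m such that Σ expit(logit(q_i) + raw_c(i) − m) = Σ q_i —
  the adjustment then preserves the first-year expected death count
  *exactly*, not just to first order.  The simulation engine uses this
  path, because when baseline risk correlates with health category (old
  people are both frailer and likelier to die) the arithmetic centring
  preserves the mean logit shift but not the expected deaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError
from .rng import substream_uniforms

DEFAULT_CUTPOINTS = (30.0, 60.0)
DEFAULT_CATEGORY_LABELS = ("bad", "medium", "good")


def category_labels(cutpoints) -> tuple[str, ...]:
    k = len(cutpoints) + 1
    if k == 3:
        return DEFAULT_CATEGORY_LABELS
    return tuple(f"cat{i}" for i in range(k))


def categorize_hm(hm, cutpoints=DEFAULT_CUTPOINTS) -> np.ndarray:
    """Bin the health metric into categories, half-open [lo, hi) bins.

    With the default cutpoints (30, 60): bad = [0, 30), medium = [30, 60),
    good = [60, 100].  Empty cutpoints give a single (degenerate) category.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.size and np.any(np.diff(cut) <= 0):
        raise ConfigurationError("hm cutpoints must be strictly increasing")
    labels = category_labels(cut)
    idx = np.searchsorted(cut, np.atleast_1d(np.asarray(hm, dtype=float)), side="right")
    out = np.asarray(labels, dtype=object)[idx]
    return out if np.ndim(hm) else out[0]


@dataclass
class GompertzSchedule:
    """Synthetic baseline schedule: logit(q) linear in age with additive
    shifts by sex, education and country and a calendar-year trend
    (negative trend = improving longevity).  Illustrative stand-in for an
    externally supplied mortality table."""

    intercept: float = -6.2        # logit q at age 50, male, high education
    slope_age: float = 0.105       # per year of age
    sex_shifts: dict[str, float] = field(default_factory=lambda: {"male": 0.0, "female": -0.4})
    education_shifts: dict[str, float] = field(
        default_factory=lambda: {"low": 0.25, "medium": 0.10, "high": 0.0})
    country_shifts: dict[str, float] = field(default_factory=dict)
    year_trend: float = -0.01      # per calendar year since ref_year
    ref_year: int = 2011
    max_age: float = 110.0

    def q(self, df: pd.DataFrame, year: int) -> np.ndarray:
        age = np.minimum(df["age"].to_numpy(dtype=float), self.max_age)
        eta = self.intercept + self.slope_age * (age - 50.0)
        eta += np.vectorize(lambda s: self.sex_shifts.get(s, 0.0))(df["sex"].to_numpy())
        eta += np.vectorize(lambda e: self.education_shifts.get(e, 0.0))(df["education"].to_numpy())
        if self.country_shifts:
            eta += np.vectorize(lambda c: self.country_shifts.get(c, 0.0))(df["country"].to_numpy())
        eta += self.year_trend * (year - self.ref_year)
        return expit(eta)


class MortalityBaseline:
    """Baseline yearly death probabilities by (age, sex, education, country,
    year), from either a parametric Gompertz-type schedule or a long-format
    table.  Table lookups clamp age and year to the tabulated range
    (constant extrapolation); a missing (sex, education, country) stratum is
    a configuration error."""

    def __init__(self, schedule: GompertzSchedule | None = None,
                 table: pd.DataFrame | None = None):
        if (schedule is None) == (table is None):
            raise ConfigurationError("provide exactly one of schedule or table")
        self.schedule = schedule
        self.table = None
        if table is not None:
            required = {"age", "sex", "education", "country", "year", "q"}
            if not required.issubset(table.columns):
                raise ConfigurationError(
                    f"mortality table must have columns {sorted(required)}")
            if ((table["q"] < 0) | (table["q"] > 1)).any():
                raise ConfigurationError("mortality table: q outside [0, 1]")
            t = table.copy()
            t["age"] = t["age"].astype(int)
            self.table = t.set_index(["sex", "education", "country", "year", "age"])["q"].sort_index()
            self._ages = np.array(sorted(table["age"].astype(int).unique()))
            self._years = np.array(sorted(table["year"].unique()))

    def q(self, df: pd.DataFrame, year: int) -> np.ndarray:
        if self.schedule is not None:
            return self.schedule.q(df, year)
        year_c = int(np.clip(year, self._years.min(), self._years.max()))
        ages = np.clip(df["age"].to_numpy(dtype=float).astype(int),
                       self._ages.min(), self._ages.max())
        # snap to nearest tabulated age
        ages = self._ages[np.searchsorted(self._ages, ages).clip(0, len(self._ages) - 1)]
        keys = pd.MultiIndex.from_arrays(
            [df["sex"], df["education"], df["country"],
             np.full(len(df), year_c), ages])
        q = self.table.reindex(keys).to_numpy()
        if np.isnan(q).any():
            bad = keys[np.isnan(q)][0]
            raise ConfigurationError(f"mortality table: missing stratum {tuple(bad)}")
        return q


@dataclass
class MortalityContrast:
    """Per-category logit effects on mortality after contrast centring."""

    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    raw_betas: dict[str, float] = field(default_factory=dict)
    contrast_betas: dict[str, float] = field(default_factory=dict)

    def beta_for(self, hm: np.ndarray) -> np.ndarray:
        cats = categorize_hm(hm, self.cutpoints)
        return np.vectorize(lambda c: self.contrast_betas[c])(np.atleast_1d(cats))


def center_contrasts(
    raw_betas: dict[str, float],
    population: pd.DataFrame,
    cutpoints=DEFAULT_CUTPOINTS,
    baseline_q: np.ndarray | None = None,
) -> MortalityContrast:
    """Centre raw category effects so the whole population is the reference.

    Without ``baseline_q``: arithmetic centring — subtract the
    population-share-weighted mean of the raw effects, so
    Σ_c w_c · contrast_c = 0 with w_c the base-population category shares
    (zero-weight categories are excluded from the mean with a warning).

    With ``baseline_q`` (one baseline death probability per alive
    individual): death-calibrated centring — subtract the uniform offset m
    solving Σ expit(logit(q_i) + raw_c(i) − m) = Σ q_i, so the adjustment
    leaves the first-year expected death count unchanged.
    """
    if population.empty:
        raise ConfigurationError("center_contrasts: population is empty")
    labels = category_labels(tuple(sorted(cutpoints)))
    for c in labels:
        if c not in raw_betas:
            raise ConfigurationError(f"center_contrasts: no raw beta for category {c!r}")
    alive = population[population["alive"]] if "alive" in population.columns else population
    cats = categorize_hm(alive["hm"].to_numpy(dtype=float), cutpoints)
    shares = {c: float(np.mean(cats == c)) for c in labels}

    if baseline_q is None:
        present = {c: w for c, w in shares.items() if w > 0}
        absent = [c for c in labels if c not in present]
        if absent:
            warnings.warn(
                f"center_contrasts: categories {absent} have zero population weight; "
                "excluded from the reference mean")
        mean = sum(w * raw_betas[c] for c, w in present.items()) / sum(present.values())
        contrasts = {c: raw_betas[c] - mean for c in labels}
    else:
        q = np.asarray(baseline_q, dtype=float)
        if q.shape[0] != len(alive):
            raise ConfigurationError("baseline_q must have one entry per alive individual")
        raw = np.vectorize(lambda c: raw_betas[c])(cats)
        lq = logit(np.clip(q, 1e-12, 1 - 1e-12))
        target = q.sum()

        def excess(m: float) -> float:
            return expit(lq + raw - m).sum() - target

        lo = min(raw_betas.values()) - 1.0
        hi = max(raw_betas.values()) + 1.0
        e_lo, e_hi = excess(lo), excess(hi)
        if e_lo <= 0.0 <= e_hi or e_hi <= 0.0 <= e_lo:
            m = brentq(excess, lo, hi, xtol=1e-12)
        else:
            # degenerate q (all 0 or 1): the shift cannot move expected
            # deaths, so centre arithmetically on the category shares
            present = {c: w for c, w in shares.items() if w > 0}
            m = sum(w * raw_betas[c] for c, w in present.items()) / sum(present.values())
        contrasts = {c: raw_betas[c] - m for c in labels}

    return MortalityContrast(cutpoints=tuple(sorted(cutpoints)),
                             raw_betas=dict(raw_betas), contrast_betas=contrasts)


def adjusted_mortality(q, contrast_beta):
    """expit(logit(q) + β); q = 0 and q = 1 are fixed points by continuity."""
    q = np.asarray(q, dtype=float)
    out = np.where(
        (q <= 0.0) | (q >= 1.0),
        q,
        expit(logit(np.clip(q, 1e-300, 1 - 1e-16)) + contrast_beta),
    )
    return out if out.ndim else float(out)


def draw_survival(
    population: pd.DataFrame,
    baseline: MortalityBaseline,
    contrast: MortalityContrast,
    master_seed: int,
    year: int,
) -> np.ndarray:
    """Draw this year's deaths; returns the boolean death mask (aligned to
    the full population) and updates ``alive`` in place.

    Each alive individual dies with probability
    ``adjusted_mortality(q, β_category(start-of-year hm))``.
    """
    alive = population["alive"].to_numpy()
    death_mask = np.zeros(len(population), dtype=bool)
    if not alive.any():
        return death_mask
    snapshot = population.loc[alive]
    q = baseline.q(snapshot, year)
    beta = contrast.beta_for(snapshot["hm"].to_numpy(dtype=float))
    q_adj = adjusted_mortality(q, beta)
    u = substream_uniforms(master_seed, year, "mortality", snapshot["id"].to_numpy())
    died = u < q_adj
    death_mask[np.flatnonzero(alive)[died]] = True
    population.loc[death_mask, "alive"] = False
    return death_mask
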
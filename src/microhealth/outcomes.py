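"""Outcome aggregation.

Three headline outcomes, computable from a simulation history (one record
per individual per year lived, with start-of-year state and a death flag):

* **average health** — unweighted arithmetic mean of the health metric over
  individuals alive in each stratum-year;
* **NYLP** — number of years lived per person: total person-years over the
  projection window divided by the initial population size.  Person-years
  use the mid-year convention: the year of death contributes 0.5;
* **NYLP in good health** — same denominator, but only person-years whose
  start-of-year hm is at or above the good-health threshold (default 60)
  are counted.

All statistics can be broken down by cohort group, age group, education and
calendar year.  Strata with no alive individuals are omitted rather than
reported as NaN.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .covariates import RISK_FACTORS
from .errors import ConfigurationError

DEMOGRAPHIC_COLUMNS = ["birth_year", "sex", "education", "country"]


def attach_demographics(history: pd.DataFrame, base_population: pd.DataFrame) -> pd.DataFrame:
    """Join the invariant demographics onto the history by individual id."""
    cols = [c for c in DEMOGRAPHIC_COLUMNS if c not in history.columns]
    if not cols:
        return history
    demo = base_population.set_index("id")[cols]
    return history.join(demo, on="id")


def _five_year_label(values: np.ndarray) -> np.ndarray:
    lo = (values // 5) * 5
    return np.char.add(np.char.add(lo.astype(int).astype(str), "-"),
                       (lo + 4).astype(int).astype(str))


def add_strata(df: pd.DataFrame, stratifier: Iterable[str]) -> tuple[pd.DataFrame, list[str]]:
    """Materialise derived stratum columns (cohort_group, age_group)."""
    df = df.copy()
    keys = list(stratifier)
    if "cohort_group" in keys:
        df["cohort_group"] = _five_year_label(df["birth_year"].to_numpy())
    if "age_group" in keys:
        df["age_group"] = _five_year_label(np.floor(df["age"].to_numpy()))
    return df, keys


def average_hm(history: pd.DataFrame, stratifier: Sequence[str] = ("year",)) -> pd.DataFrame:
    """Mean hm over alive individuals per stratum (long format)."""
    if history.empty:
        raise ConfigurationError("average_hm: history is empty")
    df, keys = add_strata(history, stratifier)
    g = df.groupby(keys, observed=True)["hm"]
    out = g.agg(value="mean", n="size").reset_index()
    out.insert(len(keys), "statistic", "mean_hm")
    return out


def prevalence(history: pd.DataFrame, factor: str,
               stratifier: Sequence[str] = ("year",)) -> pd.DataFrame:
    """Share of alive individuals with the factor per stratum."""
    if factor not in RISK_FACTORS:
        raise ConfigurationError(f"unknown risk factor {factor!r}")
    df, keys = add_strata(history, stratifier)
    g = df.groupby(keys, observed=True)[factor]
    out = g.agg(value="mean", n="size").reset_index()
    out.insert(len(keys), "statistic", f"prevalence_{factor}")
    return out


def person_years(history: pd.DataFrame) -> np.ndarray:
    """Exposure per history record: 1 year, or 0.5 in the year of death."""
    return 1.0 - 0.5 * history["died"].to_numpy(dtype=float)


def nylp(
    history: pd.DataFrame,
    reference_year: int,
    end_year: int,
    hm_threshold: float | None = None,
    stratifier: Sequence[str] = (),
) -> pd.DataFrame:
    """Number of years lived per person over [reference_year, end_year].

    Denominator: individuals alive at the start of ``reference_year`` in
    the stratum.  With ``hm_threshold`` θ, only person-years whose
    start-of-year hm ≥ θ count (NYLP in good health).
    """
    if hm_threshold is not None and not 0.0 <= hm_threshold <= 100.0:
        raise ConfigurationError("hm_threshold must lie in [0, 100]")
    window = history[(history["year"] >= reference_year) & (history["year"] <= end_year)]
    base = history[history["year"] == reference_year]
    df, keys = add_strata(window, stratifier)
    base_df, _ = add_strata(base, stratifier)

    w = person_years(df)
    if hm_threshold is not None:
        w = w * (df["hm"].to_numpy(dtype=float) >= hm_threshold)

    name = "nylp" if hm_threshold is None else "nylp_good"
    if not keys:
        n0 = len(base_df)
        if n0 == 0:
            return pd.DataFrame(columns=["statistic", "value", "n"])
        return pd.DataFrame({"statistic": [name], "value": [w.sum() / n0], "n": [n0]})

    py = df.assign(_w=w).groupby(keys, observed=True)["_w"].sum()
    n0 = base_df.groupby(keys, observed=True).size()
    out = (py / n0).dropna().rename("value").reset_index()
    out["statistic"] = name
    out = out.merge(n0.rename("n").reset_index(), on=keys)
    return out


def deaths_and_exposure(history: pd.DataFrame,
                        stratifier: Sequence[str] = ("year",)) -> pd.DataFrame:
    """Additive deaths and person-years per stratum."""
    df, keys = add_strata(history, stratifier)
    df = df.assign(_py=person_years(df))
    g = df.groupby(keys, observed=True)
    out = g.agg(deaths=("died", "sum"), person_years=("_py", "sum"),
                n=("id", "size")).reset_index()
    return out


def build_outcome_table(
    history: pd.DataFrame,
    base_population: pd.DataFrame,
    scenario: str,
    reference_year: int,
    end_year: int,
    good_health_threshold: float = 60.0,
) -> pd.DataFrame:
    """Long-format outcome table for one scenario run.

    Includes mean hm and all five factor prevalences by year and by
    (year, education), plus NYLP and NYLP in good health overall and by
    education.  Prevalence trajectories of every factor are always included
    so that indirect scenario effects stay visible.
    """
    hist = attach_demographics(history, base_population)
    pieces: list[pd.DataFrame] = []
    for strat in (("year",), ("year", "education")):
        pieces.append(average_hm(hist, strat))
        for factor in RISK_FACTORS:
            pieces.append(prevalence(hist, factor, strat))
    for strat in ((), ("education",)):
        for theta in (None, good_health_threshold):
            pieces.append(nylp(hist, reference_year, end_year,
                               hm_threshold=theta, stratifier=list(strat)))
    table = pd.concat(pieces, ignore_index=True)
    table.insert(0, "scenario", scenario)
    return table
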
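"""Counterfactual scenario engine.

A scenario is a declarative transformation of the base population and/or
the parameter bundle.  "Removing" a risk factor means setting it to 0 in
the base population *and* pinning its transition to 0 thereafter (zero
prevalence and zero incidence) — otherwise transitions would quietly
re-introduce it.  The other factors keep their transition coefficients, so
indirect pathways operate automatically: e.g. removing depression raises
physical activity, which in turn slows health decline.

The built-in registry ships nine scenarios:

========== ==================================================================
Baseline   all estimated parameters as-is
NoAH       removes arterial hypertension
NoObe      removes obesity
NoSmoke    removes smoking
NoDep      removes depression
NoInactive everyone does vigorous physical activity
EqEdu      zeroes the low/medium-education coefficients in the
           health-change model only (education keeps its effects on the
           risk-factor transitions and on baseline mortality)
NoRisk     all of the above combined
BadHMAlive the good-health mortality parameter is applied to every hm
           category, eliminating mortality differences by health
========== ==================================================================

With common random numbers (the default) every scenario re-uses identical
random substreams per (individual, year, process), so contrasts between
scenarios are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .config import ParamsBundle, SimConfig
from .engine import SimResult, run_simulation
from .errors import ConfigurationError
from .outcomes import build_outcome_table

REMOVABLE_FACTORS = ("hypertension", "obese", "smoker", "depressed")


@dataclass
class ScenarioSpec:
    """Declarative description of one counterfactual."""

    name: str
    remove_factors: tuple[str, ...] = ()
    force_active: bool = False
    equalize_education_health_effect: bool = False
    equalize_mortality_by_health: bool = False

    def __post_init__(self) -> None:
        unknown = [f for f in self.remove_factors if f not in REMOVABLE_FACTORS]
        if unknown:
            raise ConfigurationError(
                f"scenario {self.name!r}: cannot remove {unknown}; "
                f"removable factors are {REMOVABLE_FACTORS}")


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "Baseline": ScenarioSpec("Baseline"),
    "NoAH": ScenarioSpec("NoAH", remove_factors=("hypertension",)),
    "NoObe": ScenarioSpec("NoObe", remove_factors=("obese",)),
    "NoSmoke": ScenarioSpec("NoSmoke", remove_factors=("smoker",)),
    "NoDep": ScenarioSpec("NoDep", remove_factors=("depressed",)),
    "NoInactive": ScenarioSpec("NoInactive", force_active=True),
    "EqEdu": ScenarioSpec("EqEdu", equalize_education_health_effect=True),
    "NoRisk": ScenarioSpec(
        "NoRisk",
        remove_factors=REMOVABLE_FACTORS,
        force_active=True,
        equalize_education_health_effect=True,
    ),
    "BadHMAlive": ScenarioSpec("BadHMAlive", equalize_mortality_by_health=True),
}


def apply_scenario(
    spec: ScenarioSpec, population: pd.DataFrame, bundle: ParamsBundle
) -> tuple[pd.DataFrame, ParamsBundle]:
    """Return the transformed (population, parameter bundle) pair.

    Inputs are not mutated; the Baseline spec returns equivalent copies.
    """
    population = population.copy()
    bundle = bundle.copy()

    for factor in spec.remove_factors:
        population[factor] = 0
        bundle.pinned[factor] = 0
    if spec.force_active:
        population["active"] = 1
        bundle.pinned["active"] = 1
    if spec.equalize_education_health_effect:
        for name in ("education_low", "education_medium"):
            bundle.health.covariate_betas.pop(name, None)
    if spec.equalize_mortality_by_health:
        bundle.equalize_mortality_by_health = True
    return population, bundle


@dataclass
class ScenarioSuiteResult:
    """Per-scenario outcome tables and yearly summaries.

    Full :class:`SimResult` objects (with per-individual histories) are kept
    only on request — a large suite would otherwise hold every history in
    memory at once.
    """

    outcome_tables: dict[str, pd.DataFrame]
    yearly_summaries: dict[str, pd.DataFrame]
    results: dict[str, SimResult] | None = None

    def combined_table(self) -> pd.DataFrame:
        return pd.concat(self.outcome_tables.values(), ignore_index=True)


def run_scenario_suite(
    specs: list[ScenarioSpec],
    population: pd.DataFrame,
    bundle: ParamsBundle,
    config: SimConfig,
    keep_results: bool = False,
) -> ScenarioSuiteResult:
    """Simulate each scenario on an identical copy of the base population.

    With ``config.crn_mode`` (default) all scenarios share the master seed,
    so every (individual, year, process) substream is identical across
    scenarios and contrasts are paired; otherwise each scenario gets its
    own derived seed.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate scenario names in suite: {names}")
    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, pd.DataFrame] = {}
    results: dict[str, SimResult] = {}
    for k, spec in enumerate(specs):
        pop_k, bundle_k = apply_scenario(spec, population, bundle)
        cfg_k = config
        if not config.crn_mode:
            cfg_k = replace(config, master_seed=(config.master_seed * 1000003 + k) % (2**31))
        result = run_simulation(pop_k, bundle_k, cfg_k)
        tables[spec.name] = build_outcome_table(
            result.history, result.initial_population, spec.name,
            config.nylp_reference_year, config.outcome_window[1],
            config.good_health_threshold)
        summaries[spec.name] = result.yearly_summary
        if keep_results:
            results[spec.name] = result
        else:
            result.history = None  # free the largest block eagerly
    return ScenarioSuiteResult(outcome_tables=tables, yearly_summaries=summaries,
                               results=results or None)
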
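"""Configuration: YAML loading, defaults, and the parameter bundle.

A single structured-text (YAML) file configures a run, with top-level keys
``population``, ``transitions``, ``health_change``, ``mortality``,
``scenarios`` and ``engine``.  User files are deep-merged over the packaged
defaults (``data/default_params.yaml``), so a file only needs the keys it
changes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .covariates import RISK_FACTORS, AgeSpline
from .errors import ConfigurationError
from .health import HealthChangeParams
from .mortality import (DEFAULT_CUTPOINTS, GompertzSchedule, MortalityBaseline)
from .population import ImputationModel, PopulationSpec
from .transitions import TransitionParams


def default_config_dict() -> dict:
    """The packaged default parameter set, as a plain dict."""
    text = resources.files("microhealth").joinpath("data/default_params.yaml").read_text()
    return yaml.safe_load(text)


def deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config_dict(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path}: top level must be a mapping")
        cfg = deep_merge(cfg, user)
    if overrides:
        cfg = deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# builders from config dicts to typed parameter objects

def _age_spline(block: dict | None) -> AgeSpline | None:
    if not block:
        return None
    return AgeSpline(knots=list(block["knots"]), values=list(block["values"]))


def build_population_spec(cfg: dict, seed: int | None = None) -> PopulationSpec:
    block = cfg.get("population", {})
    models = {
        factor: ImputationModel(
            intercept=m.get("intercept", 0.0),
            covariate_betas=dict(m.get("covariate_betas", {})),
            age_spline=_age_spline(m.get("age_spline")),
        )
        for factor, m in block.get("imputation_models", {}).items()
    }
    hm_block = block.get("hm_imputation", {})
    spec = PopulationSpec(
        n_individuals=int(block.get("n_individuals", 10_000)),
        start_year=int(block.get("start_year", 2011)),
        seed=int(block.get("seed", 0) if seed is None else seed),
        cohort_weights={int(k): float(v) for k, v in block.get("cohort_weights", {}).items()},
        country_weights=dict(block.get("country_weights", {})),
        education_low_intercept=float(block.get("education_low_intercept", -0.269)),
        education_low_slope=float(block.get("education_low_slope", -0.0558)),
        education_ref_year=int(block.get("education_ref_year", 1945)),
        education_medium_share=float(block.get("education_medium_share", 0.55)),
        imputation_models=models,
        hm_imputation=ImputationModel(
            intercept=hm_block.get("intercept", 0.0),
            covariate_betas=dict(hm_block.get("covariate_betas", {})),
            age_spline=_age_spline(hm_block.get("age_spline")),
        ),
        hm_sigma=float(block.get("hm_sigma", 0.5)),
    )
    spec.validate()
    return spec


def build_transition_params(cfg: dict) -> dict[str, TransitionParams]:
    out = {}
    for factor, block in cfg.get("transitions", {}).items():
        out[factor] = TransitionParams(
            factor=factor,
            beta0=float(block.get("beta0", 0.0)),
            beta1_duration=float(block.get("beta1_duration", 0.0)),
            beta2_lag=float(block.get("beta2_lag", 0.0)),
            covariate_betas=dict(block.get("covariate_betas", {})),
            age_spline=_age_spline(block.get("age_spline")),
        )
    missing = [f for f in RISK_FACTORS if f not in out]
    if missing:
        raise ConfigurationError(f"transitions: missing parameter blocks for {missing}")
    return out


def build_health_params(cfg: dict) -> HealthChangeParams:
    block = cfg.get("health_change", {})
    return HealthChangeParams(
        beta0=float(block.get("beta0", 0.0)),
        beta1=float(block.get("beta1", 0.0)),
        beta2=float(block.get("beta2", 0.0)),
        beta3=float(block.get("beta3", 0.0)),
        covariate_betas=dict(block.get("covariate_betas", {})),
        age_spline=_age_spline(block.get("age_spline")),
    )


def build_mortality(cfg: dict) -> tuple[MortalityBaseline, tuple[float, ...], dict[str, float]]:
    block = cfg.get("mortality", {})
    if "table_path" in block and block["table_path"]:
        baseline = MortalityBaseline(table=pd.read_csv(block["table_path"]))
    else:
        sched = block.get("schedule", {})
        baseline = MortalityBaseline(schedule=GompertzSchedule(
            intercept=float(sched.get("intercept", -6.2)),
            slope_age=float(sched.get("slope_age", 0.105)),
            sex_shifts=dict(sched.get("sex_shifts", {"male": 0.0, "female": -0.4})),
            education_shifts=dict(sched.get("education_shifts",
                                            {"low": 0.25, "medium": 0.10, "high": 0.0})),
            country_shifts=dict(sched.get("country_shifts", {})),
            year_trend=float(sched.get("year_trend", -0.01)),
            ref_year=int(sched.get("ref_year", 2011)),
            max_age=float(sched.get("max_age", 110)),
        ))
    contrast = block.get("contrast", {})
    cutpoints = tuple(float(c) for c in contrast.get("cutpoints", DEFAULT_CUTPOINTS))
    raw_betas = {str(k): float(v) for k, v in contrast.get("raw_betas", {}).items()}
    return baseline, cutpoints, raw_betas


@dataclass
class ParamsBundle:
    """Everything the yearly step needs, before scenario transformation."""

    transitions: dict[str, TransitionParams]
    health: HealthChangeParams
    baseline: MortalityBaseline
    contrast_cutpoints: tuple[float, ...]
    contrast_raw_betas: dict[str, float]
    pinned: dict[str, int] = field(default_factory=dict)
    equalize_mortality_by_health: bool = False

    def copy(self) -> "ParamsBundle":
        return ParamsBundle(
            transitions={f: replace(p, covariate_betas=dict(p.covariate_betas))
                         for f, p in self.transitions.items()},
            health=replace(self.health, covariate_betas=dict(self.health.covariate_betas)),
            baseline=self.baseline,  # read-only, safe to share
            contrast_cutpoints=tuple(self.contrast_cutpoints),
            contrast_raw_betas=dict(self.contrast_raw_betas),
            pinned=dict(self.pinned),
            equalize_mortality_by_health=self.equalize_mortality_by_health,
        )


def build_params_bundle(cfg: dict) -> ParamsBundle:
    baseline, cutpoints, raw_betas = build_mortality(cfg)
    return ParamsBundle(
        transitions=build_transition_params(cfg),
        health=build_health_params(cfg),
        baseline=baseline,
        contrast_cutpoints=cutpoints,
        contrast_raw_betas=raw_betas,
    )


@dataclass
class SimConfig:
    """Engine-level run settings."""

    start_year: int = 2011
    horizon_year: int = 2060
    outcome_window: tuple[int, int] = (2015, 2060)
    nylp_reference_year: int = 2015
    good_health_threshold: float = 60.0
    master_seed: int = 0
    crn_mode: bool = True
    record_history: bool = True

    def validate(self) -> None:
        lo, hi = self.outcome_window
        if not (self.start_year <= lo <= self.horizon_year):
            raise ConfigurationError("engine: need start_year <= outcome window start <= horizon_year")
        if hi < lo:
            raise ConfigurationError("engine: outcome window end before its start")
        if not (lo <= self.nylp_reference_year <= hi):
            raise ConfigurationError("engine: nylp_reference_year must lie in the outcome window")
        if not 0.0 <= self.good_health_threshold <= 100.0:
            raise ConfigurationError("engine: good_health_threshold must lie in [0, 100]")


def build_sim_config(cfg: dict, seed: int | None = None) -> SimConfig:
    block = cfg.get("engine", {})
    window = block.get("outcome_window", [2015, 2060])
    sim = SimConfig(
        start_year=int(block.get("start_year", 2011)),
        horizon_year=int(block.get("horizon_year", 2060)),
        outcome_window=(int(window[0]), int(window[1])),
        nylp_reference_year=int(block.get("nylp_reference_year", 2015)),
        good_health_threshold=float(block.get("good_health_threshold", 60.0)),
        master_seed=int(block.get("master_seed", 0) if seed is None else seed),
        crn_mode=bool(block.get("crn_mode", True)),
        record_history=bool(block.get("record_history", True)),
    )
    sim.validate()
    return sim
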
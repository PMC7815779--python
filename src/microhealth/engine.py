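"""Yearly simulation loop, history logging, and run orchestration.

One simulated year executes, for every alive individual, on the
start-of-year snapshot:

1. survival draw (mortality module) — death probabilities use start-of-year
   hm and covariates;
2. risk-factor redraw for survivors (transitions module) — probabilities
   conditioned on the start-of-year snapshot;
3. deterministic hm update for survivors (health module) — covariates are
   the *pre-step* risk-factor values, so within-year ordering is
   irrelevant;
4. age increases by one year.

The population is closed: no new entrants, and a dead individual is never
updated again.  Mortality contrasts are centred once at baseline using the
death-calibrated offset (see :func:`microhealth.mortality.center_contrasts`).
A full run is reproducible given (config, master seed): every draw comes
from an (id, year, process)-keyed substream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ParamsBundle, SimConfig, config_hash
from .covariates import RISK_FACTORS
from .health import update_hm
from .mortality import MortalityContrast, center_contrasts, draw_survival
from .transitions import update_risk_factors

logger = logging.getLogger("microhealth")

HISTORY_COLUMNS = ["id", "year", "age", "hm",
                   *RISK_FACTORS, "died"]


@dataclass
class SimResult:
    """Outputs of one scenario run."""

    history: pd.DataFrame | None
    yearly_summary: pd.DataFrame
    population: pd.DataFrame          # final state at horizon
    initial_population: pd.DataFrame  # state at start year (pre-simulation)
    contrast: MortalityContrast
    config: SimConfig


def prepare_contrast(population: pd.DataFrame, bundle: ParamsBundle,
                     config: SimConfig) -> MortalityContrast:
    """Centre the mortality contrasts once at baseline.

    Uses the death-calibrated offset so the first projected year's expected
    death count equals the unadjusted expectation.  Under mortality-by-health
    equalisation (the keep-bad-health-alive counterfactual) every category
    then receives the good-health (top) category's centred effect, making
    the adjustment independent of hm.
    """
    alive = population[population["alive"]]
    q = bundle.baseline.q(alive, config.start_year)
    contrast = center_contrasts(bundle.contrast_raw_betas, population,
                                cutpoints=bundle.contrast_cutpoints, baseline_q=q)
    if bundle.equalize_mortality_by_health:
        top = max(contrast.contrast_betas, key=lambda c: _category_low(contrast, c))
        value = contrast.contrast_betas[top]
        contrast.contrast_betas = {c: value for c in contrast.contrast_betas}
    return contrast


def _category_low(contrast: MortalityContrast, label: str) -> float:
    """Lower hm bound of a category (orders labels by health level)."""
    from .mortality import category_labels
    labels = category_labels(contrast.cutpoints)
    bounds = [0.0, *contrast.cutpoints]
    return bounds[labels.index(label)]


def simulate_year(
    population: pd.DataFrame,
    bundle: ParamsBundle,
    contrast: MortalityContrast,
    year: int,
    master_seed: int,
) -> pd.DataFrame:
    """Advance the population by one year (in place); returns this year's
    history increment (one record per individual alive at the start of the
    year, with its start-of-year state and a death flag)."""
    alive = population["alive"].to_numpy().copy()  # survival draw mutates the column
    snap = population.loc[alive, ["id", "age", "hm", *RISK_FACTORS]].copy()

    death_mask = draw_survival(population, bundle.baseline, contrast, master_seed, year)
    snap_records = pd.DataFrame({
        "id": snap["id"].to_numpy(),
        "year": np.full(len(snap), year, dtype=np.int16),
        "age": snap["age"].to_numpy(dtype=np.float32),
        "hm": snap["hm"].to_numpy(dtype=np.float32),
        **{f: snap[f].to_numpy(dtype=np.int8) for f in RISK_FACTORS},
        "died": death_mask[alive].astype(np.int8),
    })

    survivors = population["alive"].to_numpy()
    if survivors.any():
        # hm computed from the pre-step snapshot, assigned after the factor
        # redraw (snapshot semantics: order inside the year is irrelevant)
        surv_view = population.loc[survivors]
        new_hm = update_hm(bundle.health, surv_view)
        update_risk_factors(population, bundle.transitions, master_seed, year,
                            pinned=bundle.pinned)
        population.loc[survivors, "hm"] = new_hm
        population.loc[survivors, "age"] = surv_view["age"].to_numpy() + 1.0

    return snap_records


def run_simulation(
    population: pd.DataFrame,
    bundle: ParamsBundle,
    config: SimConfig,
) -> SimResult:
    """Run the yearly loop from start_year through horizon_year inclusive."""
    config.validate()
    population = population.copy()
    initial = population.copy()
    contrast = prepare_contrast(population, bundle, config)

    increments: list[pd.DataFrame] = []
    summaries: list[dict] = []
    for year in range(config.start_year, config.horizon_year + 1):
        inc = simulate_year(population, bundle, contrast, year, config.master_seed)
        summary = {
            "year": year,
            "alive_start": len(inc),
            "deaths": int(inc["died"].sum()),
            "mean_hm": float(inc["hm"].mean()) if len(inc) else np.nan,
            **{f"prevalence_{f}": float(inc[f].mean()) if len(inc) else np.nan
               for f in RISK_FACTORS},
        }
        summaries.append(summary)
        logger.info(
            "year %d: alive %d, deaths %d, mean hm %.1f", year,
            summary["alive_start"], summary["deaths"], summary["mean_hm"])
        if config.record_history:
            increments.append(inc)

    history = pd.concat(increments, ignore_index=True) if config.record_history else None
    return SimResult(
        history=history,
        yearly_summary=pd.DataFrame(summaries),
        population=population,
        initial_population=initial,
        contrast=contrast,
        config=config,
    )


def write_manifest(out_dir: str | Path, cfg: dict, seed: int) -> Path:
    """Machine-readable run manifest (config hash, seed, versions)."""
    import microhealth
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "master_seed": seed,
        "microhealth_version": microhealth.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
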
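# microhealth

Dynamic microsimulation of health-ageing trajectories for closed cohorts
of Europeans aged 50+. The package is for population and health
researchers who want to project how a continuous functional-health metric,
five behavioural and bio-medical risk factors, and health-modulated
survival jointly evolve over decades — and to ask counterfactual "what
if" questions (what if nobody smoked? what if education no longer
affected health decline?) with paired, low-variance comparisons.

## The model

Each individual carries demographics (birth year, sex, education,
country), five binary risk factors F ∈ {smoking, physical activity,
obesity, hypertension, depression}, and a health metric HM ∈ [0, 100]
(higher = healthier; HM ≥ 60 counts as good health). Years are simulated
one at a time, every process conditioning on the start-of-year state:

* **Risk-factor transitions** (stochastic) — autoregressive
  distributed-lag logit models:
  `logit P(F_t = 1) = β₀ + β₁(a−1) + β₂ F_{t−a} + Σᵢ βᵢ X_{i,t−a}`,
  with a = 1 inside the simulator. Cross-effects make the factors
  interact (e.g. lagged depression lowers the odds of physical activity).
* **Health dynamics** (deterministic given covariates) — with h = HM/100:
  `logit(h_{t+1}) = logit(h_t) + β₀ + β₁h + β₂h² + β₃h³ + Σᵢ βᵢ X_{i,t}`,
  so HM can never leave its bounds and the decline rate depends on the
  current level.
* **Mortality** (stochastic) — baseline death probabilities q by age,
  sex, education, country and year, shifted on the logit scale by a
  contrast-centred effect of the HM category:
  `q' = expit(logit(q) + β_c)`, centred at baseline so the first-year
  expected death count matches the unadjusted schedule.

Outcomes: average HM, number of years lived per person (NYLP), and NYLP
in good health, by year, cohort, age group and education. A scenario
engine runs nine built-in counterfactuals (risk-factor removal, universal
activity, education-effect equalisation, mortality-by-health
equalisation, all combined) under common random numbers. An estimation
module fits all three model families from two-wave panel CSVs with
cluster-robust (GEE-style) inference, so the simulator can be calibrated
to user data. See `docs/methods.md` for the full specification.

## Worked example

```python
import microhealth as mh

cfg = mh.default_config_dict()                      # packaged defaults
spec = mh.build_population_spec(cfg, seed=1)
spec.n_individuals = 50_000
pop = mh.generate_base_population(spec)             # synthetic 2011 cohort
bundle = mh.build_params_bundle(cfg)
sim = mh.SimConfig(master_seed=1)                   # 2011 -> 2060

result = mh.run_simulation(pop, bundle, sim)
s = result.yearly_summary.set_index("year")
print(f"mean HM 2015: {s.loc[2015, 'mean_hm']:.1f}")
print(f"mean HM 2060: {s.loc[2060, 'mean_hm']:.1f}")
print(f"NYLP 2015-2060: "
      f"{mh.nylp(result.history, 2015, 2060)['value'].iloc[0]:.1f}")
print(f"NYLP in good health: "
      f"{mh.nylp(result.history, 2015, 2060, hm_threshold=60)['value'].iloc[0]:.1f}")
```

Output:

```
mean HM 2015: 55.3
mean HM 2060: 22.2
NYLP 2015-2060: 19.8
NYLP in good health: 4.2
```

Read: the simulated population averages HM ≈ 55 in 2015 and, as the
closed cohort ages and the frail die, the survivors' average falls to ≈ 22
by 2060. A person alive in 2015 lives on average ≈ 20 more years of the
45-year window, but only ≈ 4 of them in good health (HM ≥ 60). A
counterfactual comparison runs the same population through the scenario
suite:

```python
suite = mh.run_scenario_suite(list(mh.BUILTIN_SCENARIOS.values()),
                              pop, bundle, sim)
```

Because every scenario shares the same random substreams per individual,
year and process, contrasts such as "NYLP under NoSmoke minus NYLP under
Baseline" are paired and need no replicate averaging.

The same machinery is scriptable from the shell:

```sh
microhealth simulate --seed 1 --out out/            # histories + outcomes
microhealth scenarios --seed 1 --out out/           # nine-scenario suite
microhealth generate-population -n 10000 --out pop.csv
microhealth fit panel.csv --model transition --factor obese \
    --covariates education_low,female,age_c50
```

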
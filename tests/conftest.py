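import pytest

import microhealth as mh


@pytest.fixture(scope="session")
def cfg():
    return mh.default_config_dict()


@pytest.fixture(scope="session")
def bundle(cfg):
    return mh.build_params_bundle(cfg)


@pytest.fixture(scope="session")
def default_spec(cfg):
    return mh.build_population_spec(cfg, seed=7)


@pytest.fixture(scope="session")
def small_pop(cfg):
    """2,000-person default base population, seed 7."""
    spec = mh.build_population_spec(cfg, seed=7)
    spec.n_individuals = 2_000
    return mh.generate_base_population(spec)


@pytest.fixture()
def sim_config():
    return mh.SimConfig(start_year=2011, horizon_year=2030,
                        outcome_window=(2015, 2030), nylp_reference_year=2015,
                        master_seed=7)
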
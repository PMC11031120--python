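import numpy as np
import pytest

from trialselect.synthgen import (SynthConfig, gen_trials, gen_ontology,
                                  gen_admet_tables, gen_disease_risk_table)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    config = SynthConfig(n_trials=120, seed=42)
    trials, truth = gen_trials(config)
    ontology = gen_ontology(config.ontology_depth, config.branching,
                            config.seed)
    return config, trials, truth, ontology


@pytest.fixture(scope="session")
def aux_tables(small_dataset):
    config, _, truth, _ = small_dataset
    return (gen_admet_tables(config, truth),
            gen_disease_risk_table(config, truth, rows_per_code=10))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
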
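import numpy as np
import pytest
from hypothesis import settings

from rnlseq import simulate as sim
from rnlseq.model import RunConfig

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale simulation parameters for fast unit tests."""
    return sim.SimParams(n_genes=400, seed=7)


@pytest.fixture(scope="session")
def small_design():
    # 2 experiments x 2 samples = 4 replicates per condition
    return sim.default_design(n_experiments=2, samples_per_experiment=2)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return sim.plant_truth(small_params)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_design, small_params):
    return sim.simulate_counts(small_truth, small_design, small_params)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=7)
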
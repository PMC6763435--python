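import numpy as np
import pytest
from hypothesis import settings

from hexadose.simulate import DepthModel, ScenarioConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

PARENTS = ("P1", "P2")


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study (n=102, ~2,000 loci), fixed seed."""
    counts, phen, scenario, f1 = simulate_dataset(seed=1)
    return counts, phen, scenario, f1


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free, complete-depth variant of the default study."""
    counts, phen, scenario, f1 = simulate_dataset(
        depth_model=DepthModel(error_rate=0.0, missing_rate=0.0), seed=2
    )
    return counts, phen, scenario, f1


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Small error-free dataset for fast I/O and pipeline tests."""
    cfg = ScenarioConfig(n_chromosomes=2, loci_per_chromosome=60, n_f1=40)
    counts, phen, scenario, f1 = simulate_dataset(
        cfg, DepthModel(error_rate=0.0, missing_rate=0.0), seed=3
    )
    return counts, phen, scenario, f1


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
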
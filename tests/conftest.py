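import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from hybridalleles import pipeline
from hybridalleles.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated hybrid scenario with duplications enabled."""
    config = SimConfig(
        n_genes=40,
        len_mean=600.0,
        len_sd=150.0,
        dup_rate_parent=0.1,
        dup_rate_hybrid=0.1,
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    """Full pipeline output on the small scenario (shared: it is not cheap)."""
    return pipeline.analyze(small_dataset.hybrid, small_dataset.parents)
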
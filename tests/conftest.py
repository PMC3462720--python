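import pytest

from estmzt.pipeline import run_pipeline
from estmzt.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def exact_dataset():
    """Small error-free dataset: every EST should round-trip exactly."""
    config = SimConfig(
        n_genes=40,
        n_mito_genes=4,
        library_sizes=(250, 250, 250, 250),
        error_rate=0.0,
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def exact_result(exact_dataset):
    return run_pipeline(exact_dataset)
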
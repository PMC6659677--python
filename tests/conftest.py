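import numpy as np
import pytest

from semnetrisk import synthetic_data as synth


@pytest.fixture(scope="session")
def small_scenario() -> synth.SyntheticScenario:
    """A reduced study used across tests: 200 genes, 40 risk, 16-gene module."""
    return synth.SyntheticScenario(
        seed=11,
        n_genes=200,
        n_risk_genes=40,
        module_size=16,
        pin_size=150,
        pathways=synth.PathwayParams(universe_size=2_000, n_pathways=50, size_range=(10, 60)),
        expression=synth.ExpressionParams(n_genes=200),
    )


@pytest.fixture(scope="session")
def default_scenario() -> synth.SyntheticScenario:
    """The packaged study conditions (600 genes, 64 risk, 24-gene module)."""
    return synth.SyntheticScenario(seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
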
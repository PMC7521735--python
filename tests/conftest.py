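import numpy as np
import pytest

from sigscreen import (
    Bioset,
    GeneRecord,
    GeneUniverse,
    SimulationConfig,
    build_biomarker,
    simulate_bioset_panel,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def panel(sim_config):
    """Activation panel + knockdown bioset + ground truth at default settings."""
    return simulate_bioset_panel(sim_config)


@pytest.fixture(scope="session")
def biomarker(panel):
    activation, knockdown, _ = panel
    return build_biomarker(activation, knockdown)


@pytest.fixture(scope="session")
def universe(panel) -> GeneUniverse:
    return panel[0][0].platform


def make_bioset(genes_fc: dict[str, float], universe: GeneUniverse, bioset_id="bs") -> Bioset:
    return Bioset(
        bioset_id, [GeneRecord(g, fc) for g, fc in genes_fc.items()], universe
    )


@pytest.fixture()
def small_universe() -> GeneUniverse:
    return GeneUniverse([f"g{i}" for i in range(10)])
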
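import pytest

from codonsel.pipeline import run_on_dataset
from codonsel.synthetic_data import SimulationConfig, simulate_dataset
from codonsel.trna_tai import TRNAPool


@pytest.fixture(scope="session")
def toy_pool():
    """Two Ala anticodons: AGC (Watson-Crick for GCT) and GGC (for GCC)."""
    return TRNAPool({"AGC": 2, "GGC": 3})


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 1), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic study."""
    workdir = tmp_path_factory.mktemp("sim_default")
    return run_on_dataset(default_dataset, workdir)
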
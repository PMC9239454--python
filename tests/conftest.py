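import numpy as np
import pytest

from linkdfe.cli_io import load_dataset
from linkdfe.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Two-cross, 20-mutation design: fast enough for chain tests."""
    return SimulationConfig(
        n_crosses=2, mutations_per_cross=(10, 10), seed=3, t_pre=0,
        depth_mean_tt=200.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_loaded(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ds")
    small_dataset.write(outdir)
    return load_dataset(outdir / "reads.tsv", outdir / "chromosomes.tsv")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
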
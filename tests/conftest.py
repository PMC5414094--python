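import numpy as np
import pytest

from chipwin.genome import GenomeBuild
from chipwin.simulate import SimulationConfig, simulate, write_fixture


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeBuild((("chrT", 10000), ("chrU", 5000)))


# Scaled-down simulation for unit tests: same structure as the default
# study conditions, smaller genome/depth so the suite stays fast.
SMALL_CONFIG = dict(
    chrom_lengths=(200_000, 100_000),
    n_genes=40,
    n_target_genes=6,
    chip_depth=30_000,
    input_depth=30_000,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimulationConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_sim):
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(small_sim, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
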
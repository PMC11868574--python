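import numpy as np
import pytest

import confactory as cf
from confactory.benchmark import Benchmark, build_benchmark


@pytest.fixture(scope="session")
def small_library():
    return cf.synthetic_library(40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_library):
    """200 labeled conformations of 40 toy molecules."""
    confs = []
    for m in small_library:
        confs.extend(cf.generate_conformations(m, 5, seed=5))
    return cf.label_conformations(confs, noise_std=0.1, seed=2)


@pytest.fixture(scope="session")
def trained_ensemble(small_dataset):
    return cf.train_ensemble(cf.DEFAULT_HETEROGENEOUS_CONFIGS, small_dataset,
                             seed=3)


@pytest.fixture(scope="session")
def benchmark() -> Benchmark:
    """The full study setup (library, strict split, labeled strata).

    Session-scoped: building it embeds ~4800 conformers and runs the
    oracle-MD stratum, which takes about a minute.
    """
    return build_benchmark(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
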
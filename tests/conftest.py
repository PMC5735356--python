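import numpy as np
import pytest

from smrnade.synthetic_data import SimConfig, generate_references


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_libraries=2,
        library_ids=("TW", "12h"),
        reads_per_library=4000,
        n_mirnas=12,
        n_refs_per_class=2,
        planted_effects=[("syn-mir-1", "12h", -2.0), ("syn-mir-2", "12h", 3.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_refs(small_config):
    return generate_references(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
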
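import numpy as np
import pytest

from virocycle import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community():
    """Two hosts, ten viruses, strong host signal — reused across tests."""
    viruses, hosts, truth = synthetic.gen_genomes(
        n_viral=10,
        n_host=2,
        gc_by_class={"marine": 0.40},
        k_signal=1.0,
        seed=7,
        viral_length_range=(10_000, 15_000),
        host_length=20_000,
    )
    return viruses, hosts, truth


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
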
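import numpy as np
import pytest

from randalign import build_index, choose_profile, simulate_genome
from randalign.seeding import SeedProfile


@pytest.fixture(scope="session")
def profile150() -> SeedProfile:
    return choose_profile(150)


@pytest.fixture(scope="session")
def genome100k() -> str:
    return simulate_genome(100_000, seed=7)


@pytest.fixture(scope="session")
def index100k(genome100k, profile150):
    return build_index([("chr1", genome100k)], profile150)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
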
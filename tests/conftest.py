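import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "talerep",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("talerep")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.choice(4, size=length)].tobytes().decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome():
    from talerep import Genome

    return Genome({"chr1": "TTAGGGTTAGGGTTAGGG", "chr2": "ACGTACGTACGT"})
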
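import numpy as np
import pytest

from bacrnaseq.formats_io import GenomeRecord, ReadRecord, RunConfig
from bacrnaseq.simdata import simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome(rng):
    return simulate_genome(2000, seed=rng)


@pytest.fixture
def config():
    return RunConfig()


def make_read(seq: str, qual: int = 30, rid: str = "r1") -> ReadRecord:
    return ReadRecord(rid, seq, np.full(len(seq), qual, dtype=np.int16))
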
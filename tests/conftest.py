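import numpy as np
import pytest

from svdense._seq import random_seq
from svdense.alignment_io import ReferenceGenome
from svdense.simulator import SimConfig, error_rng, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome(rng):
    return ReferenceGenome({"chrT": random_seq(rng, 50000)})


@pytest.fixture(scope="session")
def small_errorfree_sim():
    """Small diploid simulation with error-free reads + oracle records."""
    cfg = SimConfig(
        chrom_lengths={"c1": 300000, "c2": 200000},
        counts={"DEL": 8, "INS": 8, "DUP": 3, "INV": 3, "TRA": 1},
        depth=12,
        mean_read_length=12000,
        preset="perfect",
        seed=5,
    )
    res = simulate(cfg)
    records = list(res.records(cfg, error_rng(cfg)))
    return cfg, res, records
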
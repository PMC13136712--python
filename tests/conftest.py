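import numpy as np
import pytest

from featkit.core_io import BEScreenRecord, DatasetTable, PairedSiteRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int = 23) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_pair(rng: np.random.Generator, length: int = 23, max_mm: int = 6):
    guide = random_seq(rng, length)
    m = int(rng.integers(0, min(max_mm, length) + 1))
    positions = rng.choice(length, size=m, replace=False)
    target = list(guide)
    for p in positions:
        target[p] = rng.choice([b for b in BASES if b != guide[p]])
    return guide, "".join(target)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_ko_table():
    recs = [
        PairedSiteRecord("g1", "ACGTACGTACGTACGTACGTAGG", "ACGTACGTACGTACGTACGTAGG", 250.0),
        PairedSiteRecord("g1", "ACGTACGTACGTACGTACGTAGG", "ACGTACGAACGTACGTACGTAGG", 40.0),
        PairedSiteRecord("g2", "TTTTACGTACGTACGTACGTCGG", "TTTAACGTACGTACGAACGTCGG", 0.0),
    ]
    return DatasetTable("KO", recs)


@pytest.fixture
def toy_be_table():
    rng = np.random.default_rng(7)
    recs = [
        BEScreenRecord(f"g{i}", random_seq(rng), float(z))
        for i, z in enumerate([-3.1, -2.0, -0.5, 0.2, 1.7, -2.4])
    ]
    return DatasetTable("BE", recs)
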
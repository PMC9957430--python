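import numpy as np
import pytest

import ladscape as L
from ladscape.lads import LADTimecourse, derive_lad_partition


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic dataset, generated once per session."""
    return L.generate(seed=1)


@pytest.fixture(scope="session")
def partition(dataset):
    tc = LADTimecourse(list(dataset.lad_sets), list(dataset.lad_sets.values()))
    return derive_lad_partition(tc)


@pytest.fixture(scope="session")
def loaded_connections(dataset):
    return L.load_connections(dataset.connections)


@pytest.fixture
def toy_genome():
    return {"chrT": 10_000}


@pytest.fixture
def bool_oracle():
    """Per-base boolean-mask oracle for interval algebra on toy genomes."""

    def to_mask(iset):
        return {
            c: _mask(iset.arrays(c), n) for c, n in iset.genome.items()
        }

    def _mask(arr, n):
        m = np.zeros(n, dtype=bool)
        for s, e in arr:
            m[s:e] = True
        return m

    def from_mask(masks, genome):
        ivs = []
        for c, m in masks.items():
            padded = np.concatenate([[False], m, [False]])
            d = np.diff(padded.astype(int))
            starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
            ivs.extend(L.GenomicInterval(c, int(s), int(e)) for s, e in zip(starts, ends))
        return L.IntervalSet(ivs, genome)

    class Oracle:
        pass

    o = Oracle()
    o.to_mask = to_mask
    o.from_mask = from_mask
    return o


def random_interval_set(rng, genome, max_intervals=12, max_len=2_000):
    ivs = []
    for chrom, length in genome.items():
        for _ in range(rng.integers(0, max_intervals + 1)):
            s = int(rng.integers(0, length - 1))
            e = int(min(length, s + 1 + rng.integers(0, max_len)))
            ivs.append(L.GenomicInterval(chrom, s, e))
    return L.IntervalSet(ivs, genome)


@pytest.fixture
def make_random_set():
    return random_interval_set
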
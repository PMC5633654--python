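import numpy as np
import pandas as pd
import pytest

from methmap.intervals import IntervalSet
from methmap.io import MethylomeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_methylome(pos, levels, coverage, rng, chrom="chr1", **kw):
    """Binomial read sampling of a known level vector at Poisson coverage."""
    pos = np.asarray(pos)
    depth = np.maximum(rng.poisson(coverage, len(pos)), 1)
    meth = rng.binomial(depth, np.asarray(levels))
    return MethylomeTable(pd.DataFrame(
        {"chrom": chrom, "pos": pos, "meth": meth, "total": depth}), **kw)


def random_intervals(rng, n, chrom_len=100_000, chroms=("chr1",), max_len=2000):
    rows = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - max_len))
        rows.append((chrom, start, start + int(rng.integers(1, max_len))))
    return IntervalSet.from_tuples(rows)


def per_base(ivs, chrom, length):
    """Brute-force boolean coverage array for one chromosome."""
    arr = np.zeros(length, dtype=bool)
    for c, s, e in ivs.to_tuples():
        if c == chrom:
            arr[s:e] = True
    return arr


def bool_to_intervals(arr, chrom):
    out = []
    padded = np.concatenate([[False], arr, [False]])
    d = np.diff(padded.astype(np.int8))
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        out.append((chrom, int(s), int(e)))
    return out
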
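"""DMR predicate, antisymmetry, global statistics, t-test comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmap.dmr import (call_dmrs, global_stats, interval_methylation_compare,
                         neighbor_correlation)
from methmap.intervals import IntervalSet
from methmap.io import MethylomeTable
from methmap.smoothing import SmoothedProfile, smooth_profile

from conftest import make_methylome


def profile_from_bands(pos, level, half_width, chrom="chr1"):
    level = np.asarray(level, dtype=float)
    return SmoothedProfile(np.full(len(pos), chrom, dtype=object),
                           np.asarray(pos), level,
                           np.clip(level - half_width, 0, 1),
                           np.clip(level + half_width, 0, 1),
                           np.full(len(pos), 1000))


def test_identical_profiles_no_dmrs():
    pos = np.arange(50) * 100
    p = profile_from_bands(pos, np.full(50, 0.5), 0.05)
    assert call_dmrs(p, p) == []


def test_run_of_exactly_five_not_reported():
    """The threshold is *more than five* consecutive separated CpGs."""
    pos = np.arange(30) * 100
    base = np.full(30, 0.8)
    shifted5, shifted6 = base.copy(), base.copy()
    shifted5[10:15] = 0.2
    shifted6[10:16] = 0.2
    b = profile_from_bands(pos, base, 0.05)
    assert call_dmrs(profile_from_bands(pos, shifted5, 0.05), b) == []
    dmrs = call_dmrs(profile_from_bands(pos, shifted6, 0.05), b)
    assert len(dmrs) == 1
    d = dmrs[0]
    assert (d.direction, d.n_cpg) == ("hypo", 6)
    assert (d.interval.start, d.interval.end) == (1000, 1502)


def test_touching_bands_are_not_separated():
    pos = np.arange(20) * 100
    a = profile_from_bands(pos, np.full(20, 0.6), 0.1)   # band [0.5, 0.7]
    b = profile_from_bands(pos, np.full(20, 0.4), 0.1)   # band [0.3, 0.5]
    assert call_dmrs(a, b) == []  # shared endpoint, not disjoint


def test_antisymmetry(rng):
    pos = np.arange(200) * 100
    la = np.clip(0.5 + 0.4 * np.sin(pos / 2000), 0, 1)
    lb = np.clip(0.5 + 0.4 * np.cos(pos / 3000), 0, 1)
    a = profile_from_bands(pos, la, 0.04)
    b = profile_from_bands(pos, lb, 0.04)
    fwd = call_dmrs(a, b)
    rev = call_dmrs(b, a)
    assert len(fwd) > 0
    assert [(d.interval.start, d.interval.end, d.n_cpg) for d in fwd] == \
        [(d.interval.start, d.interval.end, d.n_cpg) for d in rev]
    flip = {"hyper": "hypo", "hypo": "hyper"}
    assert [flip[d.direction] for d in fwd] == [d.direction for d in rev]
    for f, r in zip(fwd, rev):
        assert f.mean_delta == pytest.approx(-r.mean_delta)


def test_planted_difference_detected(rng):
    """A 12-CpG planted hypomethylation at depth 20x is found reliably."""
    n = 600
    pos = np.arange(n) * 100
    mu = np.full(n, 0.75)
    mu_a = mu.copy()
    mu_a[300:312] = 0.15
    detected = 0
    for _ in range(20):
        a = smooth_profile(make_methylome(pos, mu_a, 20, rng))
        b = smooth_profile(make_methylome(pos, mu, 20, rng))
        hits = [d for d in call_dmrs(a, b)
                if d.direction == "hypo"
                and d.interval.start < pos[311] and d.interval.end > pos[300]]
        detected += bool(hits)
    assert detected >= 19


def test_global_stats_trivial_and_oracle(rng):
    pos = np.arange(100) * 50
    mk = lambda lev, sid: MethylomeTable(pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "meth": np.round(lev * 10).astype(int),
         "total": 10}), sample_id=sid)
    same = [mk(np.full(100, 0.4), "a"), mk(np.full(100, 0.4), "b")]
    gs = global_stats(same)
    assert np.allclose(gs.sd, 0) and gs.fraction_sd_gt == 0.0
    opp = [mk(np.zeros(100), "a"), mk(np.ones(100), "b")]
    gs2 = global_stats(opp)
    assert np.allclose(gs2.sd, np.sqrt(0.5))
    assert gs2.fraction_sd_gt == 1.0
    assert gs2.mean_levels == {"a": 0.0, "b": 1.0}
    # 10-sample random oracle
    samples = [make_methylome(pos, rng.uniform(0, 1, 100), 30, rng,
                              sample_id=f"s{i}") for i in range(10)]
    gs3 = global_stats(samples, min_coverage=5)
    # direct recomputation on the jointly covered set
    mats = []
    for s in samples:
        d = s.df[s.df["total"] >= 5].set_index("pos")
        mats.append(d)
    common = set(mats[0].index)
    for d in mats[1:]:
        common &= set(d.index)
    common = sorted(common)
    arr = np.column_stack([(d.loc[common, "meth"] / d.loc[common, "total"])
                           for d in mats])
    np.testing.assert_allclose(np.sort(gs3.sd), np.sort(arr.std(axis=1, ddof=1)),
                               atol=1e-12)


def test_global_stats_requires_two_samples(rng):
    with pytest.raises(ValueError):
        global_stats([make_methylome([0, 10], [0.5, 0.5], 10, rng)])


def test_neighbor_correlation_cases(rng):
    pos = np.arange(2000) * 50
    const = MethylomeTable(pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "meth": 5, "total": 10}))
    res = neighbor_correlation(const, max_distance_bp=100)
    assert not res.defined and np.isnan(res.r)
    # block-structured methylome: adjacent CpGs share their state
    state = np.repeat(rng.random(100) < 0.5, 20)
    lev = np.where(state, 0.05, 0.9)
    t = make_methylome(pos, lev, 30, rng)
    assert neighbor_correlation(t, 100).r > 0.7
    # shuffled positions destroy the autocorrelation
    shuffled = rng.permutation(lev)
    t2 = make_methylome(pos, shuffled, 30, rng)
    r2 = neighbor_correlation(t2, 100)
    assert abs(r2.r) < 3 / np.sqrt(r2.n_pairs)


def test_interval_compare_identical_groups(rng):
    pos = np.arange(500) * 100
    lev = rng.uniform(0.2, 0.8, 500)
    group = [make_methylome(pos, lev, 200, rng, sample_id=f"s{i}")
             for i in range(3)]
    regions = IntervalSet.from_tuples([("chr1", 0, 10_000),
                                       ("chr1", 20_000, 30_000)])
    df = interval_methylation_compare(group, group, regions)
    assert np.allclose(df["t"], 0.0)
    assert np.allclose(df["p"], 1.0)


def test_interval_compare_planted_difference_and_formula(rng):
    pos = np.arange(200) * 100
    regions = IntervalSet.from_tuples([("chr1", 0, 20_000)])
    ga = [make_methylome(pos, np.full(200, 0.7 + 0.01 * i), 400, rng,
                         sample_id=f"a{i}") for i in range(3)]
    gb = [make_methylome(pos, np.full(200, 0.4 + 0.01 * i), 400, rng,
                         sample_id=f"b{i}") for i in range(3)]
    df = interval_methylation_compare(ga, gb, regions)
    assert df["p"].iloc[0] < 0.01
    # textbook two-sample t on the per-sample means
    va = [s.mean_level() for s in ga]
    vb = [s.mean_level() for s in gb]
    t_ref, p_ref = stats.ttest_ind(va, vb)
    # region means equal sample means here (one region covers everything)
    assert df["t"].iloc[0] == pytest.approx(t_ref, rel=1e-9)
    assert df["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)
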
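"""Catalog partition algebra, co-activation, composite profiles, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmap.catalog import (build_catalog, co_activation, composite_profile,
                             interval_enrichment)
from methmap.intervals import GenomicInterval, IntervalSet, merge, overlap_any
from methmap.simulate import design_genome

from conftest import make_methylome, per_base, random_intervals


def test_identical_tissues_all_common():
    x = IntervalSet.from_tuples([("chr1", 100, 400), ("chr1", 900, 1300)])
    cat = build_catalog({"a": x, "b": x})
    assert cat.c_hmrs.coverage_bp() == x.coverage_bp()
    assert all(len(cat.t_hmrs[t]) == 0 for t in "ab")
    assert len(cat.frequent_hmrs) == 0


def test_disjoint_tissues_all_specific():
    a = IntervalSet.from_tuples([("chr1", 0, 100)])
    b = IntervalSet.from_tuples([("chr1", 500, 600)])
    cat = build_catalog({"a": a, "b": b})
    assert len(cat.c_hmrs) == 0
    assert cat.t_hmrs["a"] == a and cat.t_hmrs["b"] == b


def test_single_tissue_rejected():
    with pytest.raises(ValueError):
        build_catalog({"only": IntervalSet.from_tuples([("chr1", 0, 10)])})


def test_merge_gap_joins_close_common_regions():
    a = IntervalSet.from_tuples([("chr1", 0, 100), ("chr1", 150, 250)])
    b = IntervalSet.from_tuples([("chr1", 0, 250)])
    cat = build_catalog({"a": a, "b": b}, merge_gap_bp=100)
    assert cat.c_hmrs.to_tuples() == [("chr1", 0, 250)]


def test_planted_design_partition_recovered_exactly():
    d = design_genome(seed=11)
    cat = build_catalog({t: d.hmrs_by_tissue[t] for t in d.tissues})
    assert cat.c_hmrs == d.c_hmrs
    assert cat.frequent_hmrs == d.frequent_hmrs
    for t in d.tissues:
        assert cat.t_hmrs[t] == d.t_hmrs[t]


def test_frequent_against_per_base_count_oracle(rng):
    L = 50_000
    sets = {f"t{i}": random_intervals(rng, 12, chrom_len=L, max_len=800)
            for i in range(6)}
    cat = build_catalog(sets, merge_gap_bp=0)
    counts = np.zeros(L, dtype=int)
    for ivs in sets.values():
        counts += per_base(merge(ivs, 0), "chr1", L).astype(int)
    want = counts > 3  # strictly more than 50% of 6 tissues
    common = counts == 6
    got = per_base(cat.frequent_hmrs, "chr1", L)
    # frequent regions = >50% coverage minus anything touching a c-HMR region
    from conftest import bool_to_intervals
    want_iv = bool_to_intervals(want, "chr1")
    keep = ~overlap_any(IntervalSet.from_tuples(want_iv), cat.c_hmrs) \
        if want_iv else np.array([], dtype=bool)
    expected = np.zeros(L, dtype=bool)
    for (c, s, e), k in zip(want_iv, keep):
        if k:
            expected[s:e] = True
    assert np.array_equal(got, expected)


def test_adding_tissue_never_grows_common(rng):
    L = 50_000
    sets = {f"t{i}": random_intervals(rng, 15, chrom_len=L, max_len=1000)
            for i in range(3)}
    cov2 = build_catalog({k: sets[k] for k in ["t0", "t1"]}).c_hmrs.coverage_bp()
    cov3 = build_catalog(sets).c_hmrs.coverage_bp()
    assert cov3 <= cov2


def promoter_fixture():
    promoters = {"gA": GenomicInterval("chr1", 900, 1100),
                 "gB": GenomicInterval("chr1", 4900, 5100)}
    a = IntervalSet.from_tuples([("chr1", 1200, 1400)])   # near gA
    b = IntervalSet.from_tuples([("chr1", 5200, 5400)])   # near gB
    cat = build_catalog({"ta": a, "tb": b})
    return cat, promoters


def test_co_activation_all_hypo_gives_ones():
    cat, promoters = promoter_fixture()
    state = {t: {g: "hypomethylated" for g in promoters} for t in cat.tissues}
    m = co_activation(cat, promoters, state)
    assert np.allclose(m.to_numpy(), 1.0)


def test_co_activation_planted_identity():
    cat, promoters = promoter_fixture()
    state = {"ta": {"gA": "hypomethylated", "gB": "methylated"},
             "tb": {"gA": "methylated", "gB": "hypomethylated"}}
    m = co_activation(cat, promoters, state)
    assert np.allclose(np.diag(m.to_numpy()), 1.0)
    assert m.loc["ta", "tb"] == 0.0 and m.loc["tb", "ta"] == 0.0


def test_co_activation_skips_distant_hmrs():
    cat, promoters = promoter_fixture()
    far = IntervalSet.from_tuples([("chr2", 0, 200)])
    cat.t_hmrs["ta"] = far  # no gene within reach on chr2
    state = {t: {g: "hypomethylated" for g in promoters} for t in cat.tissues}
    m = co_activation(cat, promoters, state)
    assert np.isnan(m.loc["ta"].to_numpy()).all()
    assert m.attrs["n_skipped"] == 1


def test_composite_profile_flat_and_well(rng):
    hmrs = IntervalSet.from_tuples([("chr1", 10_000, 11_000)])
    pos = np.arange(7000, 15_000, 20)
    flat = make_methylome(pos, np.full(len(pos), 0.8), 300, rng,
                          sample_id="flat")
    well_levels = np.where((pos >= 10_000) & (pos < 11_000), 0.0, 1.0)
    well = make_methylome(pos, well_levels, 300, rng, sample_id="well")
    prof = composite_profile(hmrs, [flat, well], flank_bp=2000, bin_bp=4)
    f = prof["flat"].dropna()
    assert np.allclose(f, 0.8, atol=0.15)
    w = prof["well"].dropna()
    assert w[abs(w.index) < 400].max() < 0.2       # interior of the well
    assert w[abs(w.index) > 1600].min() > 0.8      # flanks stay methylated


def test_composite_profile_matches_direct_binning_oracle(rng):
    hmrs = random_intervals(rng, 10, chrom_len=80_000, max_len=1500)
    pos = np.sort(rng.choice(90_000, 3000, replace=False))
    t = make_methylome(pos, rng.uniform(0, 1, len(pos)), 30, rng,
                       sample_id="s")
    prof = composite_profile(hmrs, [t], flank_bp=1000, bin_bp=50)
    lev = t.levels
    n_bins = 2000 // 50
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for chrom, s, e in hmrs.to_tuples():
        c = (s + e) // 2
        for p, l in zip(t.df["pos"], lev):
            if c - 1000 <= p < c + 1000:
                b = min((p - (c - 1000)) // 50, n_bins - 1)
                sums[b] += l
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        want = sums / counts
    got = prof["s"].to_numpy()
    np.testing.assert_allclose(got, want, equal_nan=True, atol=1e-12)


def test_enrichment_background_rate_is_null(rng):
    universe = IntervalSet.from_tuples([("chr1", 0, 100_000)])
    # query = every other tile; annotation = random half, independent of query
    q = IntervalSet.from_tuples([("chr1", i, i + 100)
                                 for i in range(0, 100_000, 200)])
    ann_rows = [("chr1", i, i + 100) for i in range(0, 100_000, 100)
                if rng.random() < 0.5]
    res = interval_enrichment(q, IntervalSet.from_tuples(ann_rows), universe)
    assert res.p_value > 0.01
    assert 0.5 < res.odds_ratio < 2.0


def test_enrichment_degenerate_margin_flagged():
    universe = IntervalSet.from_tuples([("chr1", 0, 10_000)])
    res = interval_enrichment(
        IntervalSet.from_tuples([("chr1", 0, 500)]), universe, universe)
    assert res.degenerate and np.isnan(res.odds_ratio)


def test_enrichment_table_matches_per_tile_oracle(rng):
    universe = IntervalSet.from_tuples([("chr1", 0, 20_000)])
    q = random_intervals(rng, 8, chrom_len=20_000, max_len=900)
    a = random_intervals(rng, 8, chrom_len=20_000, max_len=900)
    res = interval_enrichment(q, a, universe, tile_bp=100)
    pq, pa = per_base(q, "chr1", 20_000), per_base(a, "chr1", 20_000)
    tab = np.zeros((2, 2), dtype=int)
    for s in range(0, 20_000, 100):
        iq, ia = pq[s:s + 100].any(), pa[s:s + 100].any()
        tab[0 if iq else 1, 0 if ia else 1] += 1
    assert np.array_equal(res.table, tab)
    _, p = stats.fisher_exact(tab)
    assert res.p_value == pytest.approx(p)
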
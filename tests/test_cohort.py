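"""Cohort stage: probe mapping, event rules, validation sweep, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from methmap.cohort import (BetaMatrix, call_hypermethylation_events,
                            cluster_samples, confirm_hypomethylated,
                            hmr_beta_summary, positive_selection_candidates,
                            validate_catalog)
from methmap.intervals import IntervalSet


def toy_matrix(beta_rows, n_probes_per_hmr, groups=None, labels=None):
    """Build a BetaMatrix with HMRs of given per-HMR probe counts; beta_rows
    is a list of per-probe sample vectors."""
    n_samples = len(beta_rows[0])
    samples = [f"s{i}" for i in range(n_samples)]
    probes, coords, rows = [], [], []
    hmr_tuples = []
    p = 0
    for h, k in enumerate(n_probes_per_hmr):
        start = 10_000 * (h + 1)
        hmr_tuples.append(("chr1", start, start + 1000))
        for j in range(k):
            probes.append(f"cg{p:04d}")
            coords.append(("chr1", start + 10 + j * 7))
            rows.append(beta_rows[p])
            p += 1
    meta = pd.DataFrame({
        "label": labels or ["x"] * n_samples,
        "group": groups or ["cancer"] * n_samples,
    }, index=pd.Index(samples, name="sample"))
    bm = BetaMatrix(
        pd.DataFrame(rows, index=pd.Index(probes, name="probe"), columns=samples),
        pd.DataFrame(coords, columns=["chrom", "pos"],
                     index=pd.Index(probes, name="probe")),
        meta)
    return IntervalSet.from_tuples(hmr_tuples), bm


def test_hmr_mean_and_representation():
    hmrs, bm = toy_matrix([[0.1, 0.5], [0.2, 0.5], [0.3, 0.5], [0.9, 0.1]],
                          n_probes_per_hmr=[3, 1])
    s = hmr_beta_summary(hmrs, bm, min_probes=2)
    assert s.means.iloc[0, 0] == pytest.approx(0.2)  # mean of .1/.2/.3
    assert s.n_probes.tolist() == [3, 1]
    assert s.represented.tolist() == [True, False]


def test_missing_betas_excluded_pairwise():
    hmrs, bm = toy_matrix([[0.1, np.nan], [np.nan, np.nan]], [2])
    s = hmr_beta_summary(hmrs, bm)
    assert s.means.iloc[0, 0] == pytest.approx(0.1)
    assert np.isnan(s.means.iloc[0, 1])


def test_confirmation_rules():
    # 8 probes at low beta -> confirmed; one tissue above 0.30 -> rejected
    rows_ok = [[0.05, 0.10]] * 8
    hmrs, bm = toy_matrix(rows_ok, [8], groups=["normal", "normal"])
    s = hmr_beta_summary(hmrs, bm)
    assert len(confirm_hypomethylated(s)) == 1
    rows_bad = [[0.05, 0.35]] * 8
    hmrs, bm = toy_matrix(rows_bad, [8], groups=["normal", "normal"])
    s = hmr_beta_summary(hmrs, bm)
    assert len(confirm_hypomethylated(s)) == 0
    # >5 probes means >= 6: a 5-probe HMR cannot confirm
    hmrs, bm = toy_matrix([[0.05, 0.05]] * 5, [5], groups=["normal", "normal"])
    assert len(confirm_hypomethylated(hmr_beta_summary(hmrs, bm))) == 0


def test_event_rule_strict_intensity_and_frequency():
    # mean beta 0.40 in 30% of cancers -> event; beta 0 everywhere -> none
    n = 10
    row_event = [0.40] * 3 + [0.05] * 7
    hmrs, bm = toy_matrix([row_event, [0.0] * n], [1, 1])
    s = hmr_beta_summary(hmrs, bm)
    ev = call_hypermethylation_events(s)
    assert ev["is_event"].tolist() == [True, False]
    assert ev["event_frequency"].iloc[0] == pytest.approx(0.3)
    # exactly at the intensity threshold is NOT above it
    hmrs, bm = toy_matrix([[0.33] * n], [1])
    ev = call_hypermethylation_events(hmr_beta_summary(hmrs, bm))
    assert not ev["is_event"].iloc[0]


def test_event_set_matches_brute_force(rng):
    n_h, n_s = 200, 50
    rows = rng.uniform(0, 1, size=(n_h, n_s))
    hmrs, bm = toy_matrix(rows.tolist(), [1] * n_h)
    s = hmr_beta_summary(hmrs, bm)
    ev = call_hypermethylation_events(s, intensity=0.33, frequency=0.25)
    for i in range(n_h):
        want = (rows[i] > 0.33).sum() / n_s >= 0.25
        assert ev["is_event"].iloc[i] == want


def test_threshold_monotonicity(rng):
    rows = rng.uniform(0, 1, size=(100, 40))
    hmrs, bm = toy_matrix(rows.tolist(), [1] * 100)
    s = hmr_beta_summary(hmrs, bm)
    prev = None
    for intensity in [0.1, 0.3, 0.5, 0.7]:
        cur = int(call_hypermethylation_events(s, intensity=intensity,
                                               frequency=0.25)["is_event"].sum())
        if prev is not None:
            assert cur <= prev
        prev = cur
    prev = None
    for freq in [0.05, 0.25, 0.5, 0.9]:
        cur = int(call_hypermethylation_events(s, intensity=0.33,
                                               frequency=freq)["is_event"].sum())
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_candidate_rules(rng):
    # promoter HMR with beta 0.6 in 2% of solid tumors, 3 probes -> candidate
    n = 100
    row = [0.6] * 2 + [0.05] * (n - 2)
    hmrs, bm = toy_matrix([row] * 3 + [row] * 2, [3, 2])
    bm.sample_meta["solid"] = True
    s = hmr_beta_summary(hmrs, bm)
    flags = pd.Series([True, False], index=s.means.index)
    cands = positive_selection_candidates(s, flags, solid_only=True)
    assert list(cands) == [s.means.index[0]]  # non-promoter never a candidate
    # random predicate oracle
    rows = rng.uniform(0, 1, size=(50, 40))
    hmrs, bm = toy_matrix(rows.tolist(), [1] * 50)
    s = hmr_beta_summary(hmrs, bm)
    flags = pd.Series(rng.random(50) < 0.5, index=s.means.index)
    cands = set(positive_selection_candidates(s, flags, min_probes=1))
    for i, hid in enumerate(s.means.index):
        want = flags.iloc[i] and ((rows[i] > 0.5).mean() > 0.01)
        assert (hid in cands) == want


def validation_fixture(perfect=True, rng=None):
    tissues = ["liver", "colon", "brain"]
    n_per = 4
    labels = sum(([t] * n_per for t in tissues), [])
    rows = []
    hmr_tissue = []
    for t in tissues:
        for _ in range(2):  # 2 t-HMRs per tissue, 2 probes each
            beta_own, beta_other = (0.0, 1.0)
            vec = [beta_own if lab == t else beta_other for lab in labels]
            rows.extend([vec, vec])
            hmr_tissue.append(t)
    hmrs, bm = toy_matrix(rows, [2] * 6, groups=["normal"] * len(labels),
                          labels=labels)
    s = hmr_beta_summary(hmrs, bm)
    t_series = pd.Series(hmr_tissue, index=s.means.index)
    return s, t_series


def test_validation_perfect_separation_gives_auc_one():
    s, t_series = validation_fixture()
    res = validate_catalog(s, t_series)
    assert res.auc == pytest.approx(1.0)
    mid = np.searchsorted(res.thresholds, 0.5)
    assert res.sensitivity[mid] == 1.0 and res.fpr[mid] == 0.0


def test_validation_counts_match_double_loop(rng):
    s, t_series = validation_fixture()
    noisy = s.means + rng.uniform(-0.3, 0.3, size=s.means.shape)
    s.means = noisy.clip(0, 1)
    res = validate_catalog(s, t_series, thresholds=[0.2, 0.5, 0.8])
    samp_t = s.sample_meta["label"]
    for k, th in enumerate([0.2, 0.5, 0.8]):
        tp = fp = pos = neg = 0
        for hid in s.means.index:
            for samp in s.means.columns:
                match = t_series.loc[hid] == samp_t.loc[samp]
                below = s.means.loc[hid, samp] < th
                pos += match
                neg += not match
                tp += match and below
                fp += (not match) and below
        assert res.sensitivity[k] == pytest.approx(tp / pos)
        assert res.fpr[k] == pytest.approx(fp / neg)


def test_validation_permuted_labels_auc_half(rng):
    s, t_series = validation_fixture()
    aucs = []
    for _ in range(20):
        perm = pd.Series(rng.permutation(s.sample_meta["label"].to_numpy()),
                         index=s.sample_meta.index)
        aucs.append(validate_catalog(s, t_series, sample_tissue=perm).auc)
    assert abs(np.mean(aucs) - 0.5) <= 0.05


def test_clustering_recovers_planted_blocks_and_twins(rng):
    # two cancer types with disjoint event sets
    n_per = 6
    labels = ["A"] * n_per + ["B"] * n_per
    rows = []
    for h in range(6):
        vec = [0.8 if (lab == ("A" if h < 3 else "B")) else 0.05
               for lab in labels]
        rows.append(vec)
    hmrs, bm = toy_matrix(rows, [1] * 6, labels=labels)
    s = hmr_beta_summary(hmrs, bm)
    cr = cluster_samples(s)
    cut = cr.cut(2)
    a_labels = {cut[f"s{i}"] for i in range(n_per)}
    b_labels = {cut[f"s{i}"] for i in range(n_per, 2 * n_per)}
    assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels
    # Jaccard distance between twin samples is zero
    from scipy.spatial.distance import jaccard
    bin_a = cr.binary.loc["s0"].to_numpy()
    bin_b = cr.binary.loc["s1"].to_numpy()
    assert np.array_equal(bin_a, bin_b)
    newick = cr.newick()
    assert newick.endswith(";") and "s0" in newick


def test_clustering_jaccard_matches_set_formula(rng):
    rows = (rng.random((8, 9)) < 0.4) * 0.9
    hmrs, bm = toy_matrix(rows.tolist(), [1] * 8)
    s = hmr_beta_summary(hmrs, bm)
    cr = cluster_samples(s)
    from scipy.spatial.distance import squareform
    b = cr.binary.to_numpy()
    for i in range(3):
        for j in range(i + 1, 3):
            si, sj = set(np.flatnonzero(b[i])), set(np.flatnonzero(b[j]))
            union = len(si | sj)
            want = 0.0 if union == 0 else 1 - len(si & sj) / union
            from scipy.spatial.distance import pdist
            d = pdist(b[[i, j]], metric="jaccard")[0]
            if np.isnan(d):
                d = 0.0
            assert d == pytest.approx(want)


def test_no_probes_is_error():
    hmrs, bm = toy_matrix([[0.1, 0.2]], [1])
    empty = BetaMatrix(bm.beta.iloc[:0], bm.probe_coords.iloc[:0],
                       bm.sample_meta)
    with pytest.raises(ValueError):
        hmr_beta_summary(hmrs, empty)
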
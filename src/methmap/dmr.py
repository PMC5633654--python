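"""Differentially methylated region (DMR) calling and genome-wide statistics.

DMRs between two samples are called from their smoothed profiles: a CpG is
*separated* when the 95% confidence bands of the two profiles are disjoint
(hyper when sample A's band lies entirely above B's, hypo when entirely
below).  Maximal same-direction runs of at least ``min_consecutive``
separated CpGs become DMRs — the default of 6 implements a
"more than five consecutive CpGs" rule.  Band disjointness with a constant
sign is a deliberately strict criterion; it keeps the false-call rate per
CpG far below the nominal 5% because both bands must miss simultaneously
and in opposite directions, six times in a row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet
from .io import MethylomeTable
from .smoothing import SmoothedProfile

logger = logging.getLogger(__name__)

__all__ = ["DMR", "GlobalStats", "NeighborCorrelation", "call_dmrs",
           "global_stats", "neighbor_correlation", "interval_methylation_compare"]


@dataclass(frozen=True)
class DMR:
    """One differentially methylated region (sample A minus sample B)."""

    interval: GenomicInterval
    direction: str  # "hyper" | "hypo"
    n_cpg: int
    mean_delta: float

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.direction == "hyper") != (self.mean_delta > 0):
            raise ValueError("direction inconsistent with the sign of mean_delta")


@dataclass(frozen=True)
class GlobalStats:
    """Cross-sample per-CpG variability summary on jointly covered CpGs."""

    mean_levels: dict  # sample_id -> genome-wide mean level
    sd: np.ndarray  # per-CpG cross-sample standard deviation
    fraction_sd_gt: float
    n_sites: int
    sd_threshold: float


@dataclass(frozen=True)
class NeighborCorrelation:
    """Pearson correlation between adjacent CpG levels."""

    r: float
    n_pairs: int
    defined: bool


def _align(a: SmoothedProfile, b: SmoothedProfile):
    fa, fb = a.to_frame(), b.to_frame()
    merged = fa.merge(fb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    dropped = len(fa) + len(fb) - 2 * len(merged)
    if dropped:
        logger.info("call_dmrs: dropped %d positions absent from one profile", dropped)
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def call_dmrs(a: SmoothedProfile, b: SmoothedProfile,
              min_consecutive: int = 6) -> list[DMR]:
    """Call DMRs between two smoothed profiles (direction = A relative to B)."""
    merged = _align(a, b)
    if len(merged) < min_consecutive:
        logger.warning("fewer than %d shared CpGs; no DMRs callable", min_consecutive)
        return []
    sign = np.zeros(len(merged), dtype=np.int8)
    sign[merged["ci_low_a"].to_numpy() > merged["ci_high_b"].to_numpy()] = 1
    sign[merged["ci_high_a"].to_numpy() < merged["ci_low_b"].to_numpy()] = -1

    dmrs: list[DMR] = []
    pos = merged["pos"].to_numpy()
    delta = merged["level_hat_a"].to_numpy() - merged["level_hat_b"].to_numpy()
    for chrom, sub in merged.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        s = sign[idx]
        # maximal constant-sign nonzero runs
        boundaries = np.flatnonzero(np.diff(s) != 0) + 1
        for seg in np.split(np.arange(len(s)), boundaries):
            if s[seg[0]] == 0 or len(seg) < min_consecutive:
                continue
            g = idx[seg]
            direction = "hyper" if s[seg[0]] > 0 else "hypo"
            dmrs.append(DMR(
                interval=GenomicInterval(chrom, int(pos[g[0]]), int(pos[g[-1]]) + 2),
                direction=direction,
                n_cpg=len(seg),
                mean_delta=float(delta[g].mean()),
            ))
    return dmrs


def global_stats(samples: list[MethylomeTable], sd_threshold: float = 0.1,
                 min_coverage: int = 5) -> GlobalStats:
    """Per-CpG cross-sample standard deviation on CpGs covered at
    ``>= min_coverage`` reads in *all* samples, plus per-sample genome-wide
    mean levels (over each sample's own covered CpGs)."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    frames = []
    for i, s in enumerate(samples):
        df = s.df[s.df["total"] >= min_coverage]
        frames.append(pd.DataFrame({
            "chrom": df["chrom"], "pos": df["pos"],
            f"lev{i}": df["meth"].to_numpy() / df["total"].to_numpy()}))
    joint = frames[0]
    for f in frames[1:]:
        joint = joint.merge(f, on=["chrom", "pos"])
    if joint.empty:
        raise ValueError("no CpGs jointly covered at the requested depth")
    levels = joint[[f"lev{i}" for i in range(len(samples))]].to_numpy()
    sd = levels.std(axis=1, ddof=1)
    return GlobalStats(
        mean_levels={s.sample_id: s.mean_level() for s in samples},
        sd=sd,
        fraction_sd_gt=float((sd > sd_threshold).mean()),
        n_sites=len(joint),
        sd_threshold=sd_threshold,
    )


def neighbor_correlation(sample: MethylomeTable,
                         max_distance_bp: int = 1000) -> NeighborCorrelation:
    """Pearson r between levels of adjacent CpGs within ``max_distance_bp``."""
    xs, ys = [], []
    for _, pos, m, t in sample.per_chrom():
        lev = m / t
        close = np.diff(pos) <= max_distance_bp
        xs.append(lev[:-1][close])
        ys.append(lev[1:][close])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if len(x) < 10:
        raise ValueError(f"only {len(x)} adjacent pairs within {max_distance_bp} bp")
    if x.std() == 0 or y.std() == 0:
        return NeighborCorrelation(r=float("nan"), n_pairs=len(x), defined=False)
    r, _ = stats.pearsonr(x, y)
    return NeighborCorrelation(r=float(r), n_pairs=len(x), defined=True)


def interval_methylation_compare(samples_a: list[MethylomeTable],
                                 samples_b: list[MethylomeTable],
                                 regions: IntervalSet) -> pd.DataFrame:
    """Per-region mean methylation per sample and a two-sample Student t-test.

    Regions with zero covered CpGs in any sample are excluded (the count is
    in the ``n_excluded`` DataFrame attribute).  Returns one row per kept
    region with per-group means, t and two-sided p.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per group for a t-test")

    def region_means(sample: MethylomeTable) -> np.ndarray:
        out = np.full(len(regions), np.nan)
        by_chrom = {c: (p, m, t) for c, p, m, t in sample.per_chrom()}
        for i, (chrom, start, end) in enumerate(regions.to_tuples()):
            if chrom not in by_chrom:
                continue
            p, m, t = by_chrom[chrom]
            a = np.searchsorted(p, start, side="left")
            b = np.searchsorted(p, end, side="left")
            if b > a:
                out[i] = float((m[a:b] / t[a:b]).mean())
        return out

    ma = np.column_stack([region_means(s) for s in samples_a])
    mb = np.column_stack([region_means(s) for s in samples_b])
    keep = ~np.isnan(ma).any(axis=1) & ~np.isnan(mb).any(axis=1)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d regions without covered CpGs in every sample",
                    n_excluded)
    t_stat, p_val = stats.ttest_ind(ma[keep], mb[keep], axis=1)
    tuples = [tup for tup, k in zip(regions.to_tuples(), keep) if k]
    df = pd.DataFrame(tuples, columns=["chrom", "start", "end"])
    df["mean_a"] = ma[keep].mean(axis=1)
    df["mean_b"] = mb[keep].mean(axis=1)
    df["t"] = t_stat
    df["p"] = p_val
    df.attrs["n_excluded"] = n_excluded
    return df
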
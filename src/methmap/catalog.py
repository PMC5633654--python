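"""The common / frequent / tissue-specific HMR catalog and its summaries.

Given per-tissue HMR interval sets the catalog partitions hypomethylation
into:

- **c-HMRs** — regions strictly covered by HMRs in *all* tissues (exact
  base-level intersection), then merged across gaps of at most
  ``merge_gap_bp`` (default 100 bp);
- **t-HMRs** — a tissue's HMRs sharing zero bases with any other tissue's
  HMRs;
- **frequent HMRs** — merged regions covered in strictly more than
  ``frequent_fraction`` of the tissues (default >50%) that do not overlap
  any c-HMR.

The partition-algebra invariants (t-HMR disjointness, frequent vs common
disjointness) are asserted on every build.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, intersect, merge, overlap_any
from .io import MethylomeTable

logger = logging.getLogger(__name__)

__all__ = ["HMRCatalog", "EnrichmentResult", "build_catalog", "co_activation",
           "composite_profile", "interval_enrichment"]


@dataclass
class HMRCatalog:
    tissues: list[str]
    per_tissue_hmrs: dict[str, IntervalSet]
    c_hmrs: IntervalSet
    frequent_hmrs: IntervalSet
    t_hmrs: dict[str, IntervalSet]


def _coverage_threshold_regions(sets: list[IntervalSet], min_count: int) -> IntervalSet:
    """Bases covered by at least ``min_count`` of the given interval sets."""
    events: dict[str, list[tuple[int, int]]] = {}
    for ivs in sets:
        for chrom, start, end in merge(ivs, 0).to_tuples():
            events.setdefault(chrom, []).append((start, +1))
            events[chrom].append((end, -1))
    rows = []
    for chrom, evs in events.items():
        evs.sort()
        depth, run_start = 0, None
        for bp, delta in evs:
            new_depth = depth + delta
            if depth < min_count <= new_depth and run_start is None:
                run_start = bp
            elif run_start is not None and new_depth < min_count:
                if bp > run_start:
                    rows.append((chrom, run_start, bp))
                run_start = None
            depth = new_depth
    return IntervalSet.from_tuples(rows)


def build_catalog(per_tissue_hmrs: dict[str, IntervalSet], merge_gap_bp: int = 100,
                  frequent_fraction: float = 0.5) -> HMRCatalog:
    """Build the c / frequent / tissue-specific HMR partition."""
    tissues = sorted(per_tissue_hmrs)
    if len(tissues) < 2:
        raise ValueError("a catalog needs at least two tissues")
    sets = [per_tissue_hmrs[t] for t in tissues]

    common = sets[0]
    for other in sets[1:]:
        common = intersect(common, other)
    c_hmrs = merge(common, merge_gap_bp)

    t_hmrs: dict[str, IntervalSet] = {}
    for t in tissues:
        others_df = pd.concat([per_tissue_hmrs[o].df[["chrom", "start", "end"]]
                               for o in tissues if o != t], ignore_index=True)
        others = IntervalSet(others_df)
        own = per_tissue_hmrs[t]
        flags = overlap_any(own, others)
        t_hmrs[t] = IntervalSet(own.df[~flags])

    min_count = int(np.floor(frequent_fraction * len(tissues))) + 1
    freq_raw = merge(_coverage_threshold_regions(sets, min_count), merge_gap_bp)
    freq_keep = ~overlap_any(freq_raw, c_hmrs)
    frequent = IntervalSet(freq_raw.df[freq_keep])

    catalog = HMRCatalog(tissues, dict(per_tissue_hmrs), c_hmrs, frequent, t_hmrs)
    _assert_partition(catalog)
    return catalog


def _assert_partition(catalog: HMRCatalog) -> None:
    for t in catalog.tissues:
        others_df = pd.concat(
            [catalog.per_tissue_hmrs[o].df[["chrom", "start", "end"]]
             for o in catalog.tissues if o != t], ignore_index=True)
        if overlap_any(catalog.t_hmrs[t], IntervalSet(others_df)).any():
            raise AssertionError(f"t-HMRs of {t} overlap another tissue's HMRs")
    if len(catalog.frequent_hmrs) and len(catalog.c_hmrs):
        if overlap_any(catalog.frequent_hmrs, catalog.c_hmrs).any():
            raise AssertionError("frequent HMRs overlap c-HMRs")


def co_activation(catalog: HMRCatalog, promoters: dict[str, "object"],
                  promoter_state: dict[str, dict[str, str]],
                  proximity_bp: int = 10_000) -> pd.DataFrame:
    """Cross-tissue co-activation of t-HMRs with promoter hypomethylation.

    ``promoters`` maps gene -> GenomicInterval; ``promoter_state`` maps
    tissue -> gene -> {"hypomethylated", "methylated"}.  Entry (i, j) is the
    fraction of tissue-i t-HMRs whose nearest gene (within ``proximity_bp``)
    has a hypomethylated promoter in tissue j.  t-HMRs without an
    assignable gene are skipped; their count is in ``df.attrs["n_skipped"]``.
    Rows for tissues without any t-HMRs hold NaN.
    """
    genes = sorted(promoters)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        iv = promoters[g]
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, g))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    def nearest_gene(chrom: str, start: int, end: int):
        best, best_d = None, None
        for s, e, g in by_chrom.get(chrom, ()):  # promoter lists are short
            if s < end and e > start:
                d = 0  # overlap
            else:
                d = s - end if s >= end else start - e
            if best_d is None or d < best_d:
                best, best_d = g, d
        return (best, best_d) if best is not None else (None, None)

    tissues = catalog.tissues
    mat = np.full((len(tissues), len(tissues)), np.nan)
    n_skipped = 0
    for i, ti in enumerate(tissues):
        assigned: list[str] = []
        for chrom, start, end in catalog.t_hmrs[ti].to_tuples():
            g, d = nearest_gene(chrom, start, end)
            if g is None or d > proximity_bp:
                n_skipped += 1
                continue
            assigned.append(g)
        if not assigned:
            logger.warning("tissue %s has no gene-assignable t-HMRs", ti)
            continue
        for j, tj in enumerate(tissues):
            state = promoter_state.get(tj, {})
            hypo = sum(state.get(g) == "hypomethylated" for g in assigned)
            mat[i, j] = hypo / len(assigned)
    df = pd.DataFrame(mat, index=tissues, columns=tissues)
    df.attrs["n_skipped"] = n_skipped
    return df


def composite_profile(hmrs: IntervalSet, samples: list[MethylomeTable],
                      flank_bp: int = 2000, bin_bp: int = 4) -> pd.DataFrame:
    """Average methylation around HMR centers, binned at ``bin_bp``.

    CpGs are mapped to their offset from each HMR center within
    ``+/- flank_bp`` and averaged per bin per sample.  Bins without CpGs are
    NaN (empty, not zero).  The index holds bin-center offsets in bp.
    """
    if len(hmrs) == 0:
        raise ValueError("no HMRs given")
    n_bins = (2 * flank_bp) // bin_bp
    centers = [(chrom, (start + end) // 2) for chrom, start, end in hmrs.to_tuples()]
    data = {}
    for sample in samples:
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=np.int64)
        by_chrom = {c: (p, m, t) for c, p, m, t in sample.per_chrom()}
        for chrom, c in centers:
            if chrom not in by_chrom:
                continue
            p, m, t = by_chrom[chrom]
            a = np.searchsorted(p, c - flank_bp, side="left")
            b = np.searchsorted(p, c + flank_bp, side="left")
            if b == a:
                continue
            offs = p[a:b] - (c - flank_bp)
            bins = np.minimum(offs // bin_bp, n_bins - 1)
            np.add.at(sums, bins, m[a:b] / t[a:b])
            np.add.at(counts, bins, 1)
        with np.errstate(invalid="ignore"):
            data[sample.sample_id] = np.where(counts > 0, sums / np.maximum(counts, 1),
                                              np.nan)
    index = np.arange(n_bins) * bin_bp - flank_bp + bin_bp // 2
    return pd.DataFrame(data, index=pd.Index(index, name="offset_bp"))


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 tile-count enrichment of a query against an annotation."""

    table: np.ndarray  # [[q&a, q&!a], [!q&a, !q&!a]]
    odds_ratio: float
    p_value: float
    degenerate: bool  # a margin is empty; OR undefined


def _tile_universe(universe: IntervalSet, tile_bp: int) -> IntervalSet:
    rows = []
    for chrom, start, end in merge(universe, 0).to_tuples():
        edges = np.arange(start, end, tile_bp)
        for s in edges:
            rows.append((chrom, int(s), int(min(s + tile_bp, end))))
    return IntervalSet.from_tuples(rows)


def interval_enrichment(query: IntervalSet, annotation: IntervalSet,
                        universe: IntervalSet, tile_bp: int = 100) -> EnrichmentResult:
    """Fisher's exact test for query/annotation co-occurrence over the universe.

    The universe is tiled at ``tile_bp`` (a tile belongs to the query or
    annotation when it shares at least one base with it), which keeps
    neighbouring bases from being counted as independent observations.
    """
    if len(query) == 0 or len(annotation) == 0:
        raise ValueError("query and annotation must be non-empty")
    tiles = _tile_universe(universe, tile_bp)
    in_q = overlap_any(tiles, query)
    in_a = overlap_any(tiles, annotation)
    table = np.array([
        [int((in_q & in_a).sum()), int((in_q & ~in_a).sum())],
        [int((~in_q & in_a).sum()), int((~in_q & ~in_a).sum())],
    ])
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        logger.warning("enrichment table has an empty margin; OR undefined")
        return EnrichmentResult(table, float("nan"), 1.0, True)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table, float(odds), float(p), False)
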
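"""Genomic interval containers and exact interval algebra.

All coordinates are 0-based half-open (BED convention) throughout the
package.  The operations here are the primitives every downstream stage
relies on: base-level intersection (used to build the common-HMR
catalog), gap-tolerant merging (the 100-bp merge of the catalog step) and
any-overlap flags (the tissue-specificity test).  Their semantics are
defined at base resolution and are verified against per-base boolean-array
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "intersect",
    "merge",
    "overlap_any",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    attributes: Mapping | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An immutable, sorted collection of genomic intervals.

    Backed by a pandas DataFrame with at least ``chrom``, ``start`` and
    ``end`` columns; extra columns (e.g. BED name/score) are preserved by
    the readers and writers but ignored by the algebra.  Intervals within
    one set may overlap unless an operation states otherwise; operations
    with base-coverage semantics normalise internally.
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, intervals: pd.DataFrame | Iterable[GenomicInterval] = ()):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
        else:
            rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
            df = pd.DataFrame(rows, columns=list(self.REQUIRED))
        if df.empty:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"interval table lacks required column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative coordinates are not allowed")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"empty or inverted interval: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self._df = df.reset_index(drop=True)

    # -- container protocol -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.to_tuples() == other.to_tuples()

    def to_tuples(self) -> list[tuple[str, int, int]]:
        return list(zip(self._df["chrom"], self._df["start"].tolist(),
                        self._df["end"].tolist()))

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        df = pd.DataFrame(list(tuples), columns=["chrom", "start", "end"])
        return cls(df)

    def chromosomes(self) -> list[str]:
        return sorted(self._df["chrom"].unique())

    def coverage_bp(self) -> int:
        """Total bases covered (overlaps within the set counted once)."""
        return sum(int(e - s) for _, s, e in merge(self, 0).to_tuples())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IntervalSet({len(self)} intervals, {len(self.chromosomes())} chromosomes)"


def _per_chrom(a: IntervalSet) -> dict[str, np.ndarray]:
    out = {}
    for chrom, sub in a.df.groupby("chrom", sort=True):
        out[chrom] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return out


def merge(a: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Union intervals that overlap or lie within ``max_gap`` bases.

    Gaps of exactly ``max_gap`` are closed; gaps strictly larger survive.
    The result is non-overlapping and sorted.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    rows: list[tuple[str, int, int]] = []
    for chrom, arr in _per_chrom(a).items():
        cur_s, cur_e = None, None
        for s, e in arr:  # sorted by (start, end)
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s - cur_e <= max_gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return IntervalSet.from_tuples(rows)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact base-level intersection of the coverage of two sets."""
    am, bm = _per_chrom(merge(a, 0)), _per_chrom(merge(b, 0))
    rows: list[tuple[str, int, int]] = []
    for chrom in sorted(set(am) & set(bm)):
        xa, xb = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xa) and j < len(xb):
            lo = max(xa[i, 0], xb[j, 0])
            hi = min(xa[i, 1], xb[j, 1])
            if lo < hi:
                rows.append((chrom, int(lo), int(hi)))
            if xa[i, 1] <= xb[j, 1]:
                i += 1
            else:
                j += 1
    return IntervalSet.from_tuples(rows)


def overlap_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Per-interval flags: does each interval of ``a`` share >=1 base with ``b``?

    Returned in the (sorted) order of ``a.df``.  Touching half-open
    intervals share zero bases and do not count as overlapping.
    """
    bm = _per_chrom(merge(b, 0))
    flags = np.zeros(len(a), dtype=bool)
    df = a.df
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in bm:
            continue
        arr = bm[chrom]
        starts, ends = arr[:, 0], arr[:, 1]
        # candidate = rightmost b-interval starting before a.end; b is merged
        # and sorted, so it is the only one that can reach into a.
        idx = np.searchsorted(starts, sub["end"].to_numpy(), side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = ends[idx[ok]] > sub["start"].to_numpy()[ok]
        flags[sub.index.to_numpy()] = hit
    return flags


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (tab-separated, 0-based half-open)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return IntervalSet()
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(6, df.shape[1])]
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write an IntervalSet as BED (round-trips through :func:`read_bed`)."""
    intervals.df.to_csv(path, sep="\t", header=False, index=False)
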
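"""Readers and writers for per-CpG methylation call tables.

Two text dialects are supported:

``bismark_cov``
    The Bismark coverage format: ``chrom  start  end  %meth  count_M  count_U``
    with 1-based inclusive coordinates.  Positions are converted to 0-based
    at the boundary.

``bedgraph_counts``
    A bedGraph-with-counts table: ``chrom  start  end  %meth  count_M
    count_total`` with 0-based half-open coordinates (``end = start + 1``).

Internally everything is 0-based; chromosome names are compared as exact
strings (no "chr" aliasing).  CpGs with zero total reads carry no level and
are dropped at read time with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MethylomeTable", "ParseError", "read_cpg_table", "write_cpg_table"]

DIALECTS = ("bismark_cov", "bedgraph_counts")
STATUSES = ("normal", "cancer_primary", "cancer_cell_line", "metastasis")


class ParseError(ValueError):
    """A methylation call table row could not be parsed."""


@dataclass
class MethylomeTable:
    """One sample's ordered per-CpG methylation calls.

    ``df`` holds columns ``chrom`` (str), ``pos`` (0-based int position of
    the CpG cytosine), ``meth`` and ``total`` (read counts).  Rows are
    sorted by (chrom, pos) with no duplicate positions and ``total >= 1``
    everywhere; the constructor enforces all invariants.
    """

    df: pd.DataFrame
    sample_id: str = "sample"
    tissue: str = ""
    status: str = "normal"

    def __post_init__(self) -> None:
        df = self.df
        required = ("chrom", "pos", "meth", "total")
        for col in required:
            if col not in df.columns:
                raise ValueError(f"methylome table lacks column {col!r}")
        df = df[list(required)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["total"] = df["total"].astype(np.int64)
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (df["total"] < 1).any():
            raise ValueError("total read count must be >= 1 at every site")
        if ((df["meth"] < 0) | (df["meth"] > df["total"])).any():
            raise ValueError("need 0 <= meth <= total at every site")
        if (df["pos"] < 0).any():
            raise ValueError("negative positions are not allowed")
        sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort")
        if not sorted_df[["pos"]].equals(df[["pos"]]):
            logger.info("methylome table was unsorted; sorting by (chrom, pos)")
        df = sorted_df.reset_index(drop=True)
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate CpG position {dup['chrom']}:{dup['pos']}")
        self.df = df

    # -- accessors ----------------------------------------------------------
    @property
    def levels(self) -> np.ndarray:
        """Per-CpG methylation levels meth/total in [0, 1]."""
        return self.df["meth"].to_numpy() / self.df["total"].to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def per_chrom(self):
        """Yield ``(chrom, pos, meth, total)`` numpy arrays per chromosome."""
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield (chrom,
                   sub["pos"].to_numpy(),
                   sub["meth"].to_numpy(),
                   sub["total"].to_numpy())

    def subset(self, chrom: str) -> "MethylomeTable":
        sub = self.df[self.df["chrom"] == chrom].reset_index(drop=True)
        return replace(self, df=sub)

    def mean_level(self) -> float:
        """Genome-wide average methylation (unweighted mean of CpG levels)."""
        return float(self.levels.mean())


def _parse_rows(path, dialect: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                c1 = int(parts[4])
                c2 = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if dialect == "bismark_cov":
                pos, meth, total = start - 1, c1, c1 + c2
            else:  # bedgraph_counts
                pos, meth, total = start, c1, c2
            if pos < 0 or meth < 0 or total < 0 or meth > total:
                raise ParseError(f"{path}:{lineno}: inconsistent counts/position")
            rows.append((chrom, pos, meth, total))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])


def read_cpg_table(path, dialect: str = "bismark_cov", *,
                   sample_id: str = "sample", tissue: str = "",
                   status: str = "normal") -> MethylomeTable:
    """Read a per-CpG methylation call table.

    Zero-coverage rows are dropped (count logged); unsorted input is sorted
    with a notice; duplicate positions raise.  Malformed rows raise
    :class:`ParseError` naming the line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = _parse_rows(path, dialect)
    n_zero = int((df["total"] == 0).sum()) if len(df) else 0
    if n_zero:
        logger.info("%s: dropped %d zero-coverage CpGs", path, n_zero)
        df = df[df["total"] > 0].reset_index(drop=True)
    return MethylomeTable(df, sample_id=sample_id, tissue=tissue, status=status)


def write_cpg_table(table: MethylomeTable, path, dialect: str = "bismark_cov") -> None:
    """Write a methylome table in one of the supported dialects."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = table.df
    pct = 100.0 * df["meth"].to_numpy() / df["total"].to_numpy()
    if dialect == "bismark_cov":
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": df["meth"],
            "unmeth": df["total"] - df["meth"],
        })
    else:
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": df["meth"],
            "total": df["total"],
        })
    out.to_csv(path, sep="\t", header=False, index=False)
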
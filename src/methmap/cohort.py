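"""Cohort-scale hypermethylation analysis on probe-level beta matrices.

This is the array stage of the pipeline: probes (HumanMethylation450-style
beta values in [0, 1] with genomic coordinates) are mapped into catalog
HMRs, per-HMR per-sample mean betas are computed, and the cohort rules are
applied:

- *confirmation*: an HMR is confirmed hypomethylated when it carries at
  least ``min_probes`` probes and its mean beta is <= ``max_beta`` in every
  normal sample;
- *hypermethylation events*: mean beta strictly above the intensity cut
  (default 0.33) in at least the frequency cut (default 25%) of cancer
  samples;
- *positive-selection candidates*: promoter HMRs with >= 2 probes whose
  high-intensity hypermethylation (mean beta > 0.50) recurs in more than
  1% of (optionally solid-only) cancer samples;
- *catalog validation*: threshold sweep over tissue-specific HMRs scoring
  a (t-HMR, sample) pair as positive when the mean beta falls below the
  threshold, a true positive when the sample's tissue matches the t-HMR's,
  and a false positive otherwise; AUC by trapezoid;
- *clustering*: Jaccard distances on dichotomised (beta > 0.33) sample
  profiles with Ward agglomeration.

Missing betas are excluded pairwise; a per-HMR per-sample mean needs at
least one non-missing probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

__all__ = ["BetaMatrix", "HMRBetaSummary", "ValidationResult", "ClusterResult",
           "hmr_beta_summary", "confirm_hypomethylated",
           "call_hypermethylation_events", "positive_selection_candidates",
           "validate_catalog", "cluster_samples"]


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions with probe coordinates.

    ``beta``: DataFrame (probes x samples), values in [0, 1] or NaN.
    ``probe_coords``: DataFrame indexed by probe id with ``chrom``/``pos``.
    ``sample_meta``: DataFrame indexed by sample id with ``label`` (tissue or
    cancer type) and ``group`` ("normal" | "cancer"); an optional boolean
    ``solid`` column marks solid-tumor samples.
    """

    beta: pd.DataFrame
    probe_coords: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.beta.index.difference(self.probe_coords.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack coordinates")
        if not self.beta.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.beta.columns]
        bad = set(self.sample_meta["group"]) - {"normal", "cancer"}
        if bad:
            raise ValueError(f"unknown sample groups: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class HMRBetaSummary:
    """Per-HMR probe counts and per-sample mean betas.

    ``hmrs``: DataFrame (hmr_id -> chrom/start/end), ``n_probes``: Series,
    ``means``: DataFrame (hmr_id x samples), ``represented``: boolean Series
    (n_probes >= the min_probes used at construction).
    """

    hmrs: pd.DataFrame
    n_probes: pd.Series
    means: pd.DataFrame
    represented: pd.Series
    sample_meta: pd.DataFrame

    def group_samples(self, group: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["group"] == group])


def hmr_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def hmr_beta_summary(catalog_hmrs: IntervalSet, betas: BetaMatrix,
                     min_probes: int = 1) -> HMRBetaSummary:
    """Map probes into HMRs and compute per-HMR per-sample mean betas."""
    if len(betas.beta) == 0:
        raise ValueError("beta matrix has no probes")
    coords = betas.probe_coords.loc[betas.beta.index]
    hmr_rows = catalog_hmrs.df[["chrom", "start", "end"]].reset_index(drop=True)
    ids = [hmr_id(r.chrom, r.start, r.end) for r in hmr_rows.itertuples(index=False)]

    assign = np.full(len(coords), -1, dtype=np.int64)
    for chrom, sub in hmr_rows.groupby("chrom", sort=False):
        pchrom = coords["chrom"].to_numpy() == chrom
        if not pchrom.any():
            continue
        ppos = coords["pos"].to_numpy()[pchrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, ppos, side="right") - 1
        ok = (idx >= 0) & (ppos < ends[np.clip(idx, 0, None)])
        tgt = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, None)], -1)
        assign[pchrom] = tgt

    vals = betas.beta.to_numpy(dtype=float)
    n_h = len(hmr_rows)
    n_s = vals.shape[1]
    sums = np.zeros((n_h, n_s))
    counts = np.zeros((n_h, n_s), dtype=np.int64)
    n_probes = np.zeros(n_h, dtype=np.int64)
    inside = assign >= 0
    np.add.at(n_probes, assign[inside], 1)
    finite = np.isfinite(vals)
    safe = np.where(finite, vals, 0.0)
    np.add.at(sums, assign[inside], safe[inside])
    np.add.at(counts, assign[inside], finite[inside].astype(np.int64))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    hmrs = hmr_rows.copy()
    hmrs.index = pd.Index(ids, name="hmr")
    return HMRBetaSummary(
        hmrs=hmrs,
        n_probes=pd.Series(n_probes, index=hmrs.index, name="n_probes"),
        means=pd.DataFrame(means, index=hmrs.index, columns=betas.beta.columns),
        represented=pd.Series(n_probes >= min_probes, index=hmrs.index,
                              name="represented"),
        sample_meta=betas.sample_meta.copy(),
    )


def confirm_hypomethylated(summary: HMRBetaSummary, normal_samples=None,
                           max_beta: float = 0.30,
                           min_probes: int = 6) -> pd.Index:
    """HMR ids with >= min_probes probes and mean beta <= max_beta in all
    normal samples (NaN means ignored)."""
    normal_samples = list(normal_samples) if normal_samples is not None \
        else summary.group_samples("normal")
    if not normal_samples:
        raise ValueError("no normal samples given")
    sub = summary.means[normal_samples]
    ok_beta = ((sub <= max_beta) | sub.isna()).all(axis=1) & sub.notna().any(axis=1)
    ok = ok_beta & (summary.n_probes >= min_probes)
    return summary.means.index[ok]


def call_hypermethylation_events(summary: HMRBetaSummary, cancer_samples=None,
                                 intensity: float = 0.33,
                                 frequency: float = 0.25,
                                 hmr_ids=None) -> pd.DataFrame:
    """Call frequent hypermethylation events among cancer samples.

    Returns a DataFrame indexed by HMR id with ``event_frequency`` (fraction
    of non-missing cancer samples with mean beta strictly above
    ``intensity``) and ``is_event`` (frequency >= ``frequency``).  HMRs with
    no non-missing cancer value are excluded; their count is in
    ``df.attrs["n_excluded"]``.
    """
    cancer_samples = list(cancer_samples) if cancer_samples is not None \
        else summary.group_samples("cancer")
    if not cancer_samples:
        raise ValueError("no cancer samples given")
    sub = summary.means[cancer_samples]
    if hmr_ids is not None:
        sub = sub.loc[hmr_ids]
    informative = sub.notna().sum(axis=1)
    excluded = int((informative == 0).sum())
    sub = sub[informative > 0]
    frac = (sub > intensity).sum(axis=1) / sub.notna().sum(axis=1)
    out = pd.DataFrame({"event_frequency": frac, "is_event": frac >= frequency})
    out.attrs["n_excluded"] = excluded
    if excluded:
        logger.info("excluded %d HMRs with no informative cancer sample", excluded)
    return out


def positive_selection_candidates(summary: HMRBetaSummary, promoter_flags: pd.Series,
                                  cancer_samples=None, intensity: float = 0.50,
                                  min_freq: float = 0.01, min_probes: int = 2,
                                  solid_only: bool = False) -> pd.Index:
    """Promoter HMRs under putative positive selection.

    Candidates carry >= ``min_probes`` probes, overlap a promoter
    (``promoter_flags``), and show mean beta strictly above ``intensity`` in
    strictly more than ``min_freq`` of the evaluated cancer samples
    (restricted to solid tumors when ``solid_only``).
    """
    if cancer_samples is None:
        cancer_samples = summary.group_samples("cancer")
    cancer_samples = list(cancer_samples)
    if solid_only:
        if "solid" not in summary.sample_meta.columns:
            raise ValueError("solid_only requires a 'solid' sample_meta column")
        solid = summary.sample_meta["solid"].astype(bool)
        cancer_samples = [s for s in cancer_samples if solid.loc[s]]
    sub = summary.means[cancer_samples]
    with np.errstate(invalid="ignore"):
        frac = (sub > intensity).sum(axis=1) / sub.notna().sum(axis=1).clip(lower=1)
    flags = promoter_flags.reindex(summary.means.index).fillna(False).astype(bool)
    ok = flags & (summary.n_probes >= min_probes) & (frac > min_freq)
    return summary.means.index[ok]


@dataclass(frozen=True)
class ValidationResult:
    """Threshold sweep of t-HMR recovery: sensitivity/FPR per threshold + AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auc: float
    n_matched_pairs: int
    n_unmatched_pairs: int


def validate_catalog(summary: HMRBetaSummary, t_hmr_tissue: pd.Series,
                     sample_tissue: pd.Series | None = None,
                     thresholds=None) -> ValidationResult:
    """Sweep hypomethylation-call thresholds over tissue-specific HMRs.

    A (t-HMR, sample) pair is called when the HMR's mean beta in that sample
    is below the threshold; calls in the t-HMR's own tissue are true
    positives, calls in any other tissue false positives.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if sample_tissue is None:
        sample_tissue = summary.sample_meta["label"]
    ids = t_hmr_tissue.index.intersection(summary.means.index)
    if len(ids) == 0:
        raise ValueError("no t-HMRs present in the summary")
    means = summary.means.loc[ids].to_numpy(dtype=float)
    hmr_t = t_hmr_tissue.loc[ids].to_numpy()
    samp_t = sample_tissue.reindex(summary.means.columns).to_numpy()
    matched = hmr_t[:, None] == samp_t[None, :]
    valid = np.isfinite(means)
    n_tp_pairs = int((matched & valid).sum())
    n_fp_pairs = int((~matched & valid).sum())
    if n_tp_pairs == 0:
        raise ValueError("no (t-HMR, matched sample) pairs to evaluate")
    sens = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, th in enumerate(thresholds):
        below = valid & (means < th)
        sens[i] = (below & matched).sum() / n_tp_pairs
        fpr[i] = (below & ~matched).sum() / n_fp_pairs if n_fp_pairs else 0.0
    order = np.argsort(fpr, kind="mergesort")
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], sens[order], [1.0]])
    auc = float(np.trapezoid(fy, fx))
    return ValidationResult(thresholds, sens, fpr, auc, n_tp_pairs, n_fp_pairs)


@dataclass
class ClusterResult:
    """Ward/Jaccard clustering of dichotomised sample profiles."""

    linkage: np.ndarray
    samples: list[str]
    binary: pd.DataFrame  # samples x HMRs
    all_identical: bool

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.samples[node.id]
            return (f"({rec(node.left)}:{node.dist / 2:.6g},"
                    f"{rec(node.right)}:{node.dist / 2:.6g})")

        return rec(tree) + ";"


def cluster_samples(summary: HMRBetaSummary, dichotomize_at: float = 0.33,
                    hmr_ids=None, samples=None) -> ClusterResult:
    """Hierarchically cluster samples on dichotomised HMR methylation.

    Mean betas are dichotomised at ``dichotomize_at`` (missing counts as not
    hypermethylated), pairwise Jaccard distances are computed on the binary
    sample vectors, and Ward agglomeration builds the dendrogram.  Samples
    are ordered by id first so ties break deterministically.
    """
    means = summary.means
    if hmr_ids is not None:
        means = means.loc[hmr_ids]
    if samples is not None:
        means = means[list(samples)]
    if means.shape[1] < 3 or means.shape[0] < 2:
        raise ValueError("need >= 3 samples and >= 2 HMRs to cluster")
    means = means[sorted(means.columns)]
    binary = (means > dichotomize_at).T.astype(bool)  # samples x HMRs
    dist = pdist(binary.to_numpy(), metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero vectors are identical
    all_identical = bool(np.all(dist == 0.0))
    if all_identical:
        logger.warning("all dichotomised sample vectors identical; single cluster")
    Z = hierarchy.linkage(dist, method="ward")
    return ClusterResult(Z, list(binary.index), binary, all_identical)
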
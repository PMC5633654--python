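"""Weighted-permutation test for mutually exclusive alteration patterns.

The statistic is the *coverage* of a gene set: the number of samples
altered in at least one gene of the set.  Under mutual exclusivity the
same alteration counts spread over more samples, so the observed coverage
is *high* relative to a burden-respecting null.

The null preserves, per simulation, (a) each gene's observed number of
altered samples and (b) the relative overall alteration burden of each
sample: for every gene its k alterations are re-assigned to samples by
weighted sampling *without replacement* with probabilities proportional
to the per-sample total alteration burden across all genes.  Samples with
zero burden stay reachable through a small pseudo-burden so coverage is
not forced exclusively onto altered samples.  Sampling uses the
Gumbel-top-k trick (equivalent to sequential weighted draws without
replacement), which vectorises across the 10^5 default simulations.

Significance is summarised as the empirical p-value
``(1 + #{coverage_sim >= coverage_obs}) / (n_sims + 1)`` and the Z score
``(observed - null_mean) / null_sd``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AlterationMatrix", "MutexResult", "coverage_statistic",
           "mutex_test", "mutex_scan"]


@dataclass
class AlterationMatrix:
    """Binary gene x sample alteration calls (1 = hypermethylation event)."""

    calls: pd.DataFrame  # genes x samples, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("alteration calls must be binary")
        self.calls = self.calls.astype(np.int8)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def burden(self) -> np.ndarray:
        """Per-sample total alteration count over all genes."""
        return self.calls.to_numpy().sum(axis=0).astype(float)

    def subset_samples(self, samples) -> "AlterationMatrix":
        return AlterationMatrix(self.calls[list(samples)])


@dataclass(frozen=True)
class MutexResult:
    observed_coverage: int
    null_mean: float
    null_sd: float
    z_score: float  # NaN when null_sd == 0
    empirical_p: float
    n_sims: int


def coverage_statistic(matrix: AlterationMatrix, gene_set) -> int:
    """Samples altered in at least one gene of the set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    missing = set(gene_set) - set(matrix.genes)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)}")
    sub = matrix.calls.loc[gene_set].to_numpy()
    return int((sub.sum(axis=0) > 0).sum())


def mutex_test(matrix: AlterationMatrix, gene_set, n_sims: int = 100_000,
               seed: int = 0, pseudo_burden: float = 0.01) -> MutexResult:
    """Weighted-permutation mutual-exclusivity test for one gene set."""
    gene_set = list(gene_set)
    observed = coverage_statistic(matrix, gene_set)
    burden = matrix.burden()
    weights = np.where(burden > 0, burden, pseudo_burden)
    n_samples = len(weights)
    ks = [int(matrix.calls.loc[g].sum()) for g in gene_set]
    eligible = int((weights > 0).sum())
    for g, k in zip(gene_set, ks):
        if k > eligible:
            raise ValueError(f"gene {g}: {k} alterations exceed the "
                             f"{eligible} positive-weight samples")

    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):  # weight 0 -> key -inf, never drawn
        logw = np.log(weights)
    chunk = max(1, int(2e7) // max(n_samples, 1))
    parts = []
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        covered = np.zeros((m, n_samples), dtype=bool)
        for k in ks:
            if k == 0:
                continue
            # Gumbel-top-k == weighted sampling without replacement
            keys = logw[None, :] + rng.gumbel(size=(m, n_samples))
            top = np.argpartition(keys, n_samples - k, axis=1)[:, n_samples - k:]
            np.put_along_axis(covered, top, True, axis=1)
        parts.append(covered.sum(axis=1))
        done += m
    sim_cov = np.concatenate(parts)
    null_mean = float(sim_cov.mean())
    null_sd = float(sim_cov.std(ddof=0))
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (1 + int((sim_cov >= observed).sum())) / (n_sims + 1)
    return MutexResult(observed, null_mean, null_sd, float(z), float(p), n_sims)


def mutex_scan(matrix: AlterationMatrix, gene_sets: dict, n_sims: int = 100_000,
               seed: int = 0, strata: pd.Series | None = None,
               min_stratum: int = 5,
               pseudo_burden: float = 0.01) -> dict[tuple[str, str], MutexResult]:
    """Run the test per stratum (e.g. cancer type) and on the pooled matrix.

    Results are keyed by ``(set_name, stratum)``; the pooled run uses the
    stratum name ``"pooled"``.  Strata with fewer than ``min_stratum``
    samples are skipped with a warning.
    """
    results: dict[tuple[str, str], MutexResult] = {}
    layers: list[tuple[str, AlterationMatrix]] = [("pooled", matrix)]
    if strata is not None:
        strata = strata.reindex(matrix.samples)
        for name in sorted(strata.dropna().unique()):
            members = list(strata.index[strata == name])
            if len(members) < min_stratum:
                logger.warning("stratum %s has %d < %d samples; skipped",
                               name, len(members), min_stratum)
                continue
            layers.append((str(name), matrix.subset_samples(members)))
    ss = np.random.SeedSequence(seed)
    for (stratum, sub), child in zip(layers, ss.spawn(len(layers))):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        for set_name, genes in gene_sets.items():
            results[(set_name, stratum)] = mutex_test(
                sub, genes, n_sims=n_sims, seed=sub_seed,
                pseudo_burden=pseudo_burden)
    return results
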
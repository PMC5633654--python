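"""Synthetic methylomes, beta cohorts and alteration matrices with planted truth.

The generator emulates the statistical structure the analysis assumes:

- somatic methylomes are bimodal — a highly methylated background (per-CpG
  true levels Beta(7.5, 2.5), global mean ~75%, matching the 70-80% range
  typical of normal somatic tissue) punctuated by focal hypomethylated
  regions (Beta(1, 19), mean ~5%) at CpG-dense "island" sites;
- CpG positions form a clustered point process: dense islands (~10 bp
  spacing, 50-200 CpGs) at planted regulatory sites over a sparse ~100 bp
  background;
- read sampling is binomial at a zero-truncated Poisson depth
  (configurable mean coverage, default 15x, within the 6-25x range of
  real WGBS studies);
- shared (c-HMR), frequent and tissue-restricted (t-HMR) hypomethylation
  is planted by assigning island sites to tissue subsets so that the
  planted sets obey the catalog algebra by construction;
- cancer methylomes add large partially methylated blocks (intermediate
  levels), focal hypermethylation of planted c-HMR sites and a global
  hypomethylation shift, with metastasis inheriting and extending the
  primary's alterations;
- array-style beta matrices sample per-HMR means from planted
  hypomethylated baselines (uniform 0.05-0.15) or planted event
  intensities, add truncated Gaussian probe noise, and record planted
  event frequencies; planted event carriers are drawn as exact sample
  counts so recorded frequencies are exact;
- alteration matrices are independent Bernoulli per gene x sample with
  per-sample burden multipliers (null mode), or draw within-set altered
  samples disjointly (exclusive mode).

Every generator is seed-deterministic and returns its planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge
from .io import MethylomeTable
from .mutex import AlterationMatrix


def _union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    both = pd.concat([a.df[["chrom", "start", "end"]],
                      b.df[["chrom", "start", "end"]]], ignore_index=True)
    return merge(IntervalSet(both), 0)

__all__ = ["GenomeDesign", "CancerDesign", "design_genome", "design_cancer",
           "simulate_methylome", "simulate_cancer_series", "simulate_beta_cohort",
           "simulate_alteration_matrix"]

DEFAULT_TISSUES = ("bcell", "brain", "breast", "colon",
                   "liver", "lung", "placenta", "prostate")


@dataclass
class GenomeDesign:
    """A synthetic genome: CpG landscape plus planted HMR truth per tissue."""

    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    tissues: tuple[str, ...]
    hmrs_by_tissue: dict[str, IntervalSet]
    c_hmrs: IntervalSet
    frequent_hmrs: IntervalSet
    t_hmrs: dict[str, IntervalSet]
    promoters: pd.DataFrame  # gene, chrom, start, end, site_kind, tissue
    background_beta: tuple[float, float] = (7.5, 2.5)
    hmr_beta: tuple[float, float] = (1.0, 19.0)

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())


@dataclass
class CancerDesign:
    """Planted cancer alterations layered on a normal methylome design."""

    pmd_blocks: IntervalSet
    extra_pmd_blocks: IntervalSet  # metastasis-only additions
    hyper_events: pd.DataFrame  # chrom, start, end, primary_level, metastasis_level
    pmd_level: float = 0.5
    global_shift_primary: float = 0.05
    global_shift_metastasis: float = 0.10
    heterogeneity_sd: float = 0.05


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def design_genome(seed: int = 0, tissues: tuple[str, ...] = DEFAULT_TISSUES,
                  n_chromosomes: int = 2, chromosome_bp: int = 2_000_000,
                  n_shared_sites: int = 30, n_frequent_sites: int = 16,
                  n_specific_sites_per_tissue: int = 10, n_inert_sites: int = 6,
                  frequent_tissue_count: int | None = None,
                  background_spacing_bp: int = 100, island_spacing_bp: int = 10,
                  island_cpgs: tuple[int, int] = (50, 200),
                  promoter_halfwidth_bp: int = 1000) -> GenomeDesign:
    """Lay out a synthetic genome with planted c/frequent/t-HMR sites.

    Site roles are chosen so the planted truth satisfies the catalog
    algebra exactly: shared sites appear in every tissue, frequent sites in
    ``frequent_tissue_count`` tissues (default: just over half), specific
    sites in exactly one, and inert sites stay methylated everywhere.
    Sites are separated by well over the catalog merge gap so merging never
    fuses distinct planted regions.
    """
    n_tissues = len(tissues)
    if n_tissues == 0:
        raise ValueError("need at least one tissue")
    if frequent_tissue_count is None:
        frequent_tissue_count = min(n_tissues, n_tissues // 2 + 1)
    rng = _substream(seed, 0xD0)

    n_sites = (n_shared_sites + n_frequent_sites
               + n_specific_sites_per_tissue * n_tissues + n_inert_sites)
    chrom_sizes = {f"chr{i + 1}": chromosome_bp for i in range(n_chromosomes)}

    # site anchors: evenly spread with jitter; >= 5 kb apart and off the ends
    anchors: list[tuple[str, int]] = []
    per_chrom = int(np.ceil(n_sites / n_chromosomes))
    for chrom in chrom_sizes:
        usable = chromosome_bp - 20_000
        step = usable // (per_chrom + 1)
        for j in range(per_chrom):
            if len(anchors) < n_sites:
                jitter = int(rng.integers(-step // 4, step // 4 + 1))
                anchors.append((chrom, 10_000 + (j + 1) * step + jitter))
    rng.shuffle(anchors)

    roles: list[tuple[str, tuple[str, ...]]] = []
    roles += [("c", tissues)] * n_shared_sites
    for _ in range(n_frequent_sites):
        members = tuple(sorted(rng.choice(tissues, size=frequent_tissue_count,
                                          replace=False)))
        roles.append(("frequent", members))
    for t in tissues:
        roles += [("t", (t,))] * n_specific_sites_per_tissue
    roles += [("inert", ())] * n_inert_sites

    cpg_parts: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}
    site_rows = []
    for (chrom, anchor), (kind, members) in zip(anchors, roles):
        n_cpg = int(rng.integers(island_cpgs[0], island_cpgs[1] + 1))
        gaps = rng.integers(max(2, island_spacing_bp // 2),
                            island_spacing_bp * 2, size=n_cpg - 1)
        pos = anchor + np.concatenate([[0], np.cumsum(gaps)])
        cpg_parts[chrom].append(pos)
        site_rows.append((chrom, int(pos[0]), int(pos[-1]) + 2, kind, members,
                          n_cpg))
    sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end", "kind",
                                             "members", "n_cpg"])

    # sparse background CpGs
    for chrom, size in chrom_sizes.items():
        gaps = rng.geometric(1.0 / background_spacing_bp,
                             size=int(2.2 * size / background_spacing_bp))
        pos = np.cumsum(gaps)
        cpg_parts[chrom].append(pos[pos < size - 2])
    cpg_positions = {c: np.unique(np.concatenate(parts))
                     for c, parts in cpg_parts.items()}

    hmrs_by_tissue: dict[str, IntervalSet] = {}
    for t in tissues:
        mask = np.array([t in m for m in sites["members"]], dtype=bool)
        hmrs_by_tissue[t] = IntervalSet(sites.loc[mask, ["chrom", "start", "end"]])
    c_set = IntervalSet(sites.loc[sites["kind"] == "c", ["chrom", "start", "end"]])
    freq_set = IntervalSet(
        sites.loc[sites["kind"] == "frequent", ["chrom", "start", "end"]])
    t_sets = {t: IntervalSet(sites.loc[
        (sites["kind"] == "t")
        & np.array([m == (t,) for m in sites["members"]], dtype=bool),
        ["chrom", "start", "end"]]) for t in tissues}

    promoters = sites[["chrom", "start", "end", "kind"]].copy()
    centers = (promoters["start"] + promoters["end"]) // 2
    promoters["gene"] = [f"gene{i:04d}" for i in range(len(promoters))]
    promoters["start"] = np.maximum(centers - promoter_halfwidth_bp, 0)
    promoters["end"] = centers + promoter_halfwidth_bp
    promoters["tissue"] = [m[0] if k == "t" else ""
                           for k, m in zip(sites["kind"], sites["members"])]
    return GenomeDesign(chrom_sizes, cpg_positions, tuple(tissues),
                        hmrs_by_tissue, c_set, freq_set, t_sets,
                        promoters[["gene", "chrom", "start", "end", "kind",
                                   "tissue"]])


def _true_levels(design: GenomeDesign, chrom: str, hypo: IntervalSet,
                 rng: np.random.Generator) -> np.ndarray:
    pos = design.cpg_positions[chrom]
    a_bg, b_bg = design.background_beta
    a_h, b_h = design.hmr_beta
    levels = rng.beta(a_bg, b_bg, size=len(pos))
    mask = np.zeros(len(pos), dtype=bool)
    sub = hypo.df[hypo.df["chrom"] == chrom]
    for start, end in zip(sub["start"], sub["end"]):
        a = np.searchsorted(pos, start, side="left")
        b = np.searchsorted(pos, end, side="left")
        mask[a:b] = True
    levels[mask] = rng.beta(a_h, b_h, size=int(mask.sum()))
    return levels


def _sample_reads(levels: np.ndarray, coverage_mean: float,
                  rng: np.random.Generator):
    depth = rng.poisson(coverage_mean, size=len(levels))
    depth[depth == 0] = 1  # zero-coverage CpGs carry no level; floor at 1
    meth = rng.binomial(depth, levels)
    return meth, depth


def simulate_methylome(design: GenomeDesign, tissue: str,
                       coverage_mean: float = 15.0, seed: int = 0
                       ) -> tuple[MethylomeTable, IntervalSet]:
    """Simulate one normal methylome; returns (table, planted HMR truth)."""
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    if tissue not in design.tissues:
        raise KeyError(f"unknown tissue {tissue!r}")
    rng = _substream(seed, 0x11, design.tissues.index(tissue))
    truth = design.hmrs_by_tissue[tissue]
    frames = []
    for chrom in design.chrom_sizes:
        levels = _true_levels(design, chrom, truth, rng)
        meth, depth = _sample_reads(levels, coverage_mean, rng)
        frames.append(pd.DataFrame({"chrom": chrom,
                                    "pos": design.cpg_positions[chrom],
                                    "meth": meth, "total": depth}))
    table = MethylomeTable(pd.concat(frames, ignore_index=True),
                           sample_id=f"{tissue}_normal", tissue=tissue,
                           status="normal")
    return table, truth


def design_cancer(design: GenomeDesign, seed: int = 0, n_pmd_blocks: int = 4,
                  n_extra_pmd_blocks: int = 3,
                  pmd_size_bp: tuple[int, int] = (100_000, 250_000),
                  n_hyper_events: int = 6, primary_intensity: float = 0.6,
                  metastasis_intensity: float = 0.75) -> CancerDesign:
    """Plant cancer alterations: PMD blocks, focal hypermethylation of c-HMR
    sites, and stage-wise global shifts."""
    rng = _substream(seed, 0xCA)
    chroms = list(design.chrom_sizes)

    def random_blocks(n: int) -> IntervalSet:
        rows = []
        for _ in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = int(rng.integers(*pmd_size_bp))
            start = int(rng.integers(0, design.chrom_sizes[chrom] - size))
            rows.append((chrom, start, start + size))
        return IntervalSet.from_tuples(rows)

    c_df = design.c_hmrs.df
    pick = rng.choice(len(c_df), size=min(n_hyper_events, len(c_df)),
                      replace=False)
    events = c_df.iloc[sorted(pick)][["chrom", "start", "end"]].copy()
    events["primary_level"] = primary_intensity
    events["metastasis_level"] = metastasis_intensity
    return CancerDesign(random_blocks(n_pmd_blocks),
                        random_blocks(n_extra_pmd_blocks),
                        events.reset_index(drop=True))


def simulate_cancer_series(design: GenomeDesign, cancer: CancerDesign,
                           tissue: str | None = None, coverage_mean: float = 15.0,
                           seed: int = 0) -> dict[str, MethylomeTable]:
    """Simulate a donor-matched normal / primary / metastasis triplet.

    The metastasis inherits every primary alteration and adds extra PMD
    coverage, stronger hyper-event intensities and a larger global
    hypomethylation shift, so planted global means decrease strictly
    normal > primary > metastasis.
    """
    tissue = tissue or design.tissues[0]
    rng = _substream(seed, 0x5E)
    truth = design.hmrs_by_tissue[tissue]
    out: dict[str, MethylomeTable] = {}
    stage_specs = [
        ("normal", 0.0, IntervalSet(), None, "normal"),
        ("primary", cancer.global_shift_primary, cancer.pmd_blocks,
         "primary_level", "cancer_primary"),
        ("metastasis", cancer.global_shift_metastasis,
         _union(cancer.pmd_blocks, cancer.extra_pmd_blocks),
         "metastasis_level", "metastasis"),
    ]
    for stage, shift, pmds, level_col, status in stage_specs:
        frames = []
        for chrom in design.chrom_sizes:
            pos = design.cpg_positions[chrom]
            levels = _true_levels(design, chrom, truth, rng)
            bg = levels > 0.5
            levels[bg] = np.clip(levels[bg] - shift, 0.0, 1.0)
            for start, end in zip(*_chrom_cols(pmds, chrom)):
                a, b = np.searchsorted(pos, [start, end])
                block = cancer.pmd_level + rng.normal(
                    0.0, cancer.heterogeneity_sd, size=b - a)
                levels[a:b] = np.clip(block, 0.0, 1.0)
            if level_col is not None:
                for row in cancer.hyper_events.itertuples(index=False):
                    if row.chrom != chrom:
                        continue
                    a, b = np.searchsorted(pos, [row.start, row.end])
                    levels[a:b] = np.clip(
                        getattr(row, level_col)
                        + rng.normal(0.0, cancer.heterogeneity_sd, size=b - a),
                        0.0, 1.0)
            meth, depth = _sample_reads(levels, coverage_mean, rng)
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "meth": meth, "total": depth}))
        out[stage] = MethylomeTable(pd.concat(frames, ignore_index=True),
                                    sample_id=f"{tissue}_{stage}", tissue=tissue,
                                    status=status)
    return out


def _chrom_cols(ivs: IntervalSet, chrom: str):
    sub = ivs.df[ivs.df["chrom"] == chrom]
    return sub["start"].to_numpy(), sub["end"].to_numpy()


def simulate_beta_cohort(design: GenomeDesign, cancer_types=None,
                         n_samples_per_type: int = 25,
                         n_normal_samples: int = 24,
                         n_rare_events_per_type: int = 4,
                         n_signature_events_per_type: int = 3,
                         rare_event_frequency: float = 0.30,
                         signature_event_frequency: float = 0.90,
                         event_intensity: float = 0.6,
                         probes_per_hmr: tuple[int, int] = (2, 8),
                         noise_sd: float = 0.05, seed: int = 0):
    """Simulate an array-style cohort over the design's c-HMRs.

    Each cancer type receives disjoint planted event HMR sets: a few
    near-universal "signature" events (frequency 0.9 by default, the
    cancer-type fingerprint) and rarer events at the configured frequency.
    Event carriers are exact sample counts (``round(freq * n)``), so the
    recorded truth frequencies are exact.  Returns ``(BetaMatrix, truth)``
    where truth is a DataFrame of planted events.
    """
    from .cohort import BetaMatrix, hmr_id

    rng = _substream(seed, 0xB7)
    if cancer_types is None:
        cancer_types = [f"{t}_ca" for t in design.tissues[:4]]
    hmr_df = design.c_hmrs.df.reset_index(drop=True)
    ids = [hmr_id(r.chrom, r.start, r.end) for r in hmr_df.itertuples(index=False)]
    n_hmr = len(hmr_df)
    need = len(cancer_types) * (n_rare_events_per_type + n_signature_events_per_type)
    if need > n_hmr:
        raise ValueError(f"need {need} event HMRs but design has only {n_hmr} c-HMRs")

    # samples
    sample_ids, labels, groups = [], [], []
    for i in range(n_normal_samples):
        t = design.tissues[i % len(design.tissues)]
        sample_ids.append(f"N{i:03d}_{t}")
        labels.append(t)
        groups.append("normal")
    for ct in cancer_types:
        for i in range(n_samples_per_type):
            sample_ids.append(f"{ct}_{i:03d}")
            labels.append(ct)
            groups.append("cancer")
    meta = pd.DataFrame({"label": labels, "group": groups,
                         "solid": [g == "cancer" for g in groups]},
                        index=pd.Index(sample_ids, name="sample"))

    # per-HMR hypomethylated baseline; per-sample true HMR beta
    baseline = rng.uniform(0.05, 0.15, size=n_hmr)
    truth_beta = np.tile(baseline[:, None], (1, len(sample_ids)))

    # assign disjoint event HMRs per type; exact carrier counts
    order = rng.permutation(n_hmr)
    truth_rows = []
    cursor = 0
    cancer_cols = {ct: [j for j, lab in enumerate(labels) if lab == ct]
                   for ct in cancer_types}
    for ct in cancer_types:
        plan = ([(signature_event_frequency, True)] * n_signature_events_per_type
                + [(rare_event_frequency, False)] * n_rare_events_per_type)
        for freq, is_signature in plan:
            h = order[cursor]
            cursor += 1
            cols = cancer_cols[ct]
            k = int(round(freq * len(cols)))
            carriers = rng.choice(cols, size=k, replace=False)
            truth_beta[h, carriers] = event_intensity
            truth_rows.append((ids[h], ct, event_intensity, k / len(cols), k,
                               is_signature))
    truth = pd.DataFrame(truth_rows, columns=["hmr", "cancer_type", "intensity",
                                              "frequency", "n_carriers",
                                              "is_signature"])

    # probes: uniform positions inside each HMR
    probe_rows, betas = [], []
    for h, row in enumerate(hmr_df.itertuples(index=False)):
        k = int(rng.integers(probes_per_hmr[0], probes_per_hmr[1] + 1))
        offs = np.sort(rng.integers(0, max(row.end - row.start, 1), size=k))
        for j, off in enumerate(offs):
            probe_rows.append((f"cg_{h:05d}_{j}", row.chrom, row.start + int(off)))
            noise = rng.normal(0.0, noise_sd, size=len(sample_ids)) if noise_sd > 0 \
                else 0.0
            betas.append(np.clip(truth_beta[h] + noise, 0.0, 1.0))
    probe_coords = pd.DataFrame(probe_rows, columns=["probe", "chrom", "pos"]
                                ).set_index("probe")
    beta = pd.DataFrame(np.array(betas), index=probe_coords.index,
                        columns=meta.index)
    return BetaMatrix(beta, probe_coords, meta), truth


def simulate_alteration_matrix(n_genes: int = 20, n_samples: int = 50,
                               per_gene_rates=0.1, burden_multipliers=None,
                               exclusive_sets: dict | None = None,
                               seed: int = 0):
    """Simulate a binary gene x sample alteration matrix.

    Null mode: ``calls[g, s] ~ Bernoulli(rate_g * multiplier_s)`` (clamped
    to [0, 1]), independent across cells.  For genes in ``exclusive_sets``,
    altered samples are instead drawn disjointly within each set (weighted
    by the burden multipliers), with per-gene counts matching the null
    expectation.  Returns ``(AlterationMatrix, truth dict)``.
    """
    rng = _substream(seed, 0xA1)
    rates = np.broadcast_to(np.asarray(per_gene_rates, dtype=float), (n_genes,))
    if burden_multipliers is None:
        mult = np.ones(n_samples)
    else:
        mult = np.asarray(burden_multipliers, dtype=float)
    probs = np.clip(rates[:, None] * mult[None, :], 0.0, 1.0)
    calls = (rng.random((n_genes, n_samples)) < probs).astype(np.int8)

    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    truth = {"exclusive_sets": exclusive_sets or {}}
    if exclusive_sets:
        gene_index = {g: i for i, g in enumerate(genes)}
        for name, members in exclusive_sets.items():
            idxs = [gene_index[g] for g in members]
            ks = [int(round(rates[i] * mult.mean() * n_samples)) for i in idxs]
            if sum(ks) > n_samples:
                raise ValueError(f"exclusive set {name!r} demands "
                                 f"{sum(ks)} > {n_samples} samples")
            pool = np.arange(n_samples)
            w = mult.copy()
            for i, k in zip(idxs, ks):
                calls[i, :] = 0
                p = w[pool] / w[pool].sum()
                chosen = rng.choice(pool, size=k, replace=False, p=p)
                calls[i, chosen] = 1
                pool = np.setdiff1d(pool, chosen)
    matrix = AlterationMatrix(pd.DataFrame(calls, index=genes, columns=samples))
    return matrix, truth
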
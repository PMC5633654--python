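"""End-to-end reproducible pipeline runs.

A :class:`RunConfig` (validated pydantic model, round-trips through YAML)
drives the full synthetic-data pipeline: simulate -> segment -> catalog ->
dmr -> cohort -> mutex.  Every stage draws its randomness from a named
substream of the root seed, outputs are plain text (BED / TSV / JSON) and
a manifest records parameters, seeds and SHA-256 checksums of every file,
so identical config + seed reproduce byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .catalog import build_catalog
from .cohort import (call_hypermethylation_events, cluster_samples,
                     confirm_hypomethylated, hmr_beta_summary,
                     positive_selection_candidates, validate_catalog)
from .dmr import call_dmrs, global_stats
from .intervals import IntervalSet, write_bed
from .mutex import mutex_test
from .segmentation import segment_hmrs, summarize_segmentation
from .simulate import (design_cancer, design_genome, simulate_alteration_matrix,
                       simulate_beta_cohort, simulate_cancer_series,
                       simulate_methylome)
from .smoothing import smooth_profile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("segment", "catalog", "dmr", "cohort", "mutex")


class SimulateParams(BaseModel):
    n_chromosomes: int = Field(2, ge=1)
    chromosome_bp: int = Field(2_000_000, ge=100_000)
    n_tissues: int = Field(8, ge=2)
    coverage_mean: float = Field(15.0, ge=1.0)


class SegmentParams(BaseModel):
    min_cpgs: int = Field(10, ge=1)
    max_intra_gap_bp: int = Field(5000, ge=1)


class CatalogParams(BaseModel):
    merge_gap_bp: int = Field(100, ge=0)
    frequent_fraction: float = Field(0.5, ge=0.0, le=1.0)


class SmoothParams(BaseModel):
    min_window_bp: int = Field(1000, ge=1)
    min_cpgs: int = Field(20, ge=2)


class DmrParams(BaseModel):
    min_consecutive: int = Field(6, ge=1)


class CohortParams(BaseModel):
    intensity: float = Field(0.33, ge=0.0, le=1.0)
    frequency: float = Field(0.25, ge=0.0, le=1.0)
    confirm_max_beta: float = Field(0.30, ge=0.0, le=1.0)
    confirm_min_probes: int = Field(6, ge=1)
    candidate_intensity: float = Field(0.50, ge=0.0, le=1.0)
    candidate_min_freq: float = Field(0.01, ge=0.0, le=1.0)
    candidate_min_probes: int = Field(2, ge=1)
    dichotomize_at: float = Field(0.33, ge=0.0, le=1.0)
    n_cancer_types: int = Field(4, ge=1)
    n_samples_per_type: int = Field(25, ge=2)


class MutexParams(BaseModel):
    n_sims: int = Field(10_000, ge=100)


class RunConfig(BaseModel):
    """Validated parameters for one pipeline run."""

    seed: int = 0
    outdir: Path = Path("methmap_run")
    stages: tuple[str, ...] = STAGES
    simulate: SimulateParams = SimulateParams()
    segment: SegmentParams = SegmentParams()
    catalog: CatalogParams = CatalogParams()
    smooth: SmoothParams = SmoothParams()
    dmr: DmrParams = DmrParams()
    cohort: CohortParams = CohortParams()
    mutex: MutexParams = MutexParams()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        bad = set(v) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return tuple(v)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        data = json.loads(self.model_dump_json())
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage failure aborts with the stage name; the partial manifest written
    so far is preserved on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": json.loads(config.model_dump_json()),
                      "outputs": {}, "stages_completed": []}
    manifest_path = out / "manifest.json"

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path.relative_to(out)),
                                     "sha256": _sha256(path)}

    def flush() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    sim = config.simulate
    design = design_genome(seed=config.seed, n_chromosomes=sim.n_chromosomes,
                           chromosome_bp=sim.chromosome_bp,
                           tissues=tuple(f"tissue{i + 1}"
                                         for i in range(sim.n_tissues)))
    stage = "init"
    try:
        hmr_sets: dict[str, IntervalSet] = {}
        if "segment" in config.stages or "catalog" in config.stages:
            stage = "segment"
            seg_rows = []
            for tissue in design.tissues:
                table, _ = simulate_methylome(design, tissue,
                                              coverage_mean=sim.coverage_mean,
                                              seed=config.seed)
                hmrs = segment_hmrs(table, min_cpgs=config.segment.min_cpgs,
                                    max_intra_gap_bp=config.segment.max_intra_gap_bp,
                                    seed=config.seed)
                ivs = IntervalSet.from_tuples(
                    [(h.interval.chrom, h.interval.start, h.interval.end)
                     for h in hmrs])
                hmr_sets[tissue] = ivs
                path = out / f"hmrs_{tissue}.bed"
                write_bed(ivs, path)
                record(f"hmrs_{tissue}", path)
                summ = summarize_segmentation(hmrs, design.genome_bp)
                seg_rows.append((tissue, summ.n_hmrs, summ.coverage_bp,
                                 summ.coverage_pct, summ.mean_size_geometric))
            seg_df = pd.DataFrame(seg_rows, columns=[
                "tissue", "n_hmrs", "coverage_bp", "coverage_pct",
                "geometric_mean_bp"]).set_index("tissue")
            _write_tsv(seg_df, out / "segmentation_summary.tsv")
            record("segmentation_summary", out / "segmentation_summary.tsv")
            manifest["stages_completed"].append("segment")
            flush()

        if "catalog" in config.stages:
            stage = "catalog"
            cat = build_catalog(hmr_sets, merge_gap_bp=config.catalog.merge_gap_bp,
                                frequent_fraction=config.catalog.frequent_fraction)
            for name, ivs in [("c_hmrs", cat.c_hmrs),
                              ("frequent_hmrs", cat.frequent_hmrs)]:
                path = out / f"{name}.bed"
                write_bed(ivs, path)
                record(name, path)
            t_df = pd.concat([
                cat.t_hmrs[t].df.assign(tissue=t) for t in cat.tissues
            ], ignore_index=True)
            _write_tsv(t_df, out / "t_hmrs.tsv", index=False)
            record("t_hmrs", out / "t_hmrs.tsv")
            manifest["stages_completed"].append("catalog")
            flush()

        if "dmr" in config.stages:
            stage = "dmr"
            cancer = design_cancer(design, seed=config.seed)
            series = simulate_cancer_series(design, cancer,
                                            coverage_mean=sim.coverage_mean,
                                            seed=config.seed)
            profiles = {k: smooth_profile(v, config.smooth.min_window_bp,
                                          config.smooth.min_cpgs)
                        for k, v in series.items()}
            rows = []
            for a, b in [("primary", "normal"), ("metastasis", "normal"),
                         ("metastasis", "primary")]:
                for d in call_dmrs(profiles[a], profiles[b],
                                   config.dmr.min_consecutive):
                    rows.append((a, b, d.interval.chrom, d.interval.start,
                                 d.interval.end, d.direction, d.n_cpg,
                                 d.mean_delta))
            dmr_df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "chrom",
                                                 "start", "end", "direction",
                                                 "n_cpg", "mean_delta"])
            _write_tsv(dmr_df, out / "dmrs.tsv", index=False)
            record("dmrs", out / "dmrs.tsv")
            gs = global_stats(list(series.values()))
            (out / "global_stats.json").write_text(json.dumps({
                "mean_levels": gs.mean_levels,
                "fraction_sd_gt": gs.fraction_sd_gt,
                "n_sites": gs.n_sites}, indent=2, sort_keys=True))
            record("global_stats", out / "global_stats.json")
            manifest["stages_completed"].append("dmr")
            flush()

        if "cohort" in config.stages:
            stage = "cohort"
            co = config.cohort
            types = [f"{design.tissues[i % len(design.tissues)]}_ca{i + 1}"
                     for i in range(co.n_cancer_types)]
            betas, truth = simulate_beta_cohort(
                design, cancer_types=types,
                n_samples_per_type=co.n_samples_per_type, seed=config.seed)
            summary = hmr_beta_summary(design.c_hmrs, betas,
                                       min_probes=co.candidate_min_probes)
            confirmed = confirm_hypomethylated(
                summary, max_beta=co.confirm_max_beta,
                min_probes=co.confirm_min_probes)
            event_frames = []
            labels = summary.sample_meta["label"]
            for ct in types:
                members = list(labels.index[labels == ct])
                ev = call_hypermethylation_events(
                    summary, cancer_samples=members, intensity=co.intensity,
                    frequency=co.frequency)
                ev.insert(0, "cancer_type", ct)
                event_frames.append(ev)
            events = pd.concat(event_frames)
            _write_tsv(events, out / "events.tsv")
            record("events", out / "events.tsv")
            promoter_flags = pd.Series(True, index=summary.means.index)
            candidates = positive_selection_candidates(
                summary, promoter_flags, intensity=co.candidate_intensity,
                min_freq=co.candidate_min_freq,
                min_probes=co.candidate_min_probes, solid_only=True)
            (out / "candidates.txt").write_text("\n".join(candidates) + "\n")
            record("candidates", out / "candidates.txt")
            cr = cluster_samples(summary, dichotomize_at=co.dichotomize_at,
                                 samples=summary.group_samples("cancer"))
            (out / "dendrogram.nwk").write_text(cr.newick() + "\n")
            record("dendrogram", out / "dendrogram.nwk")
            (out / "confirmed_hmrs.txt").write_text("\n".join(confirmed) + "\n")
            record("confirmed_hmrs", out / "confirmed_hmrs.txt")
            manifest["stages_completed"].append("cohort")
            flush()

        if "mutex" in config.stages:
            stage = "mutex"
            matrix, _ = simulate_alteration_matrix(
                n_genes=20, n_samples=100, per_gene_rates=0.08,
                exclusive_sets={"planted": ["g000", "g001", "g002", "g003"]},
                seed=config.seed)
            results = {}
            for name, genes in [("planted", ["g000", "g001", "g002", "g003"]),
                                ("control", ["g010", "g011", "g012", "g013"])]:
                r = mutex_test(matrix, genes, n_sims=config.mutex.n_sims,
                               seed=config.seed)
                results[name] = {"observed_coverage": r.observed_coverage,
                                 "null_mean": r.null_mean, "null_sd": r.null_sd,
                                 "z_score": r.z_score,
                                 "empirical_p": r.empirical_p,
                                 "n_sims": r.n_sims}
            (out / "mutex.json").write_text(
                json.dumps(results, indent=2, sort_keys=True))
            record("mutex", out / "mutex.json")
            manifest["stages_completed"].append("mutex")
            flush()
    except Exception:
        flush()
        logger.error("pipeline aborted in stage %r", stage)
        raise

    config.to_yaml(out / "config.yaml")
    record("config", out / "config.yaml")
    flush()
    return manifest
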
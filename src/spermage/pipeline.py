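"""End-to-end orchestration: simulate -> preprocess -> scan -> annotate ->
reads -> enrichment, with a validated plain-text config, per-stage logging
and a machine-readable run report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import enrich as enr
from . import io as sio
from . import preprocess as pre
from . import reads as rd
from . import synthetic as syn
from .scan import scan as run_scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_all", "demo"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths and thresholds for one run. Unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "spermage_out"
    # inputs; empty string means "generate synthetically"
    manifest: str = ""
    betas: str = ""
    samples: str = ""
    islands: str = ""
    nucleosome: str = ""
    h3k4me: str = ""
    h3k27me: str = ""
    genes: str = ""
    reads_table: str = ""
    associations: str = ""
    global_methylation: str = ""
    # scanner thresholds
    window_size: int = 1000
    min_probes: int = 3
    q_max: float = 1e-4
    min_abs_log2: float = 0.2
    regression_alpha: float = 0.05
    # annotation margins
    colocalization_margin: int = 1000
    shore_flank: int = 2000
    promoter_window: int = 1000
    cluster_window: int = 100_000
    cluster_min_marks: int = 2
    cluster_permutations: int = 200
    # read analysis
    age_cutoff: float = 45.0
    min_read_fraction: float = 0.10
    # enrichment
    min_disease_genes: int = 2
    # synthetic generation scale (used when inputs are not provided)
    n_candidate_windows: int = 500
    n_probes: int = 5000
    planted_hypo: int = 20
    planted_hyper: int = 4
    min_abs_log2_effect: float = 0.4
    min_planted_diff: float = 0.035

    def __post_init__(self) -> None:
        for name in (
            "window_size",
            "min_probes",
            "q_max",
            "min_abs_log2",
            "regression_alpha",
            "colocalization_margin",
            "shore_flank",
            "promoter_window",
            "age_cutoff",
            "min_read_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config value {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str, report: dict):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report["failed_stage"] = name
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run report dictionary.

    Partial outputs are preserved on failure; the raised StageError names
    the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config)}

    fixture = None
    with _stage("inputs", report):
        if config.manifest and config.betas and config.samples:
            manifest = sio.read_manifest(config.manifest)
            betas = sio.read_betas(config.betas)
            samples = sio.read_samples(config.samples)
            tracks = {}
            for name in ("islands", "nucleosome", "h3k4me", "h3k27me"):
                path = getattr(config, name)
                if path:
                    tracks["cpg_islands" if name == "islands" else name] = sio.read_bed(path)
            genes = sio.read_genes(config.genes) if config.genes else pd.DataFrame(
                columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
            )
            reads_df = sio.read_reads(config.reads_table) if config.reads_table else None
            assoc_df = (
                sio.read_associations(config.associations) if config.associations else None
            )
            global_df = (
                sio.read_global(config.global_methylation)
                if config.global_methylation
                else None
            )
            chrom_lengths = {
                c: int(grp["pos"].max()) + config.window_size
                for c, grp in manifest.groupby("chrom")
            }
        elif config.manifest or config.betas or config.samples:
            raise FileNotFoundError(
                "manifest, betas and samples must all be provided together"
            )
        else:
            scfg = syn.SyntheticConfig(
                seed=config.seed,
                n_candidate_windows=config.n_candidate_windows,
                n_probes=config.n_probes,
                planted_hypo=config.planted_hypo,
                planted_hyper=config.planted_hyper,
                min_abs_log2_effect=config.min_abs_log2_effect,
                min_planted_diff=config.min_planted_diff,
            )
            fixture = syn.generate_fixture(scfg)
            syn.write_fixture(fixture, out / "inputs")
            manifest = fixture.probes[syn.MANIFEST_COLUMNS]
            betas, samples = fixture.betas, fixture.samples
            tracks, genes = fixture.tracks, fixture.genes
            reads_df, assoc_df = fixture.reads, fixture.associations
            global_df = fixture.global_methylation
            chrom_lengths = syn.chromosome_lengths(scfg)
            report["synthetic_truth_regions"] = len(fixture.truth)

    with _stage("preprocess", report):
        values = betas.to_numpy(float)
        if ((values < 0) | (values > 1)).any():
            raise ValueError("beta matrix contains values outside [0, 1]")
        report["n_probes"] = int(betas.shape[0])
        report["n_samples"] = int(betas.shape[1])
        if global_df is not None:
            trend = pre.global_trend(global_df)
            report["global_trend"] = dataclasses.asdict(trend)

    with _stage("scan", report):
        result = run_scan(
            manifest,
            betas,
            samples,
            window_size=config.window_size,
            min_probes=config.min_probes,
            q_max=config.q_max,
            min_abs_log2=config.min_abs_log2,
            regression_alpha=config.regression_alpha,
        )
        report["scan"] = result.counts
        result.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
        sio.write_bed(
            result.windows.assign(score=result.windows["fdr_transformed"].round(2)),
            out / "windows.bed",
            extra=[
                "pm_young",
                "pm_aged",
                "log2_ratio",
                "q_bh",
                "fdr_transformed",
                "slope_pct_per_year",
                "t_paired_p",
                "direction",
            ],
        )
        regions = result.regions
        regions.to_csv(out / "regions.tsv", sep="\t", index=False)
        sio.write_bed(regions, out / "regions.bed", extra=["direction", "best_q", "mean_log2"])

    with _stage("annotate", report):
        hit_genes: set[str] = set()
        if len(regions):
            islands = tracks.get("cpg_islands", pd.DataFrame(columns=sio.BED_COLUMNS))
            regions = regions.copy()
            regions["island_context"] = ann.classify_regions(
                regions, islands, shore_flank=config.shore_flank
            )
            gene_hits = ann.annotate_regions_genes(
                regions, genes, promoter_window=config.promoter_window
            )
            hit_genes = set(gene_hits["gene_id"])
            gene_hits.to_csv(out / "region_genes.tsv", sep="\t", index=False)
            coloc_rows = []
            for name in ("nucleosome", "h3k4me", "h3k27me"):
                track = tracks.get(name)
                if track is None:
                    continue
                flags, res = ann.colocalize(
                    regions, track, margin=config.colocalization_margin, track_name=name
                )
                regions[f"near_{name}"] = flags
                if res is not None:
                    coloc_rows.append(
                        {
                            "track": name,
                            "hypo_near": int(res.table[0, 0]),
                            "hypo_far": int(res.table[0, 1]),
                            "hyper_near": int(res.table[1, 0]),
                            "hyper_far": int(res.table[1, 1]),
                            "fisher_p": res.fisher_p,
                        }
                    )
            pd.DataFrame(coloc_rows).to_csv(out / "colocalization.tsv", sep="\t", index=False)
            clusters = ann.chromosomal_clusters(
                regions,
                chrom_lengths,
                window=config.cluster_window,
                min_marks=config.cluster_min_marks,
                n_permutations=config.cluster_permutations,
                seed=config.seed,
            )
            clusters.to_csv(out / "chromosomal_clusters.tsv", sep="\t", index=False)
            regions.to_csv(out / "regions_annotated.tsv", sep="\t", index=False)
            report["annotate"] = {
                "regions": len(regions),
                "gene_hits": len(hit_genes),
                "clusters": len(clusters),
            }

    with _stage("reads", report):
        if reads_df is not None and len(reads_df):
            profiles = rd.pool_and_normalize(
                reads_df,
                samples,
                age_cutoff=config.age_cutoff,
                min_fraction=config.min_read_fraction,
            )
            rd.profiles_frame(profiles).to_csv(out / "read_profiles.tsv", sep="\t", index=False)
            rd.plot_profiles(profiles, out / "read_profiles.png")
            report["reads"] = {"profiles": len(profiles)}

    with _stage("enrichment", report):
        if assoc_df is not None and len(assoc_df) and hit_genes:
            table = enr.load_associations(assoc_df)
            results = enr.run_enrichment(
                hit_genes, table, min_genes=config.min_disease_genes
            )
            results.to_csv(out / "disease_enrichment.tsv", sep="\t", index=False)
            report["enrichment"] = {
                "diseases_tested": len(results),
                "bonferroni_significant": int((results.get("p_bonferroni", pd.Series(dtype=float)) < 0.05).sum())
                if len(results)
                else 0,
            }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def demo(seed: int = 7, out_dir: str | Path = "spermage_demo") -> dict:
    """One-command end-to-end run on a small generated fixture."""
    return run_all(PipelineConfig(seed=seed, out_dir=str(out_dir)))
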
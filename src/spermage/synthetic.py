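"""Seeded synthetic inputs for the paired sperm-methylome aging pipeline.

Emulates the statistical structure of a paired 450K-style methylation study:
17 donors sampled twice 9-19 years apart, ~10,000 candidate 1000-bp windows
tiled with probe clusters, a subset of windows carrying a consistent linear
per-year methylation drift (hypo- or hypermethylation with age), plus the
side tables the downstream stages consume — CpG-island / nucleosome /
histone-mark interval tracks, gene models, targeted-amplicon read
populations, a gene-disease association table with one planted enrichment,
and per-sample global (LINE-1-style) methylation values.

Everything is driven by one master seed; per-artifact RNG streams are
derived deterministically so identical configs produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ConfigurationError",
    "Fixture",
    "recovery_config",
    "generate_manifest",
    "generate_paired_betas",
    "generate_read_table",
    "generate_disease_table",
    "generate_global_table",
    "generate_fixture",
    "sample_donors",
    "write_fixture",
    "REFERENCE_COHORT",
    "cohort_age_gap",
]

# Demographic envelope of the reference paired-donor cohort (mean age in
# years with SEM per collection group). The simulator's age defaults are
# drawn from the same envelope.
REFERENCE_COHORT = pd.DataFrame(
    {
        "group": ["young", "aged"],
        "mean_age": [37.7, 50.3],
        "sem_age": [2.12, 2.1],
    }
)


def cohort_age_gap(cohort: pd.DataFrame = REFERENCE_COHORT) -> float:
    """Mean collection-age gap (aged minus young group mean), in years."""
    by_group = cohort.set_index("group")["mean_age"]
    return float(by_group["aged"] - by_group["young"])


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig cannot be realised (impossible placement)."""


# RNG stream tags; fixed so adding artifacts never perturbs existing streams.
_STREAMS = {
    "manifest": 0,
    "donors": 1,
    "betas": 2,
    "reads": 3,
    "disease": 4,
    "global": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs for the synthetic study, with the cohort envelope as defaults.

    The defaults emulate the reference study: 17 paired donors, young-sample
    ages 23-56 y, collection intervals 9-19 y, 139 planted hypomethylation and
    8 hypermethylation windows of >=3 probes each, per-year drift between
    0.08% and 0.95% fraction methylation, probe noise SD 0.02, and planted
    baselines below 0.6.
    """

    seed: int = 0
    n_donors: int = 17
    age_young_range: tuple[float, float] = (23.0, 56.0)
    interval_range: tuple[float, float] = (9.0, 19.0)
    n_probes: int = 100_000
    n_candidate_windows: int = 10_000
    planted_hypo: int = 139
    planted_hyper: int = 8
    probes_per_planted_window: int = 5
    drift_per_year: tuple[float, float] = (0.0008, 0.0095)
    noise_sd: float = 0.02
    baseline_range: tuple[float, float] = (0.2, 0.6)
    # Hypermethylating windows start low (they stay below ~0.1-0.4 even aged).
    hyper_baseline_range: tuple[float, float] = (0.05, 0.4)
    #: When set, the sampled |drift| of every planted window is floored at the
    #: magnitude needed for the group log2 ratio to reach this value at the
    #: mean collection interval (used by the recovery study conditions).
    min_abs_log2_effect: float | None = None
    #: When set, additionally floors the absolute beta change at the mean
    #: collection interval, so low-baseline windows stay resolvable above the
    #: probe noise (the cohort's average significant-window change is ~0.03).
    min_planted_diff: float | None = None
    donor_sd: float = 0.005
    noise_model: str = "gaussian"  # or "beta" (moment-matched Beta noise)

    # genome geometry
    window_size: int = 1000
    cluster_span: int = 600
    cluster_pitch: int = 6000
    n_chroms: int = 20
    chrom_margin: int = 10_000

    # annotation tracks: fraction of windows placed near each feature
    island_frac: float = 0.2
    shore_frac: float = 0.3
    nucleosome_hypo_frac: float = 0.88
    nucleosome_hyper_frac: float = 0.375
    h3k4_hypo_frac: float = 0.23
    h3k27_hypo_frac: float = 0.45
    histone_hyper_frac: float = 0.05
    track_background_frac: float = 0.3
    gene_frac: float = 0.8

    # amplicon read populations
    n_amplicons: int = 3
    reads_per_sample: int = 120
    amplicon_cpgs: int = 8
    beta_concentration: float = 30.0
    minority_read_frac: float = 0.05

    # disease association table
    n_genes: int = 2000
    n_diseases: int = 12
    association_rate: float = 0.1
    disease_enrichment_factor: float = 10.0

    # global (LINE-1-style) methylation
    global_drift_per_year: float = 0.002
    global_intercept: float = 0.72
    global_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.planted_hypo + self.planted_hyper > self.n_candidate_windows:
            raise ConfigurationError(
                "planted_hypo + planted_hyper exceeds n_candidate_windows"
            )
        if self.probes_per_planted_window < 3:
            raise ConfigurationError("probes_per_planted_window must be >= 3")
        if self.cluster_span >= self.window_size:
            raise ConfigurationError("cluster_span must be smaller than window_size")
        if self.n_probes < self.n_candidate_windows * self.probes_per_planted_window:
            raise ConfigurationError("n_probes too small to tile the candidate windows")

    @property
    def n_planted(self) -> int:
        return self.planted_hypo + self.planted_hyper


def recovery_config(seed: int, **overrides) -> SyntheticConfig:
    """Study conditions for the planted-region recovery experiment.

    Defaults plus floors on the planted effect so every planted window shows
    a group |log2 ratio| of at least ~0.3 at the aged timepoint and an
    absolute beta change comfortably above the probe noise (the cohort's
    reported average change at significant windows is 0.032-0.039).
    """
    overrides.setdefault("min_abs_log2_effect", 0.4)
    overrides.setdefault("min_planted_diff", 0.035)
    return SyntheticConfig(seed=seed, **overrides)


@dataclass
class Fixture:
    """Bundle of every synthetic input artifact for one config."""

    config: SyntheticConfig
    probes: pd.DataFrame
    clusters: pd.DataFrame
    truth: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    samples: pd.DataFrame
    betas: pd.DataFrame
    reads: pd.DataFrame
    associations: pd.DataFrame
    global_methylation: pd.DataFrame


# ---------------------------------------------------------------------------
# manifest: probe tiling, truth windows, tracks and gene models
# ---------------------------------------------------------------------------

def _cluster_layout(config: SyntheticConfig) -> pd.DataFrame:
    """Place candidate-window probe clusters on a multi-chromosome grid."""
    n = config.n_candidate_windows
    per_chrom = math.ceil(n / config.n_chroms)
    idx = np.arange(n)
    chrom_idx = idx // per_chrom
    within = idx % per_chrom
    start = config.chrom_margin + within * config.cluster_pitch
    return pd.DataFrame(
        {
            "cluster_id": idx,
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "start": start,
            "end": start + config.cluster_span,
        }
    )


def chromosome_lengths(config: SyntheticConfig) -> dict[str, int]:
    """Declared chromosome sizes for the synthetic genome."""
    per_chrom = math.ceil(config.n_candidate_windows / config.n_chroms)
    length = 2 * config.chrom_margin + per_chrom * config.cluster_pitch
    n_used = math.ceil(config.n_candidate_windows / per_chrom)
    return {f"chr{c + 1}": length for c in range(n_used)}


def _place_background(config: SyntheticConfig, clusters: pd.DataFrame) -> pd.DataFrame:
    """Scatter filler probes between clusters, never >2 per 1000-bp window."""
    n_bg = config.n_probes - config.n_candidate_windows * config.probes_per_planted_window
    if n_bg <= 0:
        return pd.DataFrame({"chrom": [], "pos0": []})
    per_gap = math.ceil(n_bg / config.n_candidate_windows)
    zone_start = config.cluster_span + config.window_size + 1
    zone_end = config.cluster_pitch - config.window_size - 1
    zone_width = zone_end - zone_start
    if zone_width < 0 or (per_gap > 1 and zone_width / (per_gap - 1) < 502):
        raise ConfigurationError(
            "impossible placement: too many background probes per inter-window gap"
        )
    if per_gap == 1:
        offsets = np.array([zone_start + zone_width // 2])
    else:
        offsets = np.round(np.linspace(zone_start, zone_end, per_gap)).astype(int)
    rows_chrom = np.repeat(clusters["chrom"].to_numpy(), per_gap)
    rows_pos = (
        np.repeat(clusters["start"].to_numpy(), per_gap)
        + np.tile(offsets, len(clusters))
    )
    return pd.DataFrame({"chrom": rows_chrom, "pos0": rows_pos}).iloc[:n_bg]


def generate_manifest(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Build the probe manifest plus truth windows, tracks and gene models.

    Returns ``(probes, clusters, truth, tracks, genes)``. ``probes`` carries
    the external manifest columns (probe_id, chrom, pos, island_context,
    gene_id, gene_feature) plus an internal ``cluster_id`` (-1 = background).
    ``truth`` is the planted-region ground truth (BED-style, half-open) with
    direction and per-year drift.
    """
    rng = _rng(config.seed, "manifest")
    clusters = _cluster_layout(config)
    n = config.n_candidate_windows

    # planted directions
    direction = np.full(n, "none", dtype=object)
    planted = rng.choice(n, size=config.n_planted, replace=False)
    direction[planted[: config.planted_hypo]] = "hypo"
    direction[planted[config.planted_hypo:]] = "hyper"
    clusters["direction"] = direction

    # baselines: hyper windows start low, everything else in baseline_range
    lo, hi = config.baseline_range
    base = rng.uniform(lo, hi, size=n)
    hlo, hhi = config.hyper_baseline_range
    is_hyper = direction == "hyper"
    base[is_hyper] = rng.uniform(hlo, hhi, size=int(is_hyper.sum()))
    clusters["baseline"] = base

    # per-year drift for planted windows
    dlo, dhi = config.drift_per_year
    drift = np.zeros(n)
    is_planted = direction != "none"
    mag = rng.uniform(dlo, dhi, size=int(is_planted.sum()))
    mean_interval = float(np.mean(config.interval_range))
    if config.min_abs_log2_effect is not None:
        target = config.min_abs_log2_effect
        b = base[is_planted]
        hyp = direction[is_planted] == "hyper"
        needed = np.where(
            hyp,
            b * (2.0 ** target - 1.0) / mean_interval,
            b * (1.0 - 2.0 ** -target) / mean_interval,
        )
        mag = np.maximum(mag, needed)
    if config.min_planted_diff is not None:
        mag = np.maximum(mag, config.min_planted_diff / mean_interval)
    sign = np.where(direction[is_planted] == "hyper", 1.0, -1.0)
    drift[is_planted] = sign * mag
    clusters["drift"] = drift

    # probes: evenly spaced across each cluster span
    ppw = config.probes_per_planted_window
    # strictly inside the half-open [start, start + span) window extent
    offsets = np.round(np.linspace(0, config.cluster_span - 1, ppw)).astype(int)
    cl_probes = pd.DataFrame(
        {
            "chrom": np.repeat(clusters["chrom"].to_numpy(), ppw),
            "pos0": np.repeat(clusters["start"].to_numpy(), ppw)
            + np.tile(offsets, n),
            "cluster_id": np.repeat(clusters["cluster_id"].to_numpy(), ppw),
        }
    )
    bg = _place_background(config, clusters)
    bg["cluster_id"] = -1
    probes = pd.concat([cl_probes, bg], ignore_index=True)
    probes = probes.sort_values(["chrom", "pos0"], kind="mergesort").reset_index(drop=True)
    probes["probe_id"] = [f"cg{i:08d}" for i in range(len(probes))]
    probes["pos"] = probes["pos0"] + 1  # manifest positions are 1-based

    # island / shore assignment per cluster
    ctx = np.full(n, "other", dtype=object)
    roll = rng.uniform(size=n)
    ctx[roll < config.island_frac] = "island"
    ctx[(roll >= config.island_frac) & (roll < config.island_frac + config.shore_frac)] = "shore"
    clusters["island_context"] = ctx
    islands = []
    for _, cl in clusters.iterrows():
        if cl["island_context"] == "island":
            islands.append((cl["chrom"], cl["start"] - 100, cl["end"] + 100))
        elif cl["island_context"] == "shore":
            islands.append((cl["chrom"], cl["end"] + 1000, cl["end"] + 1400))
    tracks: dict[str, pd.DataFrame] = {
        "cpg_islands": pd.DataFrame(islands, columns=["chrom", "start", "end"])
    }

    # chromatin tracks near a configured fraction of windows by direction
    def _chromatin(hypo_frac: float, hyper_frac: float, offset: int) -> pd.DataFrame:
        frac = np.where(
            direction == "hypo",
            hypo_frac,
            np.where(is_hyper, hyper_frac, config.track_background_frac),
        )
        hit = rng.uniform(size=n) < frac
        sub = clusters.loc[hit]
        return pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["start"].to_numpy() - offset,
                "end": sub["start"].to_numpy() - offset + 400,
            }
        )

    tracks["nucleosome"] = _chromatin(
        config.nucleosome_hypo_frac, config.nucleosome_hyper_frac, 800
    )
    tracks["h3k4me"] = _chromatin(config.h3k4_hypo_frac, config.histone_hyper_frac, 700)
    tracks["h3k27me"] = _chromatin(config.h3k27_hypo_frac, config.histone_hyper_frac, 600)
    for name, df in tracks.items():
        tracks[name] = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    # gene models: a fraction of windows sit at a promoter or inside a body
    gene_frac = np.where(is_planted, config.gene_frac, config.track_background_frac)
    has_gene = rng.uniform(size=n) < gene_frac
    promoter_like = rng.uniform(size=n) < 0.5
    gene_rows = []
    gene_of_cluster: dict[int, tuple[str, str]] = {}
    for cid in np.flatnonzero(has_gene):
        cl = clusters.iloc[cid]
        gid = f"GENE{cid:05d}"
        if promoter_like[cid]:
            tss = int(cl["start"] + config.cluster_span // 2)
            gene_rows.append((gid, cl["chrom"], "+", tss, tss, tss + 3000))
            gene_of_cluster[cid] = (gid, "promoter")
        else:
            start = int(cl["start"] - 2000)
            gene_rows.append((gid, cl["chrom"], "+", start, start, int(cl["end"] + 2000)))
            gene_of_cluster[cid] = (gid, "body")
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
    )

    probes["island_context"] = [
        clusters.at[cid, "island_context"] if cid >= 0 else "other"
        for cid in probes["cluster_id"]
    ]
    probes["gene_id"] = [
        gene_of_cluster.get(cid, ("", ""))[0] for cid in probes["cluster_id"]
    ]
    probes["gene_feature"] = [
        gene_of_cluster.get(cid, ("", ""))[1] for cid in probes["cluster_id"]
    ]

    truth = clusters.loc[is_planted, ["chrom", "start", "end", "direction", "drift"]]
    truth = truth.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return probes, clusters, truth, tracks, genes


# ---------------------------------------------------------------------------
# paired beta matrix
# ---------------------------------------------------------------------------

def sample_donors(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the donor cohort: 2 samples per donor, ages differing by 9-19 y."""
    rng = _rng(config.seed, "donors")
    young = rng.uniform(*config.age_young_range, size=config.n_donors)
    interval = rng.uniform(*config.interval_range, size=config.n_donors)
    rows = []
    for d in range(config.n_donors):
        donor = f"d{d + 1:02d}"
        rows.append((f"{donor}_young", donor, round(float(young[d]), 1), "young"))
        rows.append((f"{donor}_aged", donor, round(float(young[d] + interval[d]), 1), "aged"))
    return pd.DataFrame(rows, columns=["sample_id", "donor_id", "age", "group"])


def generate_paired_betas(
    config: SyntheticConfig,
    probes: pd.DataFrame,
    clusters: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the probes x samples beta matrix with planted linear drift.

    beta(p, s) = clamp(base_p + donor_offset + drift_w * (age_s - mean young
    age) + noise), where drift_w is nonzero only inside planted windows.
    Returns ``(betas, samples)`` with betas indexed by probe_id.
    """
    if samples is None:
        samples = sample_donors(config)
    rng = _rng(config.seed, "betas")
    n_p, n_s = len(probes), len(samples)
    ages = samples["age"].to_numpy(float)
    age_anchor = ages[samples["group"].to_numpy() == "young"].mean()

    cid = probes["cluster_id"].to_numpy()
    in_cluster = cid >= 0
    base = rng.uniform(0.1, 0.9, size=n_p)
    base[in_cluster] = clusters["baseline"].to_numpy()[cid[in_cluster]] + rng.normal(
        0.0, 0.01, size=int(in_cluster.sum())
    )
    drift = np.zeros(n_p)
    drift[in_cluster] = clusters["drift"].to_numpy()[cid[in_cluster]]

    donor_offset = rng.normal(0.0, config.donor_sd, size=config.n_donors)
    offset_by_sample = donor_offset[
        samples["donor_id"].str.slice(1).astype(int).to_numpy() - 1
    ]

    mean = (
        base[:, None]
        + offset_by_sample[None, :]
        + drift[:, None] * (ages - age_anchor)[None, :]
    )
    if config.noise_model == "beta":
        mu = np.clip(mean, 1e-3, 1 - 1e-3)
        # moment-matched Beta noise with per-probe variance ~= noise_sd^2
        var = min(config.noise_sd, 0.1) ** 2
        kappa = np.maximum(mu * (1 - mu) / var - 1.0, 0.5)
        values = rng.beta(mu * kappa, (1 - mu) * kappa)
    else:
        values = mean + rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
    values = np.clip(values, 0.0, 1.0)
    betas = pd.DataFrame(values, index=probes["probe_id"], columns=samples["sample_id"])
    betas.index.name = "probe_id"
    return betas, samples


# ---------------------------------------------------------------------------
# amplicon read populations
# ---------------------------------------------------------------------------

# (young_components, aged_components): lists of (weight, mean methylation).
# The three default amplicons emulate the three observed population shifts:
# low -> lower, single shifted population, bimodal -> single population.
_DEFAULT_PATTERNS = [
    ([(1.0, 0.15)], [(1.0, 0.07)]),
    ([(1.0, 0.55)], [(1.0, 0.30)]),
    ([(0.5, 0.15), (0.5, 0.85)], [(1.0, 0.15)]),
]


def generate_read_table(
    config: SyntheticConfig,
    samples: pd.DataFrame | None = None,
    patterns: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read CpG call table for targeted amplicons in both age groups.

    Reads are drawn from beta-binomial mixtures whose components differ
    between young (<45 y) and aged (>=45 y) samples. A minority of reads get
    one extra CpG to exercise the 10% consensus rule downstream.
    """
    if samples is None:
        samples = sample_donors(config)
    if patterns is None:
        patterns = [
            _DEFAULT_PATTERNS[i % len(_DEFAULT_PATTERNS)] for i in range(config.n_amplicons)
        ]
    rng = _rng(config.seed, "reads")
    kappa = config.beta_concentration
    rows: list[tuple[str, str, str, str]] = []
    for a in range(config.n_amplicons):
        young_mix, aged_mix = patterns[a]
        amplicon = f"amp{a + 1:02d}"
        for _, s in samples.iterrows():
            mix = aged_mix if s["age"] >= 45 else young_mix
            weights = np.array([w for w, _ in mix], float)
            weights /= weights.sum()
            means = np.array([m for _, m in mix], float)
            comp = rng.choice(len(mix), size=config.reads_per_sample, p=weights)
            extra = rng.uniform(size=config.reads_per_sample) < config.minority_read_frac
            for r in range(config.reads_per_sample):
                c = config.amplicon_cpgs + (1 if extra[r] else 0)
                mu = float(means[comp[r]])
                if mu <= 0.0:
                    p = 0.0
                elif mu >= 1.0:
                    p = 1.0
                else:
                    p = rng.beta(mu * kappa, (1 - mu) * kappa)
                calls = rng.uniform(size=c) < p
                rows.append(
                    (
                        amplicon,
                        s["sample_id"],
                        f"{amplicon}_{s['sample_id']}_r{r:04d}",
                        "".join("M" if m else "U" for m in calls),
                    )
                )
    reads = pd.DataFrame(rows, columns=["amplicon_id", "sample_id", "read_id", "call_string"])
    return reads, samples


# ---------------------------------------------------------------------------
# disease associations and global methylation
# ---------------------------------------------------------------------------

def generate_disease_table(
    config: SyntheticConfig,
    gene_universe: list[str] | None = None,
    hit_genes: set[str] | None = None,
    enrichment_factor: float | None = None,
) -> pd.DataFrame:
    """Long-form gene->disease table with one planted enriched disease.

    Association is Bernoulli(rate) everywhere except disease_01 among
    ``hit_genes``, whose rate is multiplied by the enrichment factor.
    """
    rng = _rng(config.seed, "disease")
    if gene_universe is None:
        gene_universe = [f"GENE{i:05d}" for i in range(config.n_genes)]
    if enrichment_factor is None:
        enrichment_factor = config.disease_enrichment_factor
    hit_genes = hit_genes or set()
    diseases = [f"disease_{d + 1:02d}" for d in range(config.n_diseases)]
    rows = []
    for gene in gene_universe:
        for d, disease in enumerate(diseases):
            rate = config.association_rate
            if d == 0 and gene in hit_genes:
                rate = min(1.0, rate * enrichment_factor)
            if rng.uniform() < rate:
                rows.append((gene, disease))
    return pd.DataFrame(rows, columns=["gene_id", "disease"])


def generate_global_table(
    config: SyntheticConfig, samples: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample global methylation with a planted linear age trend."""
    if samples is None:
        samples = sample_donors(config)
    rng = _rng(config.seed, "global")
    ages = samples["age"].to_numpy(float)
    value = (
        config.global_intercept
        + config.global_drift_per_year * (ages - 40.0)
        + rng.normal(0.0, config.global_noise_sd, size=len(samples))
    )
    out = samples[["sample_id", "donor_id", "age"]].copy()
    out["mean_fraction"] = np.clip(value, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# bundle + writers
# ---------------------------------------------------------------------------

def generate_fixture(config: SyntheticConfig) -> Fixture:
    """Generate every pipeline input for one seeded configuration."""
    probes, clusters, truth, tracks, genes = generate_manifest(config)
    samples = sample_donors(config)
    betas, _ = generate_paired_betas(config, probes, clusters, samples)
    reads, _ = generate_read_table(config, samples)
    universe = sorted(set(genes["gene_id"])) + [
        f"FILL{i:05d}" for i in range(max(0, config.n_genes - len(genes)))
    ]
    planted_hits = set(
        probes.loc[
            probes["cluster_id"].isin(
                clusters.loc[clusters["direction"] != "none", "cluster_id"]
            ),
            "gene_id",
        ]
    ) - {""}
    associations = generate_disease_table(config, universe, planted_hits)
    global_meth = generate_global_table(config, samples)
    return Fixture(
        config=config,
        probes=probes,
        clusters=clusters,
        truth=truth,
        tracks=tracks,
        genes=genes,
        samples=samples,
        betas=betas,
        reads=reads,
        associations=associations,
        global_methylation=global_meth,
    )


MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "island_context", "gene_id", "gene_feature"]


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact in its external tab-delimited / BED form."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=kw.pop("index", False), **kw)
        paths[name] = p

    _tsv("manifest.tsv", fixture.probes[MANIFEST_COLUMNS])
    _tsv("betas.tsv", fixture.betas.round(6), index=True)
    _tsv("samples.tsv", fixture.samples)
    _tsv("genes.tsv", fixture.genes)
    _tsv("reads.tsv", fixture.reads)
    _tsv("disease_associations.tsv", fixture.associations)
    _tsv("global_methylation.tsv", fixture.global_methylation.round(6))
    truth = fixture.truth.copy()
    truth["drift"] = truth["drift"].round(8)
    p = out / "truth.bed"
    truth.to_csv(p, sep="\t", index=False, header=False)
    paths["truth.bed"] = p
    (out / "tracks").mkdir(exist_ok=True)
    for name, df in fixture.tracks.items():
        p = out / "tracks" / f"{name}.bed"
        df.to_csv(p, sep="\t", index=False, header=False)
        paths[f"tracks/{name}.bed"] = p
    return paths
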
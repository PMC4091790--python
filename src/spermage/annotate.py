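"""Genomic annotation and co-localization of differentially methylated regions.

Classifies regions by CpG-island context (island / shore / other, with a
+-2 kb shore flank), attaches gene features (promoter vs body), tests
co-localization with chromatin interval tracks (nucleosome retention,
H3K4me, H3K27me) within a 1-kb margin using Fisher's exact test on the
hypo-vs-hyper 2x2 table, and calls 100-kb chromosomal clusters of altered
regions against a seeded uniform-permutation background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "build_trees",
    "classify_island_context",
    "classify_regions",
    "annotate_genes",
    "annotate_regions_genes",
    "colocalize",
    "ColocalizationResult",
    "fisher_exact_2x2",
    "chromosomal_clusters",
]


def build_trees(track: pd.DataFrame) -> dict[str, IntervalTree]:
    """Interval trees per chromosome from a BED-style frame (0-based, half-open)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in track.groupby("chrom"):
        ivs = [
            (int(s), int(e))
            for s, e in zip(grp["start"], grp["end"])
            if int(e) > int(s)
        ]
        trees[chrom] = IntervalTree.from_tuples(ivs)
    return trees


def _min_distance(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> float:
    """Edge-to-edge distance from [start, end) to the nearest track interval."""
    tree = trees.get(chrom)
    if tree is None or len(tree) == 0:
        return float("inf")
    if tree.overlap(start, end):
        return 0.0
    best = float("inf")
    for iv in tree:
        if iv.end <= start:
            best = min(best, start - iv.end)  # gap in bp between half-open intervals
        elif iv.begin >= end:
            best = min(best, iv.begin - end)
    return best


def classify_island_context(
    region: tuple[str, int, int],
    island_trees: dict[str, IntervalTree],
    shore_flank: int = 2000,
) -> str:
    """island if overlapping an island, shore if within ``shore_flank``, else other."""
    chrom, start, end = region
    tree = island_trees.get(chrom)
    if tree is not None and tree.overlap(int(start), int(end)):
        return "island"
    d = _min_distance(island_trees, chrom, int(start), int(end))
    if d <= shore_flank:
        return "shore"
    return "other"


def classify_regions(
    regions: pd.DataFrame, islands: pd.DataFrame, shore_flank: int = 2000
) -> pd.Series:
    trees = build_trees(islands)
    return pd.Series(
        [
            classify_island_context((r.chrom, r.start, r.end), trees, shore_flank)
            for r in regions.itertuples()
        ],
        index=regions.index,
        name="island_context",
    )


def annotate_genes(
    region: tuple[str, int, int],
    gene_models: pd.DataFrame,
    promoter_window: int = 1000,
) -> list[tuple[str, str]]:
    """Genes hit by the region, labelled promoter or body.

    Promoter = the region overlaps the strand-aware ``promoter_window``
    upstream of (or contains) the TSS; promoter takes precedence over body.
    """
    chrom, start, end = region
    hits: list[tuple[str, str]] = []
    for g in gene_models.itertuples():
        if g.chrom != chrom:
            continue
        if g.strand == "-":
            prom_lo, prom_hi = g.tss, g.tss + promoter_window + 1
        else:
            prom_lo, prom_hi = g.tss - promoter_window, g.tss + 1
        if start < prom_hi and end > prom_lo:
            hits.append((g.gene_id, "promoter"))
        elif start < g.end and end > g.start:
            hits.append((g.gene_id, "body"))
    return hits


def annotate_regions_genes(
    regions: pd.DataFrame, gene_models: pd.DataFrame, promoter_window: int = 1000
) -> pd.DataFrame:
    """Long-form (region index, gene_id, feature) table for all regions."""
    rows = []
    for r in regions.itertuples():
        for gid, feat in annotate_genes(
            (r.chrom, r.start, r.end), gene_models, promoter_window
        ):
            rows.append((r.Index, gid, feat))
    return pd.DataFrame(rows, columns=["region_index", "gene_id", "feature"])


@dataclass
class ColocalizationResult:
    track: str
    table: np.ndarray  # rows: hypo, hyper; cols: co-localized, not
    fisher_p: float


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table; degenerate margin -> 1."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("fisher_exact_2x2 requires a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def colocalize(
    regions: pd.DataFrame,
    track: pd.DataFrame,
    margin: int = 1000,
    track_name: str = "track",
) -> tuple[pd.Series, ColocalizationResult | None]:
    """Flag regions within ``margin`` bp of a track interval; Fisher on hypo vs hyper.

    Returns the per-region boolean flags and, when both inputs allow it, the
    2x2 co-localization contrast of hypo vs hyper regions. An empty track
    yields all-false flags and no test.
    """
    if track.empty:
        logger.warning("colocalize: empty track %s; Fisher test skipped", track_name)
        flags = pd.Series(False, index=regions.index, name="colocalized")
        return flags, None
    trees = build_trees(track)
    flags = pd.Series(
        [
            _min_distance(trees, r.chrom, int(r.start), int(r.end)) <= margin
            for r in regions.itertuples()
        ],
        index=regions.index,
        name="colocalized",
    )
    result = None
    if "direction" in regions.columns:
        hypo = regions["direction"] == "hypo"
        hyper = regions["direction"] == "hyper"
        table = np.array(
            [
                [int((flags & hypo).sum()), int((~flags & hypo).sum())],
                [int((flags & hyper).sum()), int((~flags & hyper).sum())],
            ]
        )
        result = ColocalizationResult(
            track=track_name, table=table, fisher_p=fisher_exact_2x2(table)
        )
    return flags, result


def chromosomal_clusters(
    regions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    min_marks: int = 2,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Call 100-kb clusters of region midpoints with a permutation background.

    A cluster is a maximal chain of midpoints with consecutive gaps <= window
    holding at least ``min_marks`` marks; its occupancy is the largest number
    of midpoints inside any single ``window``-bp span. The background places
    the same number of midpoints uniformly per chromosome; the empirical p is
    the (add-one) fraction of permutations whose genome-wide maximum span
    occupancy reaches the cluster's.
    """
    rng = np.random.default_rng(seed)
    mids: dict[str, np.ndarray] = {}
    for chrom, grp in regions.groupby("chrom"):
        mids[chrom] = np.sort(((grp["start"] + grp["end"]) // 2).to_numpy(np.int64))

    def _max_occupancy(positions: np.ndarray) -> int:
        if positions.size == 0:
            return 0
        j = np.searchsorted(positions, positions + window, side="left")
        return int((j - np.arange(positions.size)).max())

    clusters = []
    for chrom, pos in mids.items():
        if pos.size < min_marks:
            continue
        breaks = np.flatnonzero(np.diff(pos) > window)
        for seg in np.split(pos, breaks + 1):
            if seg.size >= min_marks:
                clusters.append(
                    {
                        "chrom": chrom,
                        "start": int(seg[0]),
                        "end": int(seg[-1]) + 1,
                        "n_marks": int(seg.size),
                        "occupancy": _max_occupancy(seg),
                    }
                )
    out = pd.DataFrame(clusters, columns=["chrom", "start", "end", "n_marks", "occupancy"])
    if out.empty:
        out["perm_p"] = pd.Series(dtype=float)
        return out

    counts_per_chrom = {c: p.size for c, p in mids.items()}
    null_max = np.zeros(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        best = 0
        for chrom, k in counts_per_chrom.items():
            length = chrom_lengths.get(chrom)
            if length is None:
                raise ValueError(f"no declared length for chromosome {chrom}")
            sim = np.sort(rng.integers(0, length, size=k))
            best = max(best, _max_occupancy(sim))
        null_max[b] = best
    out["perm_p"] = [
        (1 + int(np.sum(null_max >= occ))) / (n_permutations + 1)
        for occ in out["occupancy"]
    ]
    return out
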
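"""Single-molecule (per-read) methylation population analysis.

Each targeted-bisulfite read reports the methylation state of every CpG it
covers and stands in for one sperm. Per amplicon, a consensus CpG count is
chosen (the highest count carried by at least 10% of aligned reads), reads
with exactly that count are binned by their number of methylated CpGs,
bins are pooled by age group (young < 45 y at collection, aged >= 45 y) and
normalized to a total of 100 reads, giving comparable population profiles.
A cubic-spline smoothing is available for display only; statistics always
use the raw bins.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "consensus_cpg_count",
    "bin_reads",
    "pool_and_normalize",
    "fractional_difference",
    "PopulationProfile",
    "smooth_profile",
    "plot_profiles",
]


def consensus_cpg_count(
    read_lengths, min_fraction: float = 0.10, rule: str = "exact"
) -> int:
    """Consensus CpG number for one amplicon's reads.

    ``rule="exact"``: the largest count c such that at least ``min_fraction``
    of all reads have exactly c CpGs. ``rule="at_least"``: the largest c such
    that at least ``min_fraction`` of reads have c or more CpGs. If no count
    qualifies the modal count is used and flagged.
    """
    lengths = np.asarray(read_lengths, int)
    if lengths.size == 0:
        raise ValueError("consensus_cpg_count requires at least one read")
    counts = Counter(lengths.tolist())
    total = lengths.size
    if rule == "exact":
        eligible = [c for c, k in counts.items() if k / total >= min_fraction]
    elif rule == "at_least":
        eligible = [
            c
            for c in counts
            if sum(k for c2, k in counts.items() if c2 >= c) / total >= min_fraction
        ]
    else:
        raise ValueError("rule must be 'exact' or 'at_least'")
    if not eligible:
        modal = counts.most_common(1)[0][0]
        logger.warning(
            "consensus_cpg_count: no CpG count reaches %.0f%% of reads; "
            "falling back to modal count %d",
            100 * min_fraction,
            modal,
        )
        return int(modal)
    return int(max(eligible))


def bin_reads(call_strings, consensus_c: int) -> np.ndarray:
    """Histogram reads with exactly ``consensus_c`` CpGs by methylated count.

    Reads with any other CpG count (shorter or longer) are discarded. Returns
    integer bin counts indexed 0..consensus_c; zero retained reads is flagged.
    """
    if consensus_c < 1:
        raise ValueError("consensus_c must be >= 1")
    bins = np.zeros(consensus_c + 1, dtype=np.int64)
    for calls in call_strings:
        if len(calls) != consensus_c:
            continue
        bins[sum(1 for ch in calls if ch == "M")] += 1
    if bins.sum() == 0:
        logger.warning("bin_reads: no reads match consensus CpG count %d", consensus_c)
    return bins


@dataclass
class PopulationProfile:
    """Normalized per-age-group methylation-bin profile for one amplicon."""

    amplicon_id: str
    age_group: str  # "young" (<45) or "aged" (>=45)
    consensus_c: int
    bin_counts: np.ndarray
    normalized_counts: np.ndarray  # sums to 100

    @property
    def mean_methylation(self) -> float:
        """Mean per-read methylated fraction of the binned population."""
        total = self.bin_counts.sum()
        if total == 0:
            return float("nan")
        levels = np.arange(self.consensus_c + 1) / self.consensus_c
        return float((self.bin_counts * levels).sum() / total)


def pool_and_normalize(
    reads: pd.DataFrame,
    samples: pd.DataFrame,
    age_cutoff: float = 45.0,
    min_fraction: float = 0.10,
    consensus_rule: str = "exact",
) -> list[PopulationProfile]:
    """Pool per-read bins by age group and normalize each to 100 reads.

    ``reads`` has amplicon_id, sample_id, read_id, call_string; ``samples``
    maps sample_id to age at collection. Samples aged exactly ``age_cutoff``
    fall into the aged group. Empty groups are omitted with a warning.
    """
    age_of = samples.set_index("sample_id")["age"].to_dict()
    missing = set(reads["sample_id"]) - set(age_of)
    if missing:
        raise ValueError(f"reads reference unknown samples: {sorted(missing)[:5]}")
    profiles: list[PopulationProfile] = []
    for amplicon, grp in reads.groupby("amplicon_id", sort=True):
        c = consensus_cpg_count(
            grp["call_string"].str.len(), min_fraction=min_fraction, rule=consensus_rule
        )
        for group_name in ("young", "aged"):
            if group_name == "aged":
                sel = grp["sample_id"].map(age_of) >= age_cutoff
            else:
                sel = grp["sample_id"].map(age_of) < age_cutoff
            sub = grp.loc[sel]
            if sub.empty:
                logger.warning(
                    "pool_and_normalize: no %s reads for %s; profile omitted",
                    group_name,
                    amplicon,
                )
                continue
            bins = bin_reads(sub["call_string"], c)
            total = bins.sum()
            if total == 0:
                logger.warning(
                    "pool_and_normalize: %s/%s has no consensus-length reads",
                    amplicon,
                    group_name,
                )
                continue
            profiles.append(
                PopulationProfile(
                    amplicon_id=amplicon,
                    age_group=group_name,
                    consensus_c=c,
                    bin_counts=bins,
                    normalized_counts=100.0 * bins / total,
                )
            )
    return profiles


def fractional_difference(aged_value: float, young_value: float) -> float:
    """Cross-platform comparison statistic: (aged / young) - 1."""
    if young_value == 0:
        raise ValueError("fractional_difference undefined for young_value = 0")
    return float(aged_value / young_value - 1.0)


def profiles_frame(profiles: list[PopulationProfile]) -> pd.DataFrame:
    """Long-form table of profiles for reporting."""
    rows = []
    for p in profiles:
        for b in range(p.consensus_c + 1):
            rows.append(
                (
                    p.amplicon_id,
                    p.age_group,
                    p.consensus_c,
                    b,
                    int(p.bin_counts[b]),
                    float(p.normalized_counts[b]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["amplicon_id", "age_group", "consensus_c", "bin", "count", "normalized"],
    )


def smooth_profile(profile: PopulationProfile, n_points: int = 200):
    """Cubic-spline interpolation of the normalized bins, for plotting only."""
    from scipy.interpolate import CubicSpline

    x = np.arange(profile.consensus_c + 1)
    cs = CubicSpline(x, profile.normalized_counts)
    xs = np.linspace(0, profile.consensus_c, n_points)
    return xs, cs(xs)


def plot_profiles(profiles: list[PopulationProfile], out_path) -> None:
    """One panel per amplicon, smoothed young vs aged population profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amplicons = sorted({p.amplicon_id for p in profiles})
    fig, axes = plt.subplots(1, max(1, len(amplicons)), figsize=(4 * len(amplicons), 3.2))
    if len(amplicons) == 1:
        axes = [axes]
    for ax, amp in zip(axes, amplicons):
        for p in profiles:
            if p.amplicon_id != amp:
                continue
            xs, ys = smooth_profile(p)
            ax.plot(xs, ys, label=p.age_group)
        ax.set_title(amp)
        ax.set_xlabel("methylated CpGs per read")
        ax.set_ylabel("reads (per 100)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
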
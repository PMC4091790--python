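"""Sliding-window paired differential-methylation scanner.

The core method: enumerate probe-anchored 1000-bp candidate windows over the
manifest, summarise each window's paired (aged - young) probe-level beta
differences with the Hodges-Lehmann pseudo-median, test consistency across
donors with the Wilcoxon signed-rank test, correct across all candidate
windows with Benjamini-Hochberg, and call windows significant at
q <= 1e-4 with |log2 ratio of group pseudo-medians| >= 0.2. Each significant
window is additionally screened by OLS regression of the per-sample window
mean on age at collection (windows with regression p > 0.05 are excluded)
and annotated with a confirmatory paired t-test on per-donor window means.
Overlapping or book-ended significant windows of the same direction are
merged into regions.

Observation unit: all probe-level paired differences within a window
(probes x donors). With 17 donors and >=3 probes this gives >=51 paired
observations per window, which is what makes a q <= 1e-4 threshold
attainable over thousands of windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "enumerate_windows",
    "pseudo_median",
    "paired_wilcoxon",
    "bh_fdr",
    "transform_fdr",
    "window_log2_ratio",
    "regression_filter",
    "confirm_ttest",
    "call_and_merge",
    "scan",
    "ScanResult",
]

FDR_FLOOR = 1e-30


# ---------------------------------------------------------------------------
# window enumeration
# ---------------------------------------------------------------------------

def enumerate_windows(
    manifest: pd.DataFrame, window_size: int = 1000, min_probes: int = 3
) -> pd.DataFrame:
    """Probe-anchored candidate windows with subset collapse.

    One candidate is anchored at each probe and spans ``[pos0, pos0 +
    window_size)``; candidates covering fewer than ``min_probes`` probes are
    dropped. Because probes are sorted, every candidate's probe set is a
    contiguous run, so a candidate whose set is contained in another's shares
    its right endpoint; only the widest (first-anchored) candidate per
    distinct endpoint is kept.

    Returns a frame with chrom, start, end (0-based half-open, width =
    window_size), first/last probe row indices into the sorted manifest, and
    n_probes.
    """
    if manifest.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "first_idx", "last_idx", "n_probes"]
        )
    mf = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    rows = []
    for chrom, grp in mf.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy(np.int64) - 1  # manifest is 1-based
        base = grp.index[0]
        last = np.searchsorted(pos0, pos0 + window_size, side="left") - 1
        counts = last - np.arange(len(pos0)) + 1
        prev_last = -1
        for i in range(len(pos0)):
            if counts[i] < min_probes or last[i] == prev_last:
                continue
            prev_last = last[i]
            rows.append(
                (
                    chrom,
                    int(pos0[i]),
                    int(pos0[i]) + window_size,
                    int(base + i),
                    int(base + last[i]),
                    int(counts[i]),
                )
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "first_idx", "last_idx", "n_probes"]
    )
    logger.info("enumerate_windows: %d candidates from %d probes", len(out), len(mf))
    return out


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def pseudo_median(values) -> float:
    """Hodges-Lehmann one-sample estimator: median of all Walsh averages."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("pseudo_median of empty input")
    i, j = np.triu_indices(v.size)
    return float(np.median((v[i] + v[j]) / 2.0))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments (average-rank ties).

    Uses the rank-sum generating polynomial on doubled ranks (so tied
    half-ranks stay integral).
    """
    dr = np.round(2.0 * ranks).astype(np.int64)
    total = int(dr.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in dr:
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    denom = 2.0 ** len(dr)
    w2 = int(round(2.0 * w_plus))
    cdf_le = poly[: w2 + 1].sum() / denom
    cdf_ge = poly[w2:].sum() / denom
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def paired_wilcoxon(differences, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zeros are dropped before ranking; ties get average ranks. The null
    distribution is exact (full sign-flip enumeration) for n <= exact_max_n
    and a tie-corrected normal approximation otherwise. All differences zero
    returns p = 1 by convention.
    """
    d = np.asarray(differences, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("paired_wilcoxon of empty input")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        logger.warning("paired_wilcoxon: all differences zero; p = 1 by convention")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def transform_fdr(q, floor: float = FDR_FLOOR):
    """Visualisation transform -10*log10(q); q at/below ``floor`` is floored.

    40 corresponds to q = 1e-4, 20 to 0.01, 13 (rounded) to 0.05.
    """
    arr = np.asarray(q, float)
    if np.any(arr > 1) or np.any(arr < 0):
        raise ValueError("q-values must lie in [0, 1]")
    n_floored = int(np.sum(arr < floor))
    if n_floored:
        logger.warning("transform_fdr: %d value(s) below floor %g", n_floored, floor)
    out = -10.0 * np.log10(np.maximum(arr, floor))
    return float(out) if out.ndim == 0 else out


def window_log2_ratio(pm_aged: float, pm_young: float, eps: float = 1e-6) -> float:
    """log2 of aged/young group pseudo-medians, eps-guarded against zeros."""
    return float(np.log2((pm_aged + eps) / (pm_young + eps)))


def regression_filter(
    window_means: np.ndarray, ages: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """OLS of per-sample window mean beta on age; keep iff p <= alpha.

    Returns (slope in fraction/year, p, keep). Zero age variance makes the
    filter inapplicable and the window is dropped with a warning.
    """
    m = np.asarray(window_means, float)
    a = np.asarray(ages, float)
    ok = ~np.isnan(m)
    m, a = m[ok], a[ok]
    if m.size < 3:
        raise ValueError("regression_filter requires >=3 samples")
    if np.allclose(a.std(), 0.0):
        logger.warning("regression_filter: zero age variance; window dropped")
        return float("nan"), float("nan"), False
    reg = stats.linregress(a, m)
    p = float(reg.pvalue)
    return float(reg.slope), p, bool(p <= alpha)


def confirm_ttest(young_means: np.ndarray, aged_means: np.ndarray) -> float:
    """Two-sided paired t-test p on per-donor window means (reported only).

    Zero variance of the differences leaves the test undefined (NaN, flagged).
    """
    y = np.asarray(young_means, float)
    a = np.asarray(aged_means, float)
    ok = ~(np.isnan(y) | np.isnan(a))
    y, a = y[ok], a[ok]
    if y.size < 2:
        raise ValueError("confirm_ttest requires >=2 donor pairs")
    d = a - y
    if np.allclose(d.std(ddof=1), 0.0):
        logger.warning("confirm_ttest: zero variance of paired differences; undefined")
        return float("nan")
    return float(stats.ttest_rel(a, y).pvalue)


def _baseline_class(pm_young: float) -> str:
    if pm_young < 0.2:
        return "low"
    if pm_young > 0.8:
        return "high"
    return "intermediate"


# ---------------------------------------------------------------------------
# calling and merging
# ---------------------------------------------------------------------------

def call_and_merge(
    windows: pd.DataFrame, q_max: float = 1e-4, min_abs_log2: float = 0.2
) -> pd.DataFrame:
    """Merge significant windows of the same direction into regions.

    A window is significant when q_bh <= q_max, |log2_ratio| >= min_abs_log2
    and it survived the regression filter (``regression_keep``). Overlapping
    or book-ended significant windows of one direction merge; the region
    extent is the union of member windows.
    """
    required = {"chrom", "start", "end", "log2_ratio", "q_bh", "regression_keep"}
    missing = required - set(windows.columns)
    if missing:
        raise ValueError(f"windows frame lacks columns: {sorted(missing)}")
    sig = windows[
        (windows["q_bh"] <= q_max)
        & (windows["log2_ratio"].abs() >= min_abs_log2)
        & windows["regression_keep"].astype(bool)
    ].copy()
    sig["direction"] = np.where(sig["log2_ratio"] < 0, "hypo", "hyper")
    regions = []
    for (chrom, direction), grp in sig.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur["end"]:  # overlap or book-ended
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append(row.Index)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "direction": direction,
                    "members": [row.Index],
                }
        if cur is not None:
            regions.append(cur)
    rows = []
    for reg in regions:
        members = sig.loc[reg["members"]]
        rows.append(
            (
                reg["chrom"],
                reg["start"],
                reg["end"],
                reg["direction"],
                len(members),
                float(members["q_bh"].min()),
                float(members["log2_ratio"].mean()),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "n_windows", "best_q", "mean_log2"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    windows: pd.DataFrame
    regions: pd.DataFrame
    counts: dict = field(default_factory=dict)


def scan(
    manifest: pd.DataFrame,
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    window_size: int = 1000,
    min_probes: int = 3,
    q_max: float = 1e-4,
    min_abs_log2: float = 0.2,
    regression_alpha: float = 0.05,
    eps: float = 1e-6,
) -> ScanResult:
    """Run the full scanner: enumerate, test, correct, filter, merge.

    ``betas`` is probes x samples (indexed by probe_id), ``samples`` carries
    sample_id, donor_id, age, group (young/aged). BH correction spans all
    candidate windows that pass min_probes; the regression filter is applied
    after significance, so it never changes the multiple-testing universe.
    """
    mf = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    mf = mf[mf["probe_id"].isin(betas.index)].reset_index(drop=True)
    candidates = enumerate_windows(mf, window_size=window_size, min_probes=min_probes)
    counts = {"probes": len(mf), "candidate_windows": len(candidates)}
    if candidates.empty:
        empty = pd.DataFrame()
        return ScanResult(windows=empty, regions=empty, counts=counts)

    b = betas.loc[mf["probe_id"]].to_numpy(float)
    samples = samples.reset_index(drop=True)
    donors = sorted(samples["donor_id"].unique())
    col_of = {s: i for i, s in enumerate(betas.columns)}
    young_cols, aged_cols = [], []
    for d in donors:
        sub = samples[samples["donor_id"] == d].sort_values("age")
        if len(sub) != 2:
            raise ValueError(f"donor {d} does not have exactly two samples")
        young_cols.append(col_of[sub["sample_id"].iloc[0]])
        aged_cols.append(col_of[sub["sample_id"].iloc[1]])
    young_cols = np.asarray(young_cols)
    aged_cols = np.asarray(aged_cols)
    ages = samples.set_index("sample_id").loc[list(betas.columns), "age"].to_numpy(float)

    rows = []
    for w in candidates.itertuples():
        block = b[w.first_idx : w.last_idx + 1]  # probes x samples
        sample_means = np.nanmean(block, axis=0)
        young_means = sample_means[young_cols]
        aged_means = sample_means[aged_cols]
        diffs = (block[:, aged_cols] - block[:, young_cols]).ravel()
        diffs = diffs[~np.isnan(diffs)]
        pm_young = pseudo_median(young_means)
        pm_aged = pseudo_median(aged_means)
        rows.append(
            (
                w.chrom,
                w.start,
                w.end,
                w.n_probes,
                pm_young,
                pm_aged,
                pseudo_median(diffs) if diffs.size else float("nan"),
                window_log2_ratio(pm_aged, pm_young, eps=eps),
                paired_wilcoxon(diffs) if diffs.size else 1.0,
            )
        )
    win = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_probes",
            "pm_young",
            "pm_aged",
            "pm_diff",
            "log2_ratio",
            "p_raw",
        ],
    )
    win["q_bh"] = bh_fdr(win["p_raw"].to_numpy())
    win["fdr_transformed"] = transform_fdr(win["q_bh"].to_numpy())
    win["baseline_class"] = [_baseline_class(v) for v in win["pm_young"]]

    pass_sig = (win["q_bh"] <= q_max) & (win["log2_ratio"].abs() >= min_abs_log2)
    counts["significant_windows"] = int(pass_sig.sum())

    slope = np.full(len(win), np.nan)
    reg_p = np.full(len(win), np.nan)
    keep = np.zeros(len(win), bool)
    t_p = np.full(len(win), np.nan)
    for i in np.flatnonzero(pass_sig.to_numpy()):
        w = candidates.iloc[i]
        block = b[w.first_idx : w.last_idx + 1]
        sample_means = np.nanmean(block, axis=0)
        slope[i], reg_p[i], keep[i] = regression_filter(
            sample_means, ages, alpha=regression_alpha
        )
        t_p[i] = confirm_ttest(sample_means[young_cols], sample_means[aged_cols])
    win["slope"] = slope
    win["slope_pct_per_year"] = 100.0 * slope
    win["regression_p"] = reg_p
    win["regression_keep"] = keep
    win["t_paired_p"] = t_p
    called = pass_sig.to_numpy() & keep
    win["direction"] = np.where(
        called, np.where(win["log2_ratio"] < 0, "hypo", "hyper"), "none"
    )
    counts["windows_after_regression_filter"] = int(called.sum())

    regions = call_and_merge(win, q_max=q_max, min_abs_log2=min_abs_log2)
    counts["regions"] = len(regions)
    counts["regions_hypo"] = int((regions["direction"] == "hypo").sum()) if len(regions) else 0
    counts["regions_hyper"] = int((regions["direction"] == "hyper").sum()) if len(regions) else 0
    logger.info("scan: %s", counts)
    return ScanResult(windows=win, regions=regions, counts=counts)
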
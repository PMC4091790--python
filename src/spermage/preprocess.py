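"""Beta-value computation, probe QC filtering, and global methylation trends.

The beta value is the standard array summary of fraction methylation at a
CpG: methylated intensity / (methylated + unmethylated). Poorly performing
probes are removed by a QC p-value rule before any window statistics. The
global trend analysis mirrors a LINE-1 repetitive-element assay: per-sample
mean fraction methylation compared across the cohort by a paired t-test on
donor differences and by OLS regression on age at collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["compute_beta", "qc_filter", "global_trend", "GlobalTrendResult"]


def compute_beta(methylated, unmethylated):
    """Fraction methylation beta = M / (M + U), elementwise.

    Zero total intensity yields NaN (missing, flagged via log) rather than an
    arbitrary value; negative intensities are rejected.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be nonnegative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    n_missing = int(np.sum(total == 0))
    if n_missing:
        logger.warning("compute_beta: %d probe(s) with zero total intensity -> NaN", n_missing)
    if beta.ndim == 0:
        return float(beta)
    return beta


def qc_filter(
    records: pd.DataFrame, threshold: float = 0.05, polarity: str = "below"
) -> set[str]:
    """Return the probe-id set kept after the QC rule.

    The default rule removes probes with qc_p < threshold, exactly as the
    source convention prints it. ``polarity="above"`` removes qc_p > threshold
    instead (the usual detection-p convention) for real array data.
    """
    if records.empty:
        raise ValueError("qc_filter requires at least one record")
    if polarity not in {"below", "above"}:
        raise ValueError("polarity must be 'below' or 'above'")
    qc = records["qc_p"].to_numpy(float)
    bad = qc < threshold if polarity == "below" else qc > threshold
    removed = set(records.loc[bad, "probe_id"])
    kept = set(records["probe_id"]) - removed
    logger.info("qc_filter: removed %d of %d probes", len(removed), len(records))
    return kept


@dataclass
class GlobalTrendResult:
    """Outcome of the global (LINE-1-style) methylation trend analysis."""

    n_donors: int
    n_samples: int
    mean_paired_diff: float
    paired_t_p: float  # NaN when the difference variance is zero
    slope: float  # fraction methylation per year
    slope_pct_per_year: float
    regression_p: float
    intercept: float


def global_trend(records: pd.DataFrame) -> GlobalTrendResult:
    """Paired t-test on per-donor (aged - young) means plus OLS on age.

    ``records`` needs columns sample_id, donor_id, age, mean_fraction; the
    two collections per donor are identified by age order. Requires >=2
    complete donor pairs and >=3 samples.
    """
    recs = records.dropna(subset=["mean_fraction", "age"])
    pairs = []
    for _, grp in recs.groupby("donor_id"):
        if len(grp) == 2:
            grp = grp.sort_values("age")
            pairs.append(
                grp["mean_fraction"].iloc[1] - grp["mean_fraction"].iloc[0]
            )
    if len(pairs) < 2:
        raise ValueError("global_trend requires >=2 donors with paired values")
    if len(recs) < 3:
        raise ValueError("global_trend requires >=3 samples for regression")
    diffs = np.asarray(pairs, float)
    if np.allclose(diffs.std(ddof=1), 0.0):
        logger.warning("global_trend: zero variance of paired differences; t-test undefined")
        t_p = float("nan")
    else:
        t_p = float(stats.ttest_rel(diffs, np.zeros_like(diffs)).pvalue)
    reg = stats.linregress(recs["age"].to_numpy(float), recs["mean_fraction"].to_numpy(float))
    return GlobalTrendResult(
        n_donors=len(pairs),
        n_samples=len(recs),
        mean_paired_diff=float(diffs.mean()),
        paired_t_p=t_p,
        slope=float(reg.slope),
        slope_pct_per_year=float(100.0 * reg.slope),
        regression_p=float(reg.pvalue),
        intercept=float(reg.intercept),
    )
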
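"""Per-individual regression trends and change-change correlations.

Each participant gets an ordinary least-squares line of an outcome
against time since baseline (the long-term follow-up visit excluded by
default, to focus on the training period).  Correlations between two
sets of per-individual slopes — e.g. memory change vs hippocampal-volume
change, or criterion-task change vs transfer-task change — are Pearson
correlations with Fisher-z 95% confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import STATUS_LONG_TERM

logger = logging.getLogger(__name__)

TREND_COLUMNS = ["participant_id", "outcome", "slope", "intercept", "n_points"]


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False  # zero variance in a slope set

    def __iter__(self):  # allow r, lo, hi, n = result
        return iter((self.r, self.ci_low, self.ci_high, self.n))


def individual_trends(
    data: pd.DataFrame,
    outcome: str,
    exclude_followup: bool = True,
    min_points: int = 2,
) -> pd.DataFrame:
    """Per-participant OLS slope and intercept of ``outcome`` on t_years.

    Participants with fewer than ``min_points`` non-missing values are
    excluded and counted in the result's ``attrs["n_excluded"]``.
    """
    d = data[data[outcome].notna()]
    if exclude_followup:
        d = d[d["status"] != STATUS_LONG_TERM]
    rows, n_excluded = [], 0
    for pid, sub in d.groupby("participant_id", sort=True):
        t = sub["t_years"].to_numpy(float)
        y = sub[outcome].to_numpy(float)
        if len(t) < min_points or np.ptp(t) == 0.0:
            n_excluded += 1
            continue
        slope, intercept = np.polyfit(t, y, 1)
        rows.append(
            {
                "participant_id": pid,
                "outcome": outcome,
                "slope": float(slope),
                "intercept": float(intercept),
                "n_points": len(t),
            }
        )
    if not rows:
        raise ValueError(f"no participant has >= {min_points} points for {outcome!r}")
    if n_excluded:
        logger.info(
            "%d participants excluded from %s trends (<%d points)",
            n_excluded, outcome, min_points,
        )
    out = pd.DataFrame(rows, columns=TREND_COLUMNS)
    out.attrs["n_excluded"] = n_excluded
    return out


def _pearson_fisher(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("zero variance in a slope set; correlation undefined")
        return CorrelationResult(np.nan, np.nan, np.nan, n, degenerate=True)
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)  # Fisher z interval
    return CorrelationResult(float(res.statistic), float(ci.low), float(ci.high), n)


def correlate_trends(
    a: pd.DataFrame, b: pd.DataFrame, on: str = "slope"
) -> CorrelationResult:
    """Pearson correlation of two per-individual trend quantities.

    ``a`` and ``b`` are trend tables from :func:`individual_trends`;
    participants present in both (pairwise-complete matching) enter the
    correlation.  ``on`` selects "slope" (change-change correlation) or
    "intercept" (overall level).
    """
    merged = a[["participant_id", on]].merge(
        b[["participant_id", on]], on="participant_id", suffixes=("_a", "_b")
    )
    return _pearson_fisher(
        merged[f"{on}_a"].to_numpy(float), merged[f"{on}_b"].to_numpy(float)
    )


def slope_vs_followup(
    trends: pd.DataFrame, data: pd.DataFrame, score: str = "memory_score"
) -> CorrelationResult:
    """Correlation of training-period slopes with the follow-up score."""
    fu = data[(data["status"] == STATUS_LONG_TERM) & data[score].notna()]
    fu = fu.sort_values("visit_index").groupby("participant_id", sort=True).last()
    merged = trends.merge(
        fu[[score]].reset_index(), on="participant_id", how="inner"
    )
    return _pearson_fisher(
        merged["slope"].to_numpy(float), merged[score].to_numpy(float)
    )
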
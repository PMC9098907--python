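"""Long-term retention curves, bootstrap confidence bands, prevail times,
and the word-pair transfer fit.

The retention curve is the fitted immediate first-training effect decayed
over a dense grid of times since training, ``beta1_g * exp(-lambda_g * dt)``
for ``dt`` in [0, 5] years, per age group.  Confidence bands come from a
nonparametric *case* bootstrap (participants resampled with replacement,
keeping full visit histories) coupled with an *individual residual*
bootstrap: each resampled participant's outcomes are rebuilt as fitted
fixed-effect means plus a resampled participant-level random-intercept
prediction plus independently resampled observation residuals, and the
model is refit to every replicate.  Bands are pointwise percentile
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import OLDER, YOUNG
from .retention import RetentionModel, RetentionParams

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.linspace(0.0, 5.0, 201)  # dense grid, years since training


def retention_curve(
    params: RetentionParams, group: str, grid: Optional[np.ndarray] = None
) -> np.ndarray:
    """Point-estimate retention curve beta1_g * exp(-lambda_g * dt)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    if group == OLDER:
        beta1, lam = params.beta1_older, params.lambda_older
    elif group == YOUNG:
        beta1, lam = params.beta1_young, params.lambda_young
    else:
        raise ValueError(f"unknown age group {group!r}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return beta1 * np.exp(-lam * grid)


@dataclass
class BootstrapBand:
    """Pointwise percentile band for the retention curve, per age group."""

    grid: np.ndarray
    estimate: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    n_boot: int
    n_dropped: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in self.estimate:
            rows.append(
                pd.DataFrame(
                    {
                        "delta_t": self.grid,
                        "group": group,
                        "estimate": self.estimate[group],
                        "lo": self.lower[group],
                        "hi": self.upper[group],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def bootstrap_retention(
    data: pd.DataFrame,
    model: RetentionModel,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    residual_step: bool = True,
    groups: Sequence[str] = (YOUNG, OLDER),
    max_iter: int = 200,
) -> BootstrapBand:
    """Case + individual residual bootstrap band for the retention curve.

    ``model`` must already be fitted on ``data``; each replicate refits
    the same model specification, warm-started at the original optimum.
    Replicates that fail to produce a finite fit are dropped and counted;
    more than 10% dropped triggers a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not getattr(model, "converged_", False):
        logger.warning("bootstrapping a model whose fit did not converge")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(seed)

    des = model._design_
    fixed_mean = des.mean(model.params_)
    b_hat, e_hat = des.blups(model.params_)
    # Centered AND reflated pools: empirical BLUPs and conditional
    # residuals are shrunken, so resampling them as-is under-disperses
    # the rebuilt outcomes and narrows the band.  Rescale each pool to
    # the estimated variance component before resampling.
    b_pool = b_hat - b_hat.mean()
    e_pool = e_hat - e_hat.mean()
    b_sd, e_sd = b_pool.std(), e_pool.std()
    if b_sd > 0:
        b_pool = b_pool * (model.params_.sigma_b / b_sd)
    if e_sd > 0:
        e_pool = e_pool * (model.params_.sigma_e / e_sd)

    point = {g: retention_curve(model.params_, g, grid) for g in groups}
    curves: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    x0 = model._opt_vec_
    n_dropped = 0
    for _ in range(n_boot):
        draw = rng.integers(0, des.n_subjects, size=des.n_subjects)
        if residual_step:
            b_new = b_pool[rng.integers(0, len(b_pool), size=des.n_subjects)]
            des_b = des.resampled(draw, y=fixed_mean)
            e_new = e_pool[rng.integers(0, len(e_pool), size=len(des_b.y))]
            des_b.y = des_b.y + np.repeat(b_new, des_b.n_per.astype(int)) + e_new
        else:
            des_b = des.resampled(draw)
        try:
            res = model._optimize(des_b, x0, max_iter)
            if not np.isfinite(res.fun):
                raise FloatingPointError("non-finite log-likelihood")
            params = RetentionParams.from_unconstrained(res.x)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            n_dropped += 1
            continue
        for g in groups:
            curves[g].append(retention_curve(params, g, grid))
    if n_dropped > 0.1 * n_boot:
        logger.warning("%d of %d bootstrap replicates dropped", n_dropped, n_boot)

    lower, upper = {}, {}
    for g in groups:
        arr = np.asarray(curves[g])
        # quantile-unbiased tail estimator: at moderate B the default
        # linear interpolation places the 2.5/97.5 endpoints slightly
        # inside the tails
        lower[g] = np.percentile(arr, 2.5, axis=0, method="normal_unbiased")
        upper[g] = np.percentile(arr, 97.5, axis=0, method="normal_unbiased")
    return BootstrapBand(
        grid=grid,
        estimate=point,
        lower=lower,
        upper=upper,
        n_boot=n_boot,
        n_dropped=n_dropped,
        seed=seed,
    )


@dataclass
class PrevailTime:
    """Largest time since training at which the band still excludes zero."""

    years: float
    censored: bool  # True when the lower bound never crosses zero on the grid


def prevail_time(band: BootstrapBand, group: str) -> PrevailTime:
    """Operationalized 'prevail' time: largest grid dt with lower bound > 0.

    The grid maximum is returned flagged ``censored`` when the bound stays
    positive everywhere, since the true crossing lies beyond the grid.
    """
    lo = band.lower[group]
    positive = lo > 0
    if positive.all():
        return PrevailTime(float(band.grid[-1]), censored=True)
    if not positive.any():
        return PrevailTime(0.0, censored=False)
    last = np.flatnonzero(positive).max()
    return PrevailTime(float(band.grid[last]), censored=False)


def filter_transfer(data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the transfer-task completeness filter.

    Keep only rows that carry a criterion (100-words) score, then drop
    participants with fewer than two (pre and post training) word-pair
    scores.  Returns the filtered table and the number of participants
    excluded.
    """
    d = data[data["memory_score"].notna()]
    n_wp = d.groupby("participant_id")["wordpair_score"].count()
    keep = n_wp.index[n_wp >= 2]
    n_excluded = int((n_wp < 2).sum())
    if n_excluded:
        logger.info("transfer filter excluded %d participants", n_excluded)
    return d[d["participant_id"].isin(keep)], n_excluded


def fit_transfer(data: pd.DataFrame, **kwargs) -> RetentionModel:
    """Fit the retention model to the word-pair (transfer) outcome.

    The fitted model exposes ``n_excluded_transfer_`` with the number of
    participants removed by the completeness filter.
    """
    filtered, n_excluded = filter_transfer(data)
    if filtered.empty:
        raise ValueError("no participants left after the transfer filter")
    model = RetentionModel(outcome="wordpair_score", **kwargs).fit(filtered)
    model.n_excluded_transfer_ = n_excluded
    return model
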
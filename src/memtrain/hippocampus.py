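"""Short- and long-term linear mixed models of hippocampal volume.

Short term: within the intervention year, volume (left+right sum, mm^3)
is modelled with a categorical training status (baseline / post_train /
post_rest) interacting with age group, plus age group, a per-group time
slope, ICV, and sex, with a random intercept and time slope per
participant (REML).  Baseline is the reference level, so the post_train
and post_rest coefficients estimate the relative volume change directly
after a training period and ten weeks later.

Long term: trainers' visits before the first training plus their ~3-year
follow-up are compared with passive controls' two visits through a
three-way time x age-group x trained interaction (all lower-order terms
included), giving each group's trained-minus-control trajectory
difference, reported at the group's mean follow-up interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import (
    OLDER,
    PASSIVE_CTRL,
    STATUS_BASELINE,
    STATUS_LONG_TERM,
    STATUS_POST_REST,
    STATUS_POST_TRAIN,
    TRAINING_ARMS,
    YOUNG,
)
from .lmm import LinearMixedModel, LMMSpec

logger = logging.getLogger(__name__)

_Z = 1.959963984540054


class MissingStatusError(ValueError):
    """A training-status level required by the model is absent."""


class NoControlsError(ValueError):
    """The long-term contrast requires passive controls."""


@dataclass
class EffectEstimate:
    estimate: float
    se: float

    @property
    def ci_low(self) -> float:
        return self.estimate - _Z * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + _Z * self.se


@dataclass
class StatusEffects:
    """Training-status effects on hippocampal volume vs baseline (mm^3)."""

    post_train: dict[str, EffectEstimate]
    post_rest: dict[str, EffectEstimate]
    n_obs: int
    n_subjects: int
    converged: bool


@dataclass
class LongTermContrast:
    """Trained-minus-control volume difference at the follow-up horizon.

    ``slope_diff_at_horizon`` reads the difference as (trained x time
    slope difference) x horizon; ``level_at_followup`` additionally
    includes any trained-vs-control level offset at baseline.  Both
    readings are reported since the published quantity could be either.
    """

    slope_diff_at_horizon: dict[str, EffectEstimate]
    level_at_followup: dict[str, EffectEstimate]
    horizons: dict[str, float]
    n_obs: int
    n_subjects: int
    converged: bool


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    d = data[data["hippocampus_mm3"].notna()].copy()
    icv = d["icv_mm3"].astype(float)
    icv = icv.fillna(d.groupby("participant_id")["icv_mm3"].transform("mean"))
    d["icv_c"] = icv - icv.mean()
    d["older"] = (d["age_group"] == OLDER).astype(float)
    d["male"] = (d["sex"] == "M").astype(float)
    return d


class HippocampalStatusModel(BaseEstimator):
    """Short-term training-status model of hippocampal volume (REML LMM)."""

    def __init__(self, reml: bool = True):
        self.reml = reml

    def fit(self, data: pd.DataFrame, y=None):
        d = _prepare(data)
        d = d[d["arm"].isin(TRAINING_ARMS) & (d["status"] != STATUS_LONG_TERM)]
        for level in (STATUS_BASELINE, STATUS_POST_TRAIN, STATUS_POST_REST):
            if not (d["status"] == level).any():
                raise MissingStatusError(f"status level {level!r} absent from data")
        d["pt"] = (d["status"] == STATUS_POST_TRAIN).astype(float)
        d["pr"] = (d["status"] == STATUS_POST_REST).astype(float)
        spec = LMMSpec(
            formula=(
                "hippocampus_mm3 ~ pt + pr + pt:older + pr:older + older"
                " + t_years + t_years:older + icv_c + male"
            ),
            random_slope="t_years",
            reml=self.reml,
        )
        self.lmm_ = LinearMixedModel(spec).fit(d)
        est = {}
        for name, col in (("post_train", "pt"), ("post_rest", "pr")):
            young_e, young_se = self.lmm_.contrast({col: 1.0})
            older_e, older_se = self.lmm_.contrast({col: 1.0, f"{col}:older": 1.0})
            est[name] = {
                YOUNG: EffectEstimate(young_e, young_se),
                OLDER: EffectEstimate(older_e, older_se),
            }
        f = self.lmm_.fit_
        self.effects_ = StatusEffects(
            post_train=est["post_train"],
            post_rest=est["post_rest"],
            n_obs=f.n_obs,
            n_subjects=f.n_subjects,
            converged=f.converged,
        )
        return self


class HippocampalLongTermModel(BaseEstimator):
    """Trained-vs-passive-control trajectory model over the full study."""

    def __init__(self, reml: bool = True, horizons: Optional[dict[str, float]] = None):
        self.reml = reml
        self.horizons = horizons

    def fit(self, data: pd.DataFrame, y=None):
        d = _prepare(data)
        is_passive = d["arm"] == PASSIVE_CTRL
        if not is_passive.any():
            raise NoControlsError("long-term contrast requires passive controls")
        pre_training = (d["n_trainings"] == 0) & (d["status"] != STATUS_LONG_TERM)
        followup = d["status"] == STATUS_LONG_TERM
        d = d[is_passive | pre_training | followup].copy()
        d["trained"] = d["arm"].isin(TRAINING_ARMS).astype(float)
        self.has_trainers_ = bool(d["trained"].any())
        if self.horizons is not None:
            horizons = dict(self.horizons)
        else:
            fu = d[d["status"] == STATUS_LONG_TERM]
            if fu.empty:  # trainees never returned; fall back to max time
                fu = d
            horizons = fu.groupby("age_group")["t_years"].mean().to_dict()
            logger.info("long-term contrast horizons (years): %s", horizons)
        if self.has_trainers_:
            formula = "hippocampus_mm3 ~ t_years * older * trained + icv_c + male"
        else:  # controls only: the model reduces to a plain growth model
            formula = "hippocampus_mm3 ~ t_years * older + icv_c + male"
        spec = LMMSpec(formula=formula, random_slope="t_years", reml=self.reml)
        self.lmm_ = LinearMixedModel(spec).fit(d)
        if not self.has_trainers_:
            f = self.lmm_.fit_
            self.contrasts_ = LongTermContrast(
                slope_diff_at_horizon={}, level_at_followup={},
                horizons={g: float(horizons.get(g, np.nan)) for g in (YOUNG, OLDER)},
                n_obs=f.n_obs, n_subjects=f.n_subjects, converged=f.converged,
            )
            return self
        slope_diff, level = {}, {}
        for group in (YOUNG, OLDER):
            h = float(horizons.get(group, np.nan))
            w_slope = {"t_years:trained": h}
            w_level = {"trained": 1.0, "t_years:trained": h}
            if group == OLDER:
                w_slope["t_years:older:trained"] = h
                w_level["older:trained"] = 1.0
                w_level["t_years:older:trained"] = h
            e, se = self.lmm_.contrast(w_slope)
            slope_diff[group] = EffectEstimate(e, se)
            e, se = self.lmm_.contrast(w_level)
            level[group] = EffectEstimate(e, se)
        f = self.lmm_.fit_
        self.contrasts_ = LongTermContrast(
            slope_diff_at_horizon=slope_diff,
            level_at_followup=level,
            horizons={g: float(horizons.get(g, np.nan)) for g in (YOUNG, OLDER)},
            n_obs=f.n_obs,
            n_subjects=f.n_subjects,
            converged=f.converged,
        )
        return self


def fit_short_term(data: pd.DataFrame, reml: bool = True) -> StatusEffects:
    """Short-term status effects on hippocampal volume (see class docs)."""
    return HippocampalStatusModel(reml=reml).fit(data).effects_


def fit_long_term(
    data: pd.DataFrame, reml: bool = True, horizons: Optional[dict] = None
) -> LongTermContrast:
    """Long-term trained-vs-control contrast (see class docs)."""
    return HippocampalLongTermModel(reml=reml, horizons=horizons).fit(data).contrasts_
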
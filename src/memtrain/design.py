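"""Intervention arms, visit schedules, and training covariates.

The study is a crossover memory-training intervention in two age groups
(adults in their twenties and in their seventies).  Trainers alternate
10-week training (A) and rest (B) periods in one of two orders (ABAB or
BABA), an active-control arm attends lectures for one period and then
trains once (CBA), and a passive-control arm is only assessed twice,
roughly three years apart.  Every period boundary carries a cognitive
assessment and an MRI scan, plus one long-term follow-up visit.

From a participant's schedule this module derives, per visit, the
covariates the retention model is built on:

* ``n_trainings`` — completed training periods so far (0, 1, or 2),
* ``x1``/``x2`` — dummies for exactly one / exactly two completed trainings,
* ``delta_t`` — years since the end of the most recent training period
  (0 at a visit immediately following training; undefined before any),
* ``retest`` — whether the test has been taken at least once before,
* ``status`` — short-term training status of the visit: ``post_train``
  (scan immediately after a training period), ``post_rest`` (one rest
  period after a training period), ``baseline`` (no training before the
  current or previous measurement), or ``long_term`` for the follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

TRAIN = "TRAIN"
REST = "REST"
CONTROL = "CONTROL"

ABAB = "ABAB"
BABA = "BABA"
ACTIVE_CTRL_CBA = "ACTIVE_CTRL_CBA"
PASSIVE_CTRL = "PASSIVE_CTRL"

#: Ordered period sequence of each arm.
ARM_PERIODS: dict[str, tuple[str, ...]] = {
    ABAB: (TRAIN, REST, TRAIN, REST),
    BABA: (REST, TRAIN, REST, TRAIN),
    ACTIVE_CTRL_CBA: (CONTROL, REST, TRAIN),
    PASSIVE_CTRL: (),
}

TRAINING_ARMS = (ABAB, BABA, ACTIVE_CTRL_CBA)

STATUS_BASELINE = "baseline"
STATUS_POST_TRAIN = "post_train"
STATUS_POST_REST = "post_rest"
STATUS_LONG_TERM = "long_term"
STATUS_LEVELS = (STATUS_BASELINE, STATUS_POST_TRAIN, STATUS_POST_REST, STATUS_LONG_TERM)

YOUNG = "young"
OLDER = "older"
AGE_GROUPS = (YOUNG, OLDER)

#: Long-format per-visit table columns (one row per participant-visit).
VISIT_COLUMNS = [
    "participant_id",
    "age_group",
    "sex",
    "arm",
    "visit_index",
    "t_years",
    "age_years",
    "delta_t_years",
    "n_trainings",
    "x1",
    "x2",
    "retest",
    "status",
    "memory_score",
    "wordpair_score",
    "hippocampus_mm3",
    "icv_mm3",
]


class UnknownArmError(ValueError):
    """Raised for an arm label outside the study design."""


class TrainingCountError(ValueError):
    """Raised when a schedule implies more than two completed trainings."""


@dataclass(frozen=True)
class Participant:
    participant_id: str
    age_group: str  # "young" | "older"
    sex: str  # "F" | "M"
    baseline_age: float  # years at first assessment
    arm: str
    icv_baseline: Optional[float] = None  # mm^3

    def __post_init__(self) -> None:
        if self.arm not in ARM_PERIODS:
            raise UnknownArmError(f"unknown arm label: {self.arm!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")


@dataclass
class VisitRecord:
    """One participant-visit with derived training covariates and outcomes."""

    participant_id: str
    visit_index: int
    t: float  # years since the participant's first assessment
    delta_t: Optional[float]  # years since end of last completed training
    n_trainings: int
    x1: int
    x2: int
    retest: int
    status: str
    age_years: Optional[float] = None
    memory_score: Optional[float] = None  # words recalled, 0-100
    wordpair_score: Optional[float] = None  # pairs recalled, 0-36
    hippocampus_vol: Optional[float] = None  # mm^3, both hemispheres
    icv: Optional[float] = None  # mm^3


def build_schedule(
    arm: str, period_years: float = 0.21, followup_years: float = 3.0
) -> list[float]:
    """Nominal assessment times (years) bracketing every period, plus follow-up.

    ABAB/BABA yield 5 intervention visits + 1 follow-up; the active-control
    CBA arm 4 + 1; passive controls only baseline and follow-up.
    """
    if arm not in ARM_PERIODS:
        raise UnknownArmError(f"unknown arm label: {arm!r}")
    periods = ARM_PERIODS[arm]
    if periods and period_years <= 0:
        raise ValueError("period_years must be > 0")
    total = period_years * len(periods)
    if followup_years <= total:
        raise ValueError(
            f"followup_years ({followup_years}) must exceed the summed period "
            f"durations ({total:.3f})"
        )
    times = [i * period_years for i in range(len(periods) + 1)] if periods else [0.0]
    times.append(followup_years)
    return times


def _completed_trainings(periods: Sequence[str], visit_index: int) -> int:
    """Training periods fully completed before visit ``visit_index``."""
    return sum(1 for p in periods[: min(visit_index, len(periods))] if p == TRAIN)


def _last_training_boundary(periods: Sequence[str], visit_index: int) -> Optional[int]:
    """Index of the visit that closed the most recent completed training."""
    last = None
    for i, p in enumerate(periods[: min(visit_index, len(periods))]):
        if p == TRAIN:
            last = i + 1  # visit i+1 ends period i
    return last


def derive_training_covariates(
    participant: Participant, visit_times: Sequence[float]
) -> list[VisitRecord]:
    """Fill x1, x2, delta_t, n_trainings, and retest for each visit.

    Visit *i* is taken to bracket period *i* of the arm's period sequence,
    so realized (jittered or truncated) visit times are handled: a visit
    beyond the last period boundary is the long-term follow-up.  The
    CONTROL period of the active-control arm contributes nothing to the
    training covariates.
    """
    times = list(visit_times)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("visit times must be strictly increasing")
    if not all(math.isfinite(t) for t in times):
        raise ValueError("visit times must be finite")
    periods = ARM_PERIODS[participant.arm]
    records = []
    for i, t in enumerate(times):
        n_tr = _completed_trainings(periods, i)
        if n_tr > 2:
            raise TrainingCountError(
                "model defines dummies for at most two completed trainings"
            )
        boundary = _last_training_boundary(periods, i)
        delta_t = None if boundary is None else t - times[boundary]
        records.append(
            VisitRecord(
                participant_id=participant.participant_id,
                visit_index=i,
                t=t - times[0],
                delta_t=delta_t,
                n_trainings=n_tr,
                x1=int(n_tr == 1),
                x2=int(n_tr == 2),
                retest=int(i > 0),
                status=_status_at(periods, i, len(times)),
                age_years=participant.baseline_age + (t - times[0]),
            )
        )
    return records


def _status_at(periods: Sequence[str], visit_index: int, n_visits: int) -> str:
    if not periods:  # passive controls are never trained
        return STATUS_BASELINE
    if visit_index > len(periods):
        return STATUS_LONG_TERM
    if visit_index >= 1 and periods[visit_index - 1] == TRAIN:
        return STATUS_POST_TRAIN
    if (
        visit_index >= 2
        and periods[visit_index - 1] == REST
        and periods[visit_index - 2] == TRAIN
    ):
        return STATUS_POST_REST
    return STATUS_BASELINE


def derive_training_status(
    participant: Participant, visit_times: Sequence[float]
) -> list[str]:
    """Short-term training status per visit (follow-up flagged long_term)."""
    return [r.status for r in derive_training_covariates(participant, visit_times)]


def records_to_frame(
    participants: Sequence[Participant], records: Sequence[VisitRecord]
) -> pd.DataFrame:
    """Assemble VisitRecords into the long-format analysis table."""
    info = {p.participant_id: p for p in participants}
    rows = []
    for r in records:
        p = info[r.participant_id]
        rows.append(
            {
                "participant_id": r.participant_id,
                "age_group": p.age_group,
                "sex": p.sex,
                "arm": p.arm,
                "visit_index": r.visit_index,
                "t_years": r.t,
                "age_years": r.age_years,
                "delta_t_years": r.delta_t,
                "n_trainings": r.n_trainings,
                "x1": r.x1,
                "x2": r.x2,
                "retest": r.retest,
                "status": r.status,
                "memory_score": r.memory_score,
                "wordpair_score": r.wordpair_score,
                "hippocampus_mm3": r.hippocampus_vol,
                "icv_mm3": r.icv,
            }
        )
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)
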
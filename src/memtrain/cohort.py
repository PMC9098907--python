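"""Synthetic crossover memory-training cohorts.

Generates complete studies with the statistical structure the downstream
analyses assume: ABAB/BABA trainers, a small active-control arm whose
members train once after a lecture period (CBA), and passive controls
with only two assessments ~3 years apart.  Memory and word-pair scores
follow the exponential-decay retention model with a participant random
intercept; hippocampal volumes follow a linear mixed model with random
intercept and slope, categorical training-status effects, an ICV
covariate, and a trained-vs-control trajectory difference.  The
``paper_defaults`` preset encodes the published design (group sizes,
0.21-year periods, follow-up intervals) with generative effects set to
the published point estimates.

Scores are rounded to integers and clamped to their test ranges (0-100
words, 0-36 pairs); generative SDs are calibrated so clamping is rare at
the defaults, and a warning is logged when it is not.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import design
from .design import (
    ABAB,
    ACTIVE_CTRL_CBA,
    BABA,
    OLDER,
    PASSIVE_CTRL,
    VISIT_COLUMNS,
    YOUNG,
    Participant,
    records_to_frame,
)
from .retention import RetentionParams

logger = logging.getLogger(__name__)


@dataclass
class GroupValue:
    """A (young, older) pair of per-age-group values."""

    young: float
    older: float

    def get(self, group: str) -> float:
        return self.young if group == YOUNG else self.older


@dataclass
class HippocampusParams:
    """Generative/analysis parameters of the hippocampal volume model (mm^3).

    Volumes are the left+right hemisphere sum.  ``longterm_diff`` is the
    trained-minus-passive-control volume difference at each group's mean
    follow-up interval; the generator realizes it as a slope offset for
    trainers.
    """

    intercept: GroupValue = field(default_factory=lambda: GroupValue(8500.0, 7380.0))
    slope: GroupValue = field(default_factory=lambda: GroupValue(-20.0, -80.0))  # mm^3/y
    theta_post_train: GroupValue = field(default_factory=lambda: GroupValue(10.3, 22.4))
    theta_post_rest: GroupValue = field(default_factory=lambda: GroupValue(28.5, 26.9))
    longterm_diff: GroupValue = field(default_factory=lambda: GroupValue(-77.0, 136.0))
    icv_coef: float = 0.001  # mm^3 hippocampus per mm^3 ICV (centered)
    sex_effect: float = 50.0  # male - female
    sd_intercept: float = 600.0
    sd_slope: float = 15.0  # mm^3/year
    sd_resid: float = 40.0

    def __post_init__(self) -> None:
        if min(self.sd_intercept, self.sd_slope, self.sd_resid) <= 0:
            raise ValueError("variance parameters must be positive")


@dataclass
class SlopeCoupling:
    """Bivariate latent per-participant slopes for two outcomes.

    When active, the two outcomes are generated as individual linear
    trajectories over the intervention year (plateauing at follow-up),
    with latent slopes drawn from a bivariate normal with correlation
    ``rho`` — the data-generating process behind the change-change
    correlation analyses.
    """

    outcome_a: str = "memory_score"
    outcome_b: str = "wordpair_score"
    rho: float = 0.42
    mean_a: float = 20.0  # words/year
    mean_b: float = 4.0  # pairs/year
    sd_a: float = 12.0
    sd_b: float = 5.0
    level_mean_a: float = 17.0
    level_mean_b: float = 19.0
    level_sd_a: float = 3.0
    level_sd_b: float = 2.5
    resid_a: float = 0.75
    resid_b: float = 0.4

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("degenerate (zero-variance) slope configuration")


@dataclass
class CohortConfig:
    """Full generative description of a synthetic study."""

    # arm sizes, (young, older)
    n_abab: tuple[int, int] = (34, 46)
    n_baba: tuple[int, int] = (19, 42)
    n_active_ctrl: tuple[int, int] = (4, 12)  # active controls who then train (CBA)
    n_passive: tuple[int, int] = (47, 36)
    female_prop: GroupValue = field(default_factory=lambda: GroupValue(0.59, 0.59))
    age_mean: GroupValue = field(default_factory=lambda: GroupValue(26.3, 73.3))
    age_sd: GroupValue = field(default_factory=lambda: GroupValue(3.1, 3.1))
    passive_age_mean: GroupValue = field(default_factory=lambda: GroupValue(24.3, 71.9))
    passive_age_sd: GroupValue = field(default_factory=lambda: GroupValue(3.07, 3.36))
    icv_mean: GroupValue = field(default_factory=lambda: GroupValue(1.56e6, 1.54e6))
    icv_sd: GroupValue = field(default_factory=lambda: GroupValue(1.5e5, 1.55e5))
    period_years: float = 0.21
    visit_jitter_sd: float = 0.01
    followup_mean: GroupValue = field(default_factory=lambda: GroupValue(2.90, 2.97))
    followup_sd: GroupValue = field(default_factory=lambda: GroupValue(0.80, 0.61))
    passive_followup_mean: GroupValue = field(default_factory=lambda: GroupValue(3.80, 2.33))
    passive_followup_sd: GroupValue = field(default_factory=lambda: GroupValue(0.51, 0.47))
    dropout_prob: float = 0.05  # per visit, from the third visit on (monotone)
    frailty_sd: float = 0.0  # optional IQ-like attrition frailty (logit scale)
    wordpair_missing_prob: float = 0.08  # first two word-pair scores missing
    retention: RetentionParams = field(default_factory=lambda: RetentionParams())
    transfer: RetentionParams = field(default_factory=lambda: RetentionParams())
    hippocampus: HippocampusParams = field(default_factory=HippocampusParams)
    slope_coupling: Optional[SlopeCoupling] = None
    clamp_warn_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_abab", "n_baba", "n_active_ctrl", "n_passive"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


def paper_defaults(**overrides) -> CohortConfig:
    """The published study conditions as a generative configuration.

    Fixed effects equal the published point estimates; decay rates and
    variance components, which are not printed, are calibrated from the
    published score tables and retention statement (see docs/methods.md).
    """
    retention = RetentionParams(
        mu=17.0,
        alpha_older=-8.0,
        gamma_sex=-1.0,
        beta1_young=17.6,
        beta1_older=7.23,
        beta2_young=20.6,
        beta2_older=8.11,
        lambda_young=0.40,
        lambda_older=0.10,
        rho_retest=2.80,
        delta_young=-0.08,
        delta_older=-0.54,
        sigma_b=3.0,
        sigma_e=3.0,
    )
    transfer = RetentionParams(
        mu=19.0,
        alpha_older=-14.0,
        gamma_sex=-0.5,
        beta1_young=1.89,
        beta1_older=0.37,
        beta2_young=3.94,
        beta2_older=2.36,
        lambda_young=0.40,
        lambda_older=0.10,
        rho_retest=1.0,
        delta_young=-0.05,
        delta_older=-0.20,
        sigma_b=2.0,
        sigma_e=2.0,
    )
    cfg = CohortConfig(retention=retention, transfer=transfer)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def induce_slope_correlation(
    config: CohortConfig,
    outcome_a: str = "memory_score",
    outcome_b: str = "wordpair_score",
    rho: float = 0.42,
    **kwargs,
) -> CohortConfig:
    """Return a config whose generator draws correlated latent slopes."""
    coupling = SlopeCoupling(outcome_a=outcome_a, outcome_b=outcome_b, rho=rho, **kwargs)
    return dataclasses.replace(config, slope_coupling=coupling)


# ---------------------------------------------------------------------------


def _draw_participants(config: CohortConfig, rng: np.random.Generator):
    specs = []
    arm_counts = [
        (ABAB, config.n_abab),
        (BABA, config.n_baba),
        (ACTIVE_CTRL_CBA, config.n_active_ctrl),
        (PASSIVE_CTRL, config.n_passive),
    ]
    i = 0
    for arm, (n_young, n_older) in arm_counts:
        for group, n in ((YOUNG, n_young), (OLDER, n_older)):
            for _ in range(n):
                i += 1
                passive = arm == PASSIVE_CTRL
                age_mean = (config.passive_age_mean if passive else config.age_mean).get(group)
                age_sd = (config.passive_age_sd if passive else config.age_sd).get(group)
                specs.append(
                    Participant(
                        participant_id=f"P{i:04d}",
                        age_group=group,
                        sex="F" if rng.random() < config.female_prop.get(group) else "M",
                        baseline_age=float(rng.normal(age_mean, age_sd)),
                        arm=arm,
                        icv_baseline=float(
                            rng.normal(config.icv_mean.get(group), config.icv_sd.get(group))
                        ),
                    )
                )
    return specs


def _visit_times(p: Participant, config: CohortConfig, rng: np.random.Generator):
    periods = design.ARM_PERIODS[p.arm]
    passive = p.arm == PASSIVE_CTRL
    fu_mean = (config.passive_followup_mean if passive else config.followup_mean).get(p.age_group)
    fu_sd = (config.passive_followup_sd if passive else config.followup_sd).get(p.age_group)
    times = [0.0]
    for k in range(1, len(periods) + 1):
        t = k * config.period_years + rng.normal(0.0, config.visit_jitter_sd)
        times.append(max(t, times[-1] + 0.02))
    fu = rng.normal(fu_mean, fu_sd)
    times.append(max(fu, times[-1] + 0.3))
    return times


def _attended(n_visits: int, config: CohortConfig, rng: np.random.Generator, frailty: float):
    """Monotone dropout: once a visit is missed, all later visits are too."""
    if n_visits <= 2 or config.dropout_prob == 0.0:
        return n_visits
    p = config.dropout_prob
    if frailty != 0.0:
        logit = np.log(p / (1 - p)) + frailty
        p = 1.0 / (1.0 + np.exp(-logit))
    for k in range(2, n_visits):
        if rng.random() < p:
            return k
    return n_visits


def simulate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a full synthetic study.

    Returns the long-format visit table and a sidecar dict with the
    generative truth (parameters, realized centering constants, seed) for
    parameter-recovery testing.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    participants = _draw_participants(config, rng)

    records = []
    for p in participants:
        times = _visit_times(p, config, rng)
        frailty = rng.normal(0.0, config.frailty_sd) if config.frailty_sd > 0 else 0.0
        keep = _attended(len(times), config, rng, frailty) if p.arm != PASSIVE_CTRL else len(times)
        records.extend(design.derive_training_covariates(p, times)[:keep])

    frame = records_to_frame(participants, records)
    # centering constants from the realized sample, as the analysis does
    group_mean_age = frame.groupby("age_group")["age_years"].mean().to_dict()
    icv_mean = float(np.mean([p.icv_baseline for p in participants]))

    n_rows = len(frame)
    cp = config.slope_coupling
    hp = config.hippocampus

    # per-subject bookkeeping (subjects in participant order: P0001, ...)
    pid = frame["participant_id"].to_numpy()
    subj, _ = pd.factorize(pid, sort=True)
    n_subj = len(participants)
    by_p = {p.participant_id: p for p in participants}
    order = sorted(by_p)
    older_s = np.array([by_p[k].age_group == OLDER for k in order], dtype=float)
    male_s = np.array([by_p[k].sex == "M" for k in order], dtype=float)
    trained_s = np.array([by_p[k].arm != PASSIVE_CTRL for k in order], dtype=float)
    icv_s = np.array([by_p[k].icv_baseline for k in order], dtype=float)
    t = frame["t_years"].to_numpy(float)
    is_fu = (frame["status"] == design.STATUS_LONG_TERM).to_numpy() | (
        (frame["arm"] == PASSIVE_CTRL).to_numpy() & (frame["visit_index"].to_numpy() > 0)
    )

    if cp is not None:
        z = rng.standard_normal((n_subj, 2))
        s_a = cp.mean_a + cp.sd_a * z[:, 0]
        s_b = cp.mean_b + cp.sd_b * (cp.rho * z[:, 0] + np.sqrt(1 - cp.rho**2) * z[:, 1])
        lvl_a = rng.normal(cp.level_mean_a, cp.level_sd_a, n_subj)
        lvl_b = rng.normal(cp.level_mean_b, cp.level_sd_b, n_subj)
        # plateau at each subject's last intervention visit after follow-up
        t_train = np.where(is_fu, -np.inf, t)
        t_end = np.full(n_subj, 0.0)
        np.maximum.at(t_end, subj, t_train)
        t_end[~np.isfinite(t_end)] = 0.0
        t_eff = np.where(is_fu, t_end[subj], t)
        mem = lvl_a[subj] + s_a[subj] * t_eff + rng.normal(0, cp.resid_a, n_rows)
        wp = lvl_b[subj] + s_b[subj] * t_eff + rng.normal(0, cp.resid_b, n_rows)
        truth_slopes = {"a": s_a, "b": s_b}
    else:
        from .retention import _Design

        des = _Design(frame.assign(**{"memory_score": 0.0}), "memory_score", group_mean_age)
        mem = (
            des.mean(config.retention)
            + rng.normal(0.0, config.retention.sigma_b, n_subj)[subj]
            + rng.normal(0.0, config.retention.sigma_e, n_rows)
        )
        wp = (
            des.mean(config.transfer)
            + rng.normal(0.0, config.transfer.sigma_b, n_subj)[subj]
            + rng.normal(0.0, config.transfer.sigma_e, n_rows)
        )
        truth_slopes = None

    # hippocampal volume: linear mixed model with random intercept + slope
    b0 = rng.normal(0.0, hp.sd_intercept, n_subj)
    b1 = rng.normal(0.0, hp.sd_slope, n_subj)
    base_slope = np.where(older_s == 1, hp.slope.older, hp.slope.young)
    diff_slope = np.where(
        older_s == 1,
        hp.longterm_diff.older / config.followup_mean.older,
        hp.longterm_diff.young / config.followup_mean.young,
    )
    slope_s = base_slope + b1 + trained_s * diff_slope
    status = frame["status"].to_numpy()
    older_r = older_s[subj]
    theta = np.where(
        status == design.STATUS_POST_TRAIN,
        np.where(older_r == 1, hp.theta_post_train.older, hp.theta_post_train.young),
        np.where(
            status == design.STATUS_POST_REST,
            np.where(older_r == 1, hp.theta_post_rest.older, hp.theta_post_rest.young),
            0.0,
        ),
    )
    hip = (
        np.where(older_r == 1, hp.intercept.older, hp.intercept.young)
        + hp.icv_coef * (icv_s[subj] - icv_mean)
        + hp.sex_effect * male_s[subj]
        + b0[subj]
        + slope_s[subj] * t
        + theta
        + rng.normal(0.0, hp.sd_resid, n_rows)
    )
    icv_col = icv_s[subj]  # ICV is anatomically stable

    mem_r = np.clip(np.round(mem), 0, 100)
    wp_r = np.clip(np.round(wp), 0, 36)
    clamped = int(np.sum(np.round(mem) != mem_r) + np.sum(np.round(wp) != wp_r))
    frac = clamped / (2 * n_rows) if n_rows else 0.0
    if frac > config.clamp_warn_frac:
        logger.warning(
            "score clamping activated on %.1f%% of scores; the generative "
            "configuration may be implausible", 100 * frac,
        )

    frame["memory_score"] = mem_r
    frame["wordpair_score"] = wp_r
    frame["hippocampus_mm3"] = np.round(hip, 1)
    frame["icv_mm3"] = np.round(icv_col, 0)

    # word-pair task introduced late for some participants
    if config.wordpair_missing_prob > 0:
        for pid in frame["participant_id"].unique():
            if rng.random() < config.wordpair_missing_prob:
                idx = frame.index[frame["participant_id"] == pid][:2]
                frame.loc[idx, "wordpair_score"] = np.nan

    truth = {
        "seed": int(seed),
        "latent_slopes": (
            None
            if truth_slopes is None
            else {
                "participant_id": order,
                "a": truth_slopes["a"].tolist(),
                "b": truth_slopes["b"].tolist(),
            }
        ),
        "retention": dataclasses.asdict(config.retention),
        "transfer": dataclasses.asdict(config.transfer),
        "hippocampus": dataclasses.asdict(config.hippocampus),
        "slope_coupling": dataclasses.asdict(cp) if cp is not None else None,
        "group_mean_age": {k: float(v) for k, v in group_mean_age.items()},
        "icv_mean": icv_mean,
        "longterm_slope_diff": {
            g: config.hippocampus.longterm_diff.get(g) / config.followup_mean.get(g)
            for g in (YOUNG, OLDER)
        },
        "clamped_fraction": frac,
    }
    return frame, truth


def config_from_dict(payload: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML/JSON) mapping.

    Nested sections (retention, transfer, hippocampus, slope_coupling and
    the (young, older) pairs) may be given partially; unspecified values
    keep the ``paper_defaults`` preset values.
    """
    base = paper_defaults()
    payload = dict(payload or {})
    kwargs = {}
    for f in dataclasses.fields(CohortConfig):
        if f.name not in payload:
            continue
        value = payload[f.name]
        default = getattr(base, f.name)
        if isinstance(default, GroupValue):
            value = GroupValue(**value) if isinstance(value, dict) else GroupValue(*value)
        elif isinstance(default, RetentionParams):
            value = dataclasses.replace(default, **value)
        elif isinstance(default, HippocampusParams):
            sub = {
                k: (GroupValue(**v) if isinstance(v, dict) else GroupValue(*v))
                if isinstance(getattr(default, k), GroupValue)
                else v
                for k, v in value.items()
            }
            value = dataclasses.replace(default, **sub)
        elif f.name == "slope_coupling" and value is not None:
            value = SlopeCoupling(**value)
        elif isinstance(default, tuple):
            value = tuple(value)
        kwargs[f.name] = value
    return dataclasses.replace(base, **kwargs)


def write_visits_csv(frame: pd.DataFrame, path) -> None:
    """Write the long-format table; missing values as empty fields."""
    frame.to_csv(path, index=False, float_format="%.6g", columns=VISIT_COLUMNS)


def read_visits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
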
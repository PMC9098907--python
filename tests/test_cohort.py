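"""Synthetic-cohort generator: determinism, calibration, coupling."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

import memtrain as mt
from memtrain import cohort as cohort_mod
from memtrain.retention import _Design

from conftest import noiseless_config


def test_deterministic_output(small_config):
    frames = []
    for _ in range(2):
        frame, _ = mt.simulate_cohort(small_config, seed=42)
        buf = io.StringIO()
        cohort_mod.write_visits_csv(frame, buf)
        frames.append(buf.getvalue())
    assert frames[0] == frames[1]


def test_paper_defaults_design(paper_cohort):
    frame, _ = paper_cohort
    trainers = frame[frame.arm != "PASSIVE_CTRL"]
    passive = frame[frame.arm == "PASSIVE_CTRL"]
    assert trainers.participant_id.nunique() == 157
    assert passive.participant_id.nunique() == 83
    assert frame.groupby("participant_id").size().max() <= 6
    assert (passive.groupby("participant_id").size() == 2).all()
    young = trainers[trainers.age_group == "young"]
    assert young.participant_id.nunique() == 57


def test_dropout_is_monotone(paper_cohort):
    frame, _ = paper_cohort
    for _, sub in frame.groupby("participant_id"):
        idx = sub.visit_index.to_numpy()
        assert (idx == np.arange(len(idx))).all()


def test_marginal_moments(paper_config):
    """Simulated baseline scores and volumes match the configured
    generative moments within Monte-Carlo error (z-test at n=1000)."""
    cfg = dataclasses.replace(
        paper_config,
        n_abab=(250, 250), n_baba=(250, 250), n_active_ctrl=(0, 0),
        n_passive=(0, 0), dropout_prob=0.0,
        retention=dataclasses.replace(
            paper_config.retention, delta_young=0.0, delta_older=0.0
        ),
    )
    frame, truth = mt.simulate_cohort(cfg, seed=9)
    base = frame[(frame.visit_index == 0)]
    for group in ("young", "older"):
        sub = base[base.age_group == group]
        n = len(sub)
        p = cfg.retention
        expect = p.mu + p.alpha_older * (group == "older") + p.gamma_sex * (
            sub.sex == "M"
        ).mean()
        sd = np.hypot(p.sigma_b, p.sigma_e)
        z = (sub.memory_score.mean() - expect) / (sd / np.sqrt(n))
        assert abs(z) < 4
        hp = cfg.hippocampus
        expect_v = hp.intercept.get(group) + hp.sex_effect * (sub.sex == "M").mean()
        sd_v = np.hypot(
            np.hypot(hp.sd_intercept, hp.sd_resid), hp.icv_coef * cfg.icv_sd.get(group)
        )
        zv = (sub.hippocampus_mm3.mean() - expect_v) / (sd_v / np.sqrt(n))
        assert abs(zv) < 4
        # SD calibration within 10%
        assert sub.memory_score.std() == pytest.approx(sd, rel=0.15)
        assert sub.hippocampus_mm3.std() == pytest.approx(sd_v, rel=0.15)


def test_noiseless_scores_equal_model_mean(noiseless_cohort, small_config):
    frame, truth = noiseless_cohort
    cfg = noiseless_config(small_config)
    des = _Design(frame.assign(memory_score=0.0), "memory_score",
                  truth["group_mean_age"])
    expected = des.mean(cfg.retention)
    assert np.array_equal(frame.memory_score.to_numpy(float), expected)
    # hippocampal volumes equal the linear-model mean up to output rounding
    hp = cfg.hippocampus
    base = np.where(frame.age_group == "older", hp.intercept.older, hp.intercept.young)
    slope = np.where(frame.age_group == "older", hp.slope.older, hp.slope.young)
    diff = np.where(
        frame.age_group == "older",
        hp.longterm_diff.older / cfg.followup_mean.older,
        hp.longterm_diff.young / cfg.followup_mean.young,
    ) * (frame.arm != "PASSIVE_CTRL")
    theta = np.where(
        frame.status == "post_train",
        np.where(frame.age_group == "older", hp.theta_post_train.older,
                 hp.theta_post_train.young),
        np.where(
            frame.status == "post_rest",
            np.where(frame.age_group == "older", hp.theta_post_rest.older,
                     hp.theta_post_rest.young),
            0.0,
        ),
    )
    expected_v = base + (slope + diff) * frame.t_years.to_numpy(float) + theta
    assert np.allclose(frame.hippocampus_mm3, expected_v, atol=0.06)


def test_zero_training_effect_leaves_only_retest(small_config):
    """With beta1 = beta2 = 0 the post-training vs baseline mean gap
    estimates the configured retest effect across seeds."""
    p = dataclasses.replace(
        small_config.retention,
        beta1_young=0.0, beta1_older=0.0, beta2_young=0.0, beta2_older=0.0,
        delta_young=0.0, delta_older=0.0,
    )
    cfg = dataclasses.replace(small_config, retention=p, dropout_prob=0.0)
    diffs = []
    for seed in range(25):
        frame, _ = mt.simulate_cohort(cfg, seed=1000 + seed)
        trainers = frame[frame.arm != "PASSIVE_CTRL"]
        first = trainers[trainers.retest == 0].memory_score.mean()
        later = trainers[trainers.retest == 1].memory_score.mean()
        diffs.append(later - first)
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - p.rho_retest) < 4 * se + 0.05


def test_clamping_warning_logged(small_config, caplog):
    wild = dataclasses.replace(
        small_config.retention, mu=95.0, beta1_young=30.0, beta2_young=30.0
    )
    cfg = dataclasses.replace(small_config, retention=wild)
    with caplog.at_level("WARNING", logger="memtrain.cohort"):
        mt.simulate_cohort(cfg, seed=0)
    assert any("clamping" in r.message for r in caplog.records)


class TestSlopeCoupling:
    def test_latent_correlation_matches_target(self, paper_config):
        cfg = mt.induce_slope_correlation(
            dataclasses.replace(
                paper_config, n_abab=(300, 0), n_baba=(300, 0),
                n_active_ctrl=(0, 0), n_passive=(0, 0), dropout_prob=0.0,
            ),
            rho=0.42,
        )
        _, truth = mt.simulate_cohort(cfg, seed=3)
        a = np.asarray(truth["latent_slopes"]["a"])
        b = np.asarray(truth["latent_slopes"]["b"])
        assert len(a) >= 500
        assert abs(np.corrcoef(a, b)[0, 1] - 0.42) < 0.05

    def test_perfect_coupling_is_proportional(self, small_config):
        cfg = mt.induce_slope_correlation(small_config, rho=1.0)
        _, truth = mt.simulate_cohort(cfg, seed=4)
        a = np.asarray(truth["latent_slopes"]["a"])
        b = np.asarray(truth["latent_slopes"]["b"])
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_independent_slopes_uncorrelated(self, paper_config):
        cfg = mt.induce_slope_correlation(
            dataclasses.replace(
                paper_config, n_abab=(400, 0), n_baba=(400, 0),
                n_active_ctrl=(0, 0), n_passive=(0, 0),
            ),
            rho=0.0,
        )
        _, truth = mt.simulate_cohort(cfg, seed=6)
        a = np.asarray(truth["latent_slopes"]["a"])
        b = np.asarray(truth["latent_slopes"]["b"])
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1

    def test_invalid_coupling_rejected(self, small_config):
        with pytest.raises(ValueError):
            mt.induce_slope_correlation(small_config, rho=1.5)
        with pytest.raises(ValueError):
            mt.induce_slope_correlation(small_config, rho=0.3, sd_a=0.0)


def test_config_from_dict_partial_override(paper_config):
    cfg = cohort_mod.config_from_dict(
        {
            "n_abab": [5, 6],
            "retention": {"beta1_young": 12.0},
            "hippocampus": {"theta_post_train": [1.0, 2.0]},
            "slope_coupling": {"rho": 0.3},
        }
    )
    assert cfg.n_abab == (5, 6)
    assert cfg.retention.beta1_young == 12.0
    assert cfg.retention.beta2_young == paper_config.retention.beta2_young
    assert cfg.hippocampus.theta_post_train.older == 2.0
    assert cfg.slope_coupling.rho == 0.3
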
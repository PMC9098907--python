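"""Retention model: mean function, marginal likelihood, ML fitting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import multivariate_normal, norm

import memtrain as mt
from memtrain.retention import PARAM_NAMES, RetentionParams, _Design

from conftest import noiseless_config


def _random_frame(rng, n_subjects=3, n_visits=4):
    """A small arbitrary visit table with valid covariates."""
    rows = []
    for i in range(n_subjects):
        group = "young" if i % 2 == 0 else "older"
        sex = "F" if rng.random() < 0.5 else "M"
        age0 = 25.0 + i if group == "young" else 72.0 + i
        for v in range(n_visits):
            n_tr = min(v, 2)
            rows.append(
                {
                    "participant_id": f"s{i}",
                    "age_group": group,
                    "sex": sex,
                    "arm": "ABAB",
                    "visit_index": v,
                    "t_years": 0.21 * v,
                    "age_years": age0 + 0.21 * v,
                    "delta_t_years": 0.0 if n_tr == 0 else rng.uniform(0, 2),
                    "n_trainings": n_tr,
                    "x1": int(n_tr == 1),
                    "x2": int(n_tr == 2),
                    "retest": int(v > 0),
                    "status": "baseline",
                    "memory_score": float(rng.normal(20, 5)),
                    "wordpair_score": np.nan,
                    "hippocampus_mm3": np.nan,
                    "icv_mm3": np.nan,
                }
            )
    return pd.DataFrame(rows)


def _random_params(rng):
    return RetentionParams(
        mu=rng.normal(18, 2), alpha_older=rng.normal(-7, 1),
        gamma_sex=rng.normal(0, 1),
        beta1_young=rng.normal(15, 2), beta1_older=rng.normal(7, 1),
        beta2_young=rng.normal(18, 2), beta2_older=rng.normal(8, 1),
        lambda_young=rng.uniform(0.05, 1.0), lambda_older=rng.uniform(0.05, 1.0),
        rho_retest=rng.normal(2, 1), delta_young=rng.normal(0, 0.2),
        delta_older=rng.normal(-0.5, 0.2),
        sigma_b=rng.uniform(1, 4), sigma_e=rng.uniform(1, 4),
    )


class TestDecayMultiplier:
    @pytest.mark.parametrize("lam", [0.0, 0.05, 0.4, 2.0, 10.0])
    def test_unity_at_zero_delta_t(self, lam):
        assert mt.decay_multiplier(lam, 0.0) == 1.0

    def test_closed_form(self):
        assert mt.decay_multiplier(0.2, 3.0) == pytest.approx(np.exp(-0.6))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mt.decay_multiplier(-0.1, 1.0)


class TestRetentionMean:
    def test_immediate_first_training_effect(self):
        """At delta_t = 0 the decay multiplier is 1, so the mean is the
        baseline plus the full immediate effect."""
        p = RetentionParams(mu=10.0, beta1_young=17.6, lambda_young=0.7,
                            sigma_b=1, sigma_e=1)
        visit = dict(age_group="young", sex="F", x1=1, x2=0, delta_t=0.0,
                     retest=0, age_years=None)
        assert mt.retention_mean(p, visit, 26.0) == pytest.approx(10.0 + 17.6)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 3.0])
    def test_untrained_rows_have_no_training_term(self, lam):
        p = RetentionParams(mu=12.0, beta1_young=9.0, beta2_young=9.0,
                            lambda_young=lam, sigma_b=1, sigma_e=1)
        visit = dict(age_group="young", sex="F", x1=0, x2=0, delta_t=None,
                     retest=0, age_years=None)
        assert mt.retention_mean(p, visit, 26.0) == pytest.approx(12.0)

    def test_decayed_effect_closed_form(self):
        p = RetentionParams(mu=0.0, beta1_young=10.0, lambda_young=0.2,
                            sigma_b=1, sigma_e=1)
        visit = dict(age_group="young", sex="F", x1=1, x2=0, delta_t=3.0,
                     retest=0, age_years=None)
        assert mt.retention_mean(p, visit, 26.0) == pytest.approx(
            10.0 * np.exp(-0.6)
        )

    def test_undefined_delta_t_after_training_rejected(self):
        p = RetentionParams(mu=0.0, beta1_young=10.0, sigma_b=1, sigma_e=1)
        visit = dict(age_group="young", sex="F", x1=1, x2=0, delta_t=None,
                     retest=0, age_years=None)
        with pytest.raises(ValueError):
            mt.retention_mean(p, visit, 26.0)


class TestMarginalLoglik:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_multivariate_normal(self, seed):
        """Compound-symmetry likelihood equals a brute-force per-subject
        multivariate-normal construction to 1e-8 relative tolerance."""
        rng = np.random.default_rng(seed)
        frame = _random_frame(rng, n_subjects=5, n_visits=4)
        params = _random_params(rng)
        des = _Design(frame, "memory_score")
        ll = mt.nlmm_marginal_loglik(params, frame)
        oracle = 0.0
        for _, sub in frame.groupby("participant_id"):
            sub_des = _Design(sub, "memory_score", des.group_mean_age)
            m = sub_des.mean(params)
            n = len(sub)
            cov = params.sigma_b**2 * np.ones((n, n)) + params.sigma_e**2 * np.eye(n)
            oracle += multivariate_normal.logpdf(
                sub.memory_score.to_numpy(float), m, cov
            )
        assert ll == pytest.approx(oracle, rel=1e-8)

    def test_single_visit_collapses_to_univariate(self):
        rng = np.random.default_rng(5)
        frame = _random_frame(rng, n_subjects=1, n_visits=1)
        params = _random_params(rng)
        des = _Design(frame, "memory_score")
        m = des.mean(params)[0]
        sd = np.hypot(params.sigma_b, params.sigma_e)
        assert mt.nlmm_marginal_loglik(params, frame) == pytest.approx(
            norm.logpdf(frame.memory_score.iloc[0], m, sd)
        )

    def test_independence_limit(self):
        """sigma_b -> 0 gives a sum of independent normal densities."""
        rng = np.random.default_rng(7)
        frame = _random_frame(rng)
        params = dataclasses.replace(_random_params(rng), sigma_b=1e-9)
        des = _Design(frame, "memory_score")
        m = des.mean(params)
        indep = norm.logpdf(
            frame.memory_score.to_numpy(float), m, params.sigma_e
        ).sum()
        assert mt.nlmm_marginal_loglik(params, frame) == pytest.approx(indep)

    def test_missing_outcomes_dropped_rowwise(self):
        rng = np.random.default_rng(8)
        frame = _random_frame(rng)
        frame.loc[2, "memory_score"] = np.nan
        params = _random_params(rng)
        ll = mt.nlmm_marginal_loglik(params, frame)
        ll_sub = mt.nlmm_marginal_loglik(
            params, frame[frame.memory_score.notna()],
        )
        assert ll == pytest.approx(ll_sub)

    def test_nonfinite_covariates_rejected(self):
        rng = np.random.default_rng(9)
        frame = _random_frame(rng)
        frame.loc[1, "delta_t_years"] = np.nan  # trained row without delta_t
        with pytest.raises(ValueError):
            mt.nlmm_marginal_loglik(_random_params(rng), frame)

    def test_analytic_gradient(self):
        rng = np.random.default_rng(11)
        frame = _random_frame(rng, n_subjects=6)
        des = _Design(frame, "memory_score")
        vec = _random_params(rng).to_unconstrained()
        _, g = des.loglik_and_grad(vec)
        g_num = approx_fprime(vec, lambda v: des.loglik_and_grad(v)[0], 1e-6)
        assert np.allclose(g, g_num, rtol=1e-4, atol=1e-5)


class TestFit:
    def test_noiseless_recovery(self, noiseless_cohort, small_config):
        frame, _ = noiseless_cohort
        truth = noiseless_config(small_config).retention
        m = mt.RetentionModel(compute_se=False).fit(frame)
        for name in ("mu", "alpha_older", "beta1_young", "beta1_older",
                     "beta2_young", "beta2_older", "rho_retest"):
            assert getattr(m.params_, name) == pytest.approx(
                getattr(truth, name), abs=1e-3
            )

    def test_fit_is_deterministic(self, small_cohort):
        frame, _ = small_cohort
        a = mt.RetentionModel(compute_se=False).fit(frame)
        b = mt.RetentionModel(compute_se=False).fit(frame)
        assert a.params_ == b.params_
        assert a.loglik_ == b.loglik_

    def test_outcome_shift_moves_only_intercept(self, small_cohort):
        frame, _ = small_cohort
        a = mt.RetentionModel(compute_se=False).fit(frame)
        shifted = frame.assign(memory_score=frame.memory_score + 7.0)
        b = mt.RetentionModel(compute_se=False).fit(shifted)
        assert b.params_.mu == pytest.approx(a.params_.mu + 7.0, abs=1e-3)
        for name in PARAM_NAMES:
            if name == "mu":
                continue
            assert getattr(b.params_, name) == pytest.approx(
                getattr(a.params_, name), abs=2e-3
            )

    def test_time_rescaling_rescales_decay(self, paper_config):
        """Measuring time in units of k years divides lambda by k
        (the training effect itself is unchanged)."""
        # strong decay in both groups so lambda is well-identified
        retention = dataclasses.replace(
            paper_config.retention, lambda_young=0.5, lambda_older=0.6,
            beta1_older=12.0, beta2_older=14.0,
        )
        cfg = dataclasses.replace(
            paper_config, retention=retention,
            n_abab=(40, 40), n_baba=(30, 30), n_active_ctrl=(0, 0),
            n_passive=(0, 0), dropout_prob=0.0,
        )
        frame, _ = mt.simulate_cohort(cfg, seed=21)
        a = mt.RetentionModel(compute_se=False).fit(frame)
        k = 2.0
        scaled = frame.assign(
            t_years=frame.t_years * k,
            delta_t_years=frame.delta_t_years * k,
            age_years=frame.age_years,  # age covariate kept in true years
        )
        b = mt.RetentionModel(compute_se=False).fit(scaled)
        assert b.params_.lambda_young == pytest.approx(
            a.params_.lambda_young / k, rel=1e-2
        )
        assert b.params_.lambda_older == pytest.approx(
            a.params_.lambda_older / k, rel=1e-2
        )
        assert b.params_.beta1_young == pytest.approx(
            a.params_.beta1_young, rel=1e-2
        )

    def test_inclusion_filter(self):
        """Participants need >= 2 outcome visits and >= 1 completed
        training; passive controls never qualify."""
        rng = np.random.default_rng(13)
        frame = _random_frame(rng, n_subjects=6, n_visits=4)
        frame.loc[frame.participant_id == "s0", "memory_score"] = np.nan
        one_visit = frame.participant_id == "s1"
        frame.loc[one_visit & (frame.visit_index > 0), "memory_score"] = np.nan
        passive = frame.participant_id == "s2"
        frame.loc[passive, "arm"] = "PASSIVE_CTRL"
        m = mt.RetentionModel(compute_se=False)
        kept, n_excluded = m._filter(frame)
        assert set(kept.participant_id) == {"s3", "s4", "s5"}
        assert n_excluded == 2  # s0 drops out before counting; s1, s2 counted

    def test_predict_matches_retention_mean(self, small_cohort):
        frame, _ = small_cohort
        m = mt.RetentionModel(compute_se=False).fit(frame)
        sub = frame[frame.memory_score.notna()].head(8)
        pred = m.predict(sub)
        for (_, row), p_hat in zip(sub.iterrows(), pred):
            gma = m.group_mean_age_[row.age_group]
            assert p_hat == pytest.approx(
                mt.retention_mean(m.params_, row, gma)
            )

    def test_wald_intervals_bracket_estimates(self, small_cohort):
        frame, _ = small_cohort
        m = mt.RetentionModel().fit(frame)
        est = np.array([getattr(m.params_, n) for n in PARAM_NAMES])
        assert (m.conf_int_["low"].to_numpy() <= est).all()
        assert (est <= m.conf_int_["high"].to_numpy()).all()
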
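"""Nonlinear mixed model for training effects on memory with exponential decay.

The expected score of participant *i* (age group *g*, sex *s*) at a visit is

    mu + alpha_older*I(g=older) + gamma_sex*I(s=M)
       + (x1*beta1_g + x2*beta2_g) * exp(-lambda_g * delta_t)
       + rho_retest * retest
       + delta_g * (age_at_visit - mean_age_g)

where x1/x2 indicate exactly one / exactly two completed training periods,
delta_t is the time since the last completed training, and lambda_g >= 0 is
a per-age-group decay rate, so beta1_g/beta2_g are the *immediate* effects
of the first and second training (the decay multiplier is exactly 1 at
delta_t = 0).  A per-participant random intercept (SD sigma_b) induces a
compound-symmetry covariance sigma_b^2 * J + sigma_e^2 * I within subject;
the marginal Gaussian likelihood is maximized (ML) over all parameters with
lambda and the SDs optimized on the log scale.

Wald standard errors come from the observed information (numerical Hessian
of the negative log-likelihood), mapped to the natural scale by the delta
method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .design import OLDER, TRAINING_ARMS, YOUNG

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class RetentionParams:
    """All parameters of the retention model (score units = words/pairs)."""

    mu: float = 0.0  # grand intercept (young, female, never trained)
    alpha_older: float = 0.0  # older-group main effect
    gamma_sex: float = 0.0  # male main effect
    beta1_young: float = 0.0  # immediate effect of first training
    beta1_older: float = 0.0
    beta2_young: float = 0.0  # immediate effect of second training
    beta2_older: float = 0.0
    lambda_young: float = 0.0  # decay rates, 1/years (>= 0)
    lambda_older: float = 0.0
    rho_retest: float = 0.0  # prior-exposure (retest) effect
    delta_young: float = 0.0  # within-study ageing slope, per group
    delta_older: float = 0.0
    sigma_b: float = 1.0  # random-intercept SD (> 0)
    sigma_e: float = 1.0  # residual SD (> 0)

    def __post_init__(self) -> None:
        if self.lambda_young < 0 or self.lambda_older < 0:
            raise ValueError("decay rates must be non-negative")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("sigma_b and sigma_e must be non-negative")

    def to_unconstrained(self) -> np.ndarray:
        """Pack into the optimizer vector (log scale for lambda and SDs)."""
        v = [getattr(self, f.name) for f in fields(self)]
        out = np.asarray(v, dtype=float)
        for k in _LOG_IDX:
            out[k] = np.log(max(out[k], 1e-12))
        return out

    @classmethod
    def from_unconstrained(cls, vec: np.ndarray) -> "RetentionParams":
        vec = np.asarray(vec, dtype=float)
        vals = vec.copy()
        for k in _LOG_IDX:
            vals[k] = np.exp(vals[k])
        return cls(**dict(zip(PARAM_NAMES, vals)))


PARAM_NAMES = [f.name for f in fields(RetentionParams)]
_LOG_IDX = [
    PARAM_NAMES.index(n)
    for n in ("lambda_young", "lambda_older", "sigma_b", "sigma_e")
]


def decay_multiplier(lam: float, delta_t) -> np.ndarray:
    """Retention multiplier exp(-lambda * delta_t); exactly 1 at delta_t = 0."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return np.exp(-lam * np.asarray(delta_t, dtype=float))


def retention_mean(
    params: RetentionParams, visit, group_mean_age: float
) -> float:
    """Expected score for one visit record (see module docstring).

    ``visit`` may be a :class:`~memtrain.design.VisitRecord` paired with a
    participant via its ``age_years`` field plus an ``age_group``/``sex``
    attribute lookup, or any object/row with attributes ``x1, x2, delta_t,
    retest, age_years, age_group, sex``.
    """
    get = lambda name, default=None: getattr(
        visit, name, visit.get(name, default) if hasattr(visit, "get") else default
    )
    age_group = get("age_group", YOUNG)
    older = age_group == OLDER
    x1 = float(get("x1", 0) or 0)
    x2 = float(get("x2", 0) or 0)
    delta_t = get("delta_t", get("delta_t_years"))
    n_tr = x1 + x2
    if n_tr > 0:
        if delta_t is None or not math.isfinite(float(delta_t)):
            raise ValueError("delta_t undefined for a visit after training")
        delta_t = float(delta_t)
    else:
        delta_t = 0.0
    lam = params.lambda_older if older else params.lambda_young
    b1 = params.beta1_older if older else params.beta1_young
    b2 = params.beta2_older if older else params.beta2_young
    dlt = params.delta_older if older else params.delta_young
    male = get("sex", "F") == "M"
    age = get("age_years", get("age"))
    age_c = 0.0 if age is None else float(age) - group_mean_age
    return (
        params.mu
        + params.alpha_older * older
        + params.gamma_sex * male
        + (x1 * b1 + x2 * b2) * float(decay_multiplier(lam, delta_t))
        + params.rho_retest * float(get("retest", 0) or 0)
        + dlt * age_c
    )


# ---------------------------------------------------------------------------
# vectorized design + likelihood


class _Design:
    """Pre-extracted numpy arrays for fast repeated likelihood evaluation."""

    def __init__(self, frame: pd.DataFrame, outcome: str,
                 group_mean_age: Optional[Mapping[str, float]] = None):
        frame = frame.reset_index(drop=True)
        self.frame = frame
        self.y = frame[outcome].to_numpy(dtype=float)
        self.older = (frame["age_group"] == OLDER).to_numpy(dtype=float)
        self.male = (frame["sex"] == "M").to_numpy(dtype=float)
        self.x1 = frame["x1"].to_numpy(dtype=float)
        self.x2 = frame["x2"].to_numpy(dtype=float)
        dt = frame["delta_t_years"].to_numpy(dtype=float)
        trained = (self.x1 + self.x2) > 0
        if np.any(trained & ~np.isfinite(dt)):
            raise ValueError("delta_t undefined for a visit after training")
        self.dt = np.where(trained, dt, 0.0)
        self.retest = frame["retest"].to_numpy(dtype=float)
        if group_mean_age is None:
            age = frame["age_years"].to_numpy(dtype=float)
            group_mean_age = {
                YOUNG: float(age[self.older == 0].mean()) if (self.older == 0).any() else 0.0,
                OLDER: float(age[self.older == 1].mean()) if (self.older == 1).any() else 0.0,
            }
        self.group_mean_age = dict(group_mean_age)
        centers = np.where(
            self.older == 1, self.group_mean_age[OLDER], self.group_mean_age[YOUNG]
        )
        self.age_c = frame["age_years"].to_numpy(dtype=float) - centers
        cols = np.stack([self.older, self.male, self.x1, self.x2, self.dt,
                         self.retest, self.age_c])
        if not np.all(np.isfinite(cols)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite covariates or outcomes in the data")
        codes, _ = pd.factorize(frame["participant_id"], sort=True)
        self.subject = codes
        self.n_subjects = int(codes.max()) + 1 if len(codes) else 0
        self.n_per = np.bincount(codes, minlength=self.n_subjects).astype(float)

    def resampled(self, draw: np.ndarray, y: Optional[np.ndarray] = None) -> "_Design":
        """Design for a case-bootstrap resample of subjects (no DataFrame).

        ``draw`` holds subject indices (with repetition); each drawn
        subject keeps its full visit history and becomes a new subject.
        """
        subj_rows = self._subject_rows()
        rows = np.concatenate([subj_rows[s] for s in draw])
        new = object.__new__(_Design)
        new.frame = None
        src = self.y if y is None else y
        new.y = src[rows]
        for name in ("older", "male", "x1", "x2", "dt", "retest", "age_c"):
            setattr(new, name, getattr(self, name)[rows])
        lengths = np.array([len(subj_rows[s]) for s in draw])
        new.subject = np.repeat(np.arange(len(draw)), lengths)
        new.n_subjects = len(draw)
        new.n_per = lengths.astype(float)
        new.group_mean_age = self.group_mean_age
        return new

    def _subject_rows(self) -> list[np.ndarray]:
        if not hasattr(self, "_subj_rows"):
            order = np.argsort(self.subject, kind="stable")
            splits = np.cumsum(self.n_per.astype(int))[:-1]
            self._subj_rows = np.split(order, splits)
        return self._subj_rows

    def mean(self, p: RetentionParams) -> np.ndarray:
        b1 = np.where(self.older == 1, p.beta1_older, p.beta1_young)
        b2 = np.where(self.older == 1, p.beta2_older, p.beta2_young)
        lam = np.where(self.older == 1, p.lambda_older, p.lambda_young)
        dlt = np.where(self.older == 1, p.delta_older, p.delta_young)
        return (
            p.mu
            + p.alpha_older * self.older
            + p.gamma_sex * self.male
            + (self.x1 * b1 + self.x2 * b2) * np.exp(-lam * self.dt)
            + p.rho_retest * self.retest
            + dlt * self.age_c
        )

    def loglik(self, p: RetentionParams) -> float:
        """Marginal log-likelihood under compound symmetry per subject.

        With Sigma_i = sigma_e^2 I + sigma_b^2 J the Sherman-Morrison
        identity gives a closed form per subject, avoiding any matrix
        factorization.
        """
        if p.sigma_e <= 0:
            raise ValueError("sigma_e must be positive to evaluate the likelihood")
        r = self.y - self.mean(p)
        s2e = p.sigma_e**2
        s2b = p.sigma_b**2
        sum_r = np.bincount(self.subject, weights=r, minlength=self.n_subjects)
        sum_r2 = np.bincount(self.subject, weights=r * r, minlength=self.n_subjects)
        denom = s2e + self.n_per * s2b
        quad = (sum_r2 - s2b * sum_r**2 / denom) / s2e
        logdet = (self.n_per - 1.0) * math.log(s2e) + np.log(denom)
        return float(-0.5 * np.sum(self.n_per * _LOG2PI + logdet + quad))

    def loglik_and_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and its analytic gradient in unconstrained space.

        The score uses u = Sigma^-1 r (closed form under compound
        symmetry) for the mean parameters and the identity
        d ll / d v = 0.5 [u' (dSigma/dv) u - tr(Sigma^-1 dSigma/dv)]
        for the variance components, chained through the log
        parameterization of lambda and the SDs.
        """
        p = RetentionParams.from_unconstrained(vec)
        older, x1, x2, dt = self.older, self.x1, self.x2, self.dt
        young = 1.0 - older
        lam = np.where(older == 1, p.lambda_older, p.lambda_young)
        b1 = np.where(older == 1, p.beta1_older, p.beta1_young)
        b2 = np.where(older == 1, p.beta2_older, p.beta2_young)
        E = np.exp(-lam * dt)
        m = (
            p.mu
            + p.alpha_older * older
            + p.gamma_sex * self.male
            + (x1 * b1 + x2 * b2) * E
            + p.rho_retest * self.retest
            + np.where(older == 1, p.delta_older, p.delta_young) * self.age_c
        )
        r = self.y - m
        s2e, s2b = p.sigma_e**2, p.sigma_b**2
        n = self.n_per
        S = np.bincount(self.subject, weights=r, minlength=self.n_subjects)
        SS = np.bincount(self.subject, weights=r * r, minlength=self.n_subjects)
        d = s2e + n * s2b
        w = s2b / d
        quad = (SS - s2b * S**2 / d) / s2e
        logdet = (n - 1.0) * math.log(s2e) + np.log(d)
        ll = float(-0.5 * np.sum(n * _LOG2PI + logdet + quad))

        u = (r - (w * S)[self.subject]) / s2e
        uE1, uE2 = u * x1 * E, u * x2 * E
        dE = -(x1 * b1 + x2 * b2) * dt * E  # d mean / d lambda
        g = np.empty(len(PARAM_NAMES))
        g[0] = u.sum()  # mu
        g[1] = (u * older).sum()  # alpha_older
        g[2] = (u * self.male).sum()  # gamma_sex
        g[3] = (uE1 * young).sum()  # beta1_young
        g[4] = (uE1 * older).sum()  # beta1_older
        g[5] = (uE2 * young).sum()  # beta2_young
        g[6] = (uE2 * older).sum()  # beta2_older
        g[7] = (u * dE * young).sum() * p.lambda_young  # log lambda_young
        g[8] = (u * dE * older).sum() * p.lambda_older  # log lambda_older
        g[9] = (u * self.retest).sum()  # rho_retest
        g[10] = (u * self.age_c * young).sum()  # delta_young
        g[11] = (u * self.age_c * older).sum()  # delta_older
        g_s2b = 0.5 * float(np.sum(S**2 / d**2) - np.sum(n / d))
        g_s2e = 0.5 * float(np.sum(u * u) - np.sum(n * (1.0 - w)) / s2e)
        g[12] = 2.0 * s2b * g_s2b  # log sigma_b
        g[13] = 2.0 * s2e * g_s2e  # log sigma_e
        return ll, g

    def profiled_loglik_and_grad(self, vec: np.ndarray):
        """Concentrated log-likelihood over (mean params, log variance ratio).

        The residual variance s = sigma_e^2 maximizes in closed form given
        the ratio rho = sigma_b^2 / sigma_e^2 (s* = Q/N with Q the
        GLS-weighted residual sum of squares), which removes the
        ill-conditioning of a raw (sigma_b, sigma_e) search and handles
        the zero-noise limit gracefully.  Returns (ll, grad, s*, Q).
        """
        p = RetentionParams.from_unconstrained(np.append(vec[:12], [0.0, 0.0]))
        ratio = math.exp(min(vec[12], 30.0))
        older, x1, x2, dt = self.older, self.x1, self.x2, self.dt
        young = 1.0 - older
        lam = np.where(older == 1, p.lambda_older, p.lambda_young)
        b1 = np.where(older == 1, p.beta1_older, p.beta1_young)
        b2 = np.where(older == 1, p.beta2_older, p.beta2_young)
        E = np.exp(-lam * dt)
        m = (
            p.mu
            + p.alpha_older * older
            + p.gamma_sex * self.male
            + (x1 * b1 + x2 * b2) * E
            + p.rho_retest * self.retest
            + np.where(older == 1, p.delta_older, p.delta_young) * self.age_c
        )
        r = self.y - m
        n = self.n_per
        N = float(n.sum())
        S = np.bincount(self.subject, weights=r, minlength=self.n_subjects)
        SS = np.bincount(self.subject, weights=r * r, minlength=self.n_subjects)
        a = 1.0 + n * ratio
        Q = float(np.sum(SS) - ratio * np.sum(S**2 / a))
        Q = max(Q, 1e-12)
        ll = -0.5 * (N * _LOG2PI + N * math.log(Q / N) + float(np.sum(np.log(a))) + N)

        u = r - ((ratio * S / a)[self.subject])
        scale = N / Q
        uE1, uE2 = u * x1 * E, u * x2 * E
        dE = -(x1 * b1 + x2 * b2) * dt * E
        g = np.empty(13)
        g[0] = u.sum()
        g[1] = (u * older).sum()
        g[2] = (u * self.male).sum()
        g[3] = (uE1 * young).sum()
        g[4] = (uE1 * older).sum()
        g[5] = (uE2 * young).sum()
        g[6] = (uE2 * older).sum()
        g[7] = (u * dE * young).sum() * p.lambda_young
        g[8] = (u * dE * older).sum() * p.lambda_older
        g[9] = (u * self.retest).sum()
        g[10] = (u * self.age_c * young).sum()
        g[11] = (u * self.age_c * older).sum()
        g[:12] *= scale
        dQ_dr = -float(np.sum(S**2 / a**2))
        g[12] = -0.5 * ratio * (float(np.sum(n / a)) + scale * dQ_dr)
        return ll, g, Q / N, Q

    def blups(self, p: RetentionParams) -> tuple[np.ndarray, np.ndarray]:
        """Empirical BLUPs of the random intercepts and conditional residuals."""
        r = self.y - self.mean(p)
        sum_r = np.bincount(self.subject, weights=r, minlength=self.n_subjects)
        shrink = p.sigma_b**2 / (p.sigma_e**2 + self.n_per * p.sigma_b**2)
        b = shrink * sum_r
        e = r - b[self.subject]
        return b, e


def nlmm_marginal_loglik(
    params: RetentionParams,
    data: pd.DataFrame,
    outcome: str = "memory_score",
    group_mean_age: Optional[Mapping[str, float]] = None,
) -> float:
    """Marginal ML log-likelihood of the retention model on a visit table.

    Rows with a missing outcome are dropped (row-wise likelihood
    marginalization); the within-subject covariance is the compound
    symmetry induced by the random intercept.
    """
    frame = data[data[outcome].notna()]
    if frame.empty:
        raise ValueError("no non-missing outcomes")
    return _Design(frame, outcome, group_mean_age).loglik(params)


# ---------------------------------------------------------------------------
# estimator


class RetentionModel(BaseEstimator):
    """ML estimator of the exponential-decay retention model.

    Parameters
    ----------
    outcome : str
        Outcome column ("memory_score" for the criterion task,
        "wordpair_score" for the transfer task).
    lambda_inits : tuple of float
        Multi-start initial decay rates (1/years); the flat-likelihood
        pathology of exponential decay with small effects makes a
        single start unreliable.
    min_visits : int
        Minimum non-missing outcome visits for a participant to enter
        the fit.
    require_training : bool
        Restrict to participants from arms with at least one training
        period (the model's inclusion rule).
    max_iter, tol : optimizer budget and relative log-likelihood tolerance.

    Attributes (after fit)
    ----------------------
    params_ : RetentionParams          point estimates
    se_, conf_int_ : pd.Series / pd.DataFrame   Wald SEs and 95% CIs
    loglik_ : float
    converged_ : bool
    n_subjects_, n_obs_ : int
    n_excluded_ : int                  participants dropped by the filter
    group_mean_age_ : dict             centering constants actually used
    """

    def __init__(
        self,
        outcome: str = "memory_score",
        lambda_inits: Sequence[float] = (0.5, 0.1, 2.0),
        min_visits: int = 2,
        require_training: bool = True,
        max_iter: int = 500,
        tol: float = 1e-8,
        compute_se: bool = True,
    ):
        self.outcome = outcome
        self.lambda_inits = lambda_inits
        self.min_visits = min_visits
        self.require_training = require_training
        self.max_iter = max_iter
        self.tol = tol
        self.compute_se = compute_se

    # -- data preparation ---------------------------------------------------

    def _filter(self, data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        d = data
        if self.require_training:
            d = d[d["arm"].isin(TRAINING_ARMS)]
        eligible = d["participant_id"].nunique()
        d = d[d[self.outcome].notna()]
        counts = d.groupby("participant_id")["visit_index"].count()
        trained = d.groupby("participant_id")["n_trainings"].max()
        keep = counts.index[(counts >= self.min_visits) & (trained >= 1)]
        n_excluded = eligible - keep.size
        if n_excluded:
            logger.info("%d participants excluded by the inclusion rule", n_excluded)
        return d[d["participant_id"].isin(keep)], n_excluded

    def _init_params(self, des: _Design, lam0: float) -> RetentionParams:
        y, older = des.y, des.older == 1
        untrained = (des.x1 + des.x2) == 0
        post = des.dt < 1e-9
        mu0 = float(y[untrained & ~older].mean()) if (untrained & ~older).any() else float(y.mean())
        alpha0 = (float(y[untrained & older].mean()) - mu0) if (untrained & older).any() else 0.0

        def _gain(mask):
            return float(y[mask].mean() - (mu0 + alpha0 * older[mask].mean())) if mask.any() else 5.0

        b1y = _gain((des.x1 == 1) & post & ~older)
        b1o = _gain((des.x1 == 1) & post & older)
        b2y = _gain((des.x2 == 1) & post & ~older)
        b2o = _gain((des.x2 == 1) & post & older)
        sd = float(np.std(y)) or 1.0
        return RetentionParams(
            mu=mu0, alpha_older=alpha0, gamma_sex=0.0,
            beta1_young=b1y, beta1_older=b1o, beta2_young=b2y, beta2_older=b2o,
            lambda_young=lam0, lambda_older=lam0, rho_retest=0.0,
            delta_young=0.0, delta_older=0.0,
            sigma_b=sd / 2.0, sigma_e=sd / 2.0,
        )

    # -- fitting ------------------------------------------------------------

    def _optimize(self, des: _Design, x0: np.ndarray, max_iter: int):
        """Maximize the concentrated likelihood; x0 and result.x are full
        (14-element) unconstrained vectors."""
        p0 = np.append(x0[:12], 2.0 * (x0[12] - x0[13]))  # log variance ratio

        def nll(vec: np.ndarray):
            ll, g, _, _ = des.profiled_loglik_and_grad(np.clip(vec, -40.0, 40.0))
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(g)
            return -ll, -g

        res = optimize.minimize(
            nll, p0, method="L-BFGS-B", jac=True,
            bounds=[(-40.0, 40.0)] * 13,
            options={"maxiter": max_iter, "ftol": self.tol * 1e-2, "gtol": 1e-6},
        )
        ll, _, s_hat, _ = des.profiled_loglik_and_grad(res.x)
        log_se = 0.5 * math.log(max(s_hat, 1e-24))
        log_sb = 0.5 * (math.log(max(s_hat, 1e-24)) + res.x[12])
        res.x = np.concatenate([res.x[:12], [log_sb, log_se]])
        res.fun = -ll
        return res

    def fit(self, data: pd.DataFrame, y=None, init: Optional[RetentionParams] = None):
        frame, self.n_excluded_ = self._filter(data)
        if frame.empty:
            raise ValueError("no participants left after inclusion filtering")
        have_older = (frame["age_group"] == OLDER).any()
        have_young = (frame["age_group"] == YOUNG).any()
        if not (have_older and have_young):
            logger.warning(
                "only one age group present; the other group's parameters "
                "are not identified"
            )
        des = _Design(frame, self.outcome)
        best = None
        inits = (
            [init]
            if init is not None
            else [self._init_params(des, lam0) for lam0 in self.lambda_inits]
        )
        for p0 in inits:
            res = self._optimize(des, p0.to_unconstrained(), self.max_iter)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        self._design_ = des
        self._opt_vec_ = best.x
        self.params_ = RetentionParams.from_unconstrained(best.x)
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(best.success)
        if not self.converged_:
            logger.warning("retention model did not converge: %s", best.message)
        self.n_obs_ = len(des.y)
        self.n_subjects_ = des.n_subjects
        self.group_mean_age_ = dict(des.group_mean_age)
        if self.compute_se:
            self._wald()
        else:
            self.se_ = None
            self.conf_int_ = None
        return self

    def _wald(self) -> None:
        des = self._design_

        def nll(vec):
            return -des.loglik(RetentionParams.from_unconstrained(vec))

        try:
            hess = approx_hess(self._opt_vec_, nll)
            cov = np.linalg.inv(hess)
            var = np.diag(cov).copy()
            if np.any(var <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            logger.warning("singular observed information; SEs set to missing")
            self.se_ = pd.Series(np.nan, index=PARAM_NAMES)
            self.conf_int_ = pd.DataFrame(
                np.nan, index=PARAM_NAMES, columns=["low", "high"]
            )
            return
        # delta method back to the natural scale for log-parameterized terms
        natural = np.array([getattr(self.params_, n) for n in PARAM_NAMES])
        grad = np.ones(len(PARAM_NAMES))
        for k in _LOG_IDX:
            grad[k] = natural[k]
        se = np.sqrt(var) * np.abs(grad)
        self.se_ = pd.Series(se, index=PARAM_NAMES)
        z = 1.959963984540054
        self.conf_int_ = pd.DataFrame(
            {"low": natural - z * se, "high": natural + z * se}, index=PARAM_NAMES
        )

    # -- prediction ---------------------------------------------------------

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed-effect (population) mean score for each row of ``data``."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        frame = data.copy()
        frame[self.outcome] = 0.0  # outcome not used by the mean
        des = _Design(frame, self.outcome, self.group_mean_age_)
        return des.mean(self.params_)

    def summary(self) -> pd.DataFrame:
        est = pd.Series(
            {n: getattr(self.params_, n) for n in PARAM_NAMES}, name="estimate"
        )
        out = est.to_frame()
        if self.se_ is not None:
            out["se"] = self.se_
            out["ci_low"] = self.conf_int_["low"]
            out["ci_high"] = self.conf_int_["high"]
        return out


def fit_retention(data: pd.DataFrame, **kwargs) -> RetentionModel:
    """Fit the retention model to the criterion (100-words) outcome."""
    return RetentionModel(outcome="memory_score", **kwargs).fit(data)
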
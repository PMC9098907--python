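"""Linear mixed models with per-subject random intercept (+ time slope).

The marginal covariance of subject *i* with random design ``Z_i`` is
``Z_i D Z_i' + sigma_e^2 I``; :func:`lmm_marginal_loglik` evaluates the
ML or REML log-likelihood of that Gaussian model directly (REML adds the
standard ``-0.5 log|X' V^-1 X|`` correction plus its constant).  This
function is the package's reference likelihood, cross-checked in the test
suite against a dense multivariate-normal construction; model *fitting*
is delegated to :class:`statsmodels` ``MixedLM`` through
:class:`LinearMixedModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMSpec:
    """A linear mixed model: fixed formula + per-subject random design."""

    formula: str  # patsy formula for the fixed part, e.g. "y ~ x1 + x2"
    groups: str = "participant_id"
    random_slope: Optional[str] = None  # column for a random slope, or None
    reml: bool = True

    @property
    def re_formula(self) -> str:
        return "~" + self.random_slope if self.random_slope else "~1"


def lmm_marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    D: np.ndarray,
    sigma2: float,
    reml: bool = False,
) -> float:
    """Marginal Gaussian log-likelihood of a linear mixed model.

    Parameters are on the natural scale: ``D`` is the random-effect
    covariance (q x q, PSD), ``sigma2`` the residual variance.  Missing
    outcomes should be dropped before calling.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    D = np.atleast_2d(np.asarray(D, float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    r = y - X @ np.asarray(beta, float)
    ll = 0.0
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        Zi = Z[idx]
        Vi = Zi @ D @ Zi.T + sigma2 * np.eye(len(idx))
        Li = np.linalg.cholesky(Vi)
        u = np.linalg.solve(Li, r[idx])
        ll += -0.5 * (
            len(idx) * _LOG2PI + 2.0 * np.sum(np.log(np.diag(Li))) + u @ u
        )
        if reml:
            Wi = np.linalg.solve(Li, X[idx])
            xtvx += Wi.T @ Wi
    if reml:
        p = X.shape[1]
        sign, logdet = np.linalg.slogdet(xtvx / (2.0 * np.pi))
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        ll -= 0.5 * logdet
    return float(ll)


def gls_fixed_effects(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, groups: np.ndarray,
    D: np.ndarray, sigma2: float,
) -> np.ndarray:
    """Closed-form GLS fixed effects at known variance components."""
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        Zi = np.atleast_2d(Z[idx])
        Vi = Zi @ np.atleast_2d(D) @ Zi.T + sigma2 * np.eye(len(idx))
        Vinv_X = np.linalg.solve(Vi, X[idx])
        XtVX += X[idx].T @ Vinv_X
        XtVy += Vinv_X.T @ y[idx]
    return np.linalg.solve(XtVX, XtVy)


@dataclass
class LMMFit:
    """Fitted state of a linear mixed model."""

    fe_params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame
    cov_re: pd.DataFrame  # random-effect covariance (variance scale)
    sigma2: float  # residual variance
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int


class LinearMixedModel(BaseEstimator):
    """REML/ML linear mixed model (statsmodels MixedLM backend).

    sklearn-style wrapper: ``fit(data)`` takes a long-format DataFrame;
    fitted state lands in ``result_`` (the statsmodels results object)
    and ``fit_`` (an :class:`LMMFit` summary).
    """

    def __init__(self, spec: Optional[LMMSpec] = None, **spec_kwargs):
        self.spec = spec
        self.spec_kwargs = spec_kwargs

    def _spec(self) -> LMMSpec:
        return self.spec if self.spec is not None else LMMSpec(**self.spec_kwargs)

    def fit(self, data: pd.DataFrame, y=None):
        spec = self._spec()
        model = smf.mixedlm(
            spec.formula, data, groups=data[spec.groups], re_formula=spec.re_formula
        )
        # gradient methods stall on the small-per-subject-cluster designs
        # used here; Powell is slower per step but converges reliably
        result = model.fit(reml=spec.reml, method=["powell", "lbfgs"], maxiter=1000)
        self.result_ = result
        ci = result.conf_int().loc[result.fe_params.index]
        ci.columns = ["low", "high"]
        self.fit_ = LMMFit(
            fe_params=result.fe_params,
            se=result.bse.loc[result.fe_params.index],
            conf_int=ci,
            cov_re=result.cov_re,
            sigma2=float(result.scale),
            loglik=float(result.llf),
            converged=bool(result.converged),
            n_subjects=int(data[spec.groups].nunique()),
            n_obs=int(result.nobs),
        )
        if not result.converged:
            logger.warning("linear mixed model did not converge")
        return self

    def contrast(self, weights: dict[str, float]) -> tuple[float, float]:
        """Estimate and SE of a linear combination of fixed effects."""
        fe = self.result_.fe_params
        cov = self.result_.cov_params().loc[fe.index, fe.index]
        c = pd.Series(0.0, index=fe.index)
        for name, w in weights.items():
            c[name] = w
        est = float(c @ fe)
        se = float(np.sqrt(c @ cov @ c))
        return est, se
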
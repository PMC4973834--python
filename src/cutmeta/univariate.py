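"""Univariate random-effects meta-analysis, prediction intervals and
meta-regression.

The model is the standard two-level normal hierarchy: each study's estimate
y_i ~ N(theta_i, s_i^2) with known sampling variance, and the true effects
theta_i ~ N(beta, tau^2).  Between-study variance tau^2 is estimated by
restricted maximum likelihood (default) or DerSimonian-Laird moments; the
summary beta-hat is the inverse-variance weighted mean at the estimated
tau^2.  Prediction intervals for the effect in a new study use a t critical
value with N - 2 degrees of freedom on sqrt(tau^2 + Var(beta-hat)), which
widens the interval to acknowledge the uncertainty in tau-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import DataError, EffectRecord

__all__ = [
    "UnivariateResult",
    "PredictionInterval",
    "MetaRegressionResult",
    "fit_univariate",
    "prediction_interval",
    "heterogeneity",
    "fit_meta_regression",
]

_REML_TOL = 1e-8
_LOG_TAU2_STARTS = (-4.0, 0.0, 2.0)  # dispersed starts on the log-tau^2 scale


@dataclass(frozen=True)
class UnivariateResult:
    beta_hat: float
    var_beta: float
    tau2_hat: float
    k: int
    Q: float
    I2: float
    ci: tuple[float, float]
    method: str
    restricted_loglik: float | None = None

    @property
    def se_beta(self) -> float:
        return math.sqrt(self.var_beta)

    @property
    def tau_hat(self) -> float:
        return math.sqrt(self.tau2_hat)

    @property
    def summary_ratio(self) -> float:
        """exp(beta-hat): summary odds or hazard ratio."""
        return math.exp(self.beta_hat)

    @property
    def ci_ratio(self) -> tuple[float, float]:
        return (math.exp(self.ci[0]), math.exp(self.ci[1]))


@dataclass(frozen=True)
class PredictionInterval:
    lo: float
    hi: float
    df: int
    t_crit: float

    @property
    def lo_ratio(self) -> float:
        return math.exp(self.lo)

    @property
    def hi_ratio(self) -> float:
        return math.exp(self.hi)


@dataclass(frozen=True)
class MetaRegressionResult:
    coef: np.ndarray          # (intercept alpha, slope gamma1, ...)
    vcov: np.ndarray
    tau2_hat: float
    k: int
    restricted_loglik: float

    @property
    def alpha_hat(self) -> float:
        return float(self.coef[0])

    @property
    def gamma1_hat(self) -> float:
        return float(self.coef[1])

    def predict(self, x: float) -> tuple[float, float]:
        """Summary effect alpha + gamma1*x and its delta-method variance."""
        c = np.array([1.0, x])
        return float(c @ self.coef), float(c @ self.vcov @ c)


def _as_arrays(records: Sequence[EffectRecord] | tuple) -> tuple[np.ndarray, np.ndarray]:
    if len(records) and isinstance(records[0], EffectRecord):
        y = np.array([r.y for r in records], dtype=float)
        se = np.array([r.se for r in records], dtype=float)
    else:
        y, se = (np.asarray(a, dtype=float) for a in records)
    if np.any(se <= 0):
        raise DataError("all standard errors must be > 0")
    return y, se


def _gls(y: np.ndarray, X: np.ndarray, v: np.ndarray):
    """Weighted LS of y on X with variances v: coefficients, their
    covariance (X'WX)^-1, and the weighted residual sum of squares."""
    w = 1.0 / v
    XtWX = (X * w[:, None]).T @ X
    XtWy = (X * w[:, None]).T @ y
    vcov = np.linalg.inv(XtWX)
    coef = vcov @ XtWy
    resid = y - X @ coef
    return coef, vcov, XtWX, float(np.sum(w * resid**2))


def _restricted_loglik(tau2: float, y: np.ndarray, se: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 with the mean profiled out."""
    v = se**2 + tau2
    _, _, XtWX, rss = _gls(y, X, v)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise DataError("design matrix is rank deficient")
    n, p = X.shape
    return -0.5 * (np.sum(np.log(v)) + logdet + rss + (n - p) * math.log(2 * math.pi))


def _reml_tau2(y: np.ndarray, se: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Maximise the restricted log-likelihood over tau^2 >= 0.

    Runs bounded Brent searches on log tau^2 from dispersed starts and
    compares with the tau^2 = 0 boundary.
    """
    best_t, best_ll = 0.0, _restricted_loglik(0.0, y, se, X)
    lo, hi = -30.0, math.log(max(np.var(y) * 10, se.max() ** 2 * 10, 1e-4))

    def nll(log_t: float) -> float:
        return -_restricted_loglik(math.exp(log_t), y, se, X)

    for start in _LOG_TAU2_STARTS:
        s = min(max(start, lo + 1), hi - 1)
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": _REML_TOL, "maxiter": 200},
        )
        # a local polish around the dispersed start guards against flat spells
        res2 = optimize.minimize_scalar(
            nll, bracket=(s - 1.0, s), method="brent", options={"xtol": _REML_TOL}
        )
        for r in (res, res2):
            t = math.exp(min(max(float(r.x), lo), hi))
            ll = _restricted_loglik(t, y, se, X)
            if ll > best_ll + 1e-12:
                best_t, best_ll = t, ll
    return best_t, best_ll


def _dl_tau2(y: np.ndarray, se: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator (floored at zero)."""
    w = 1.0 / se**2
    beta_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - beta_fe) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (Q - (len(y) - 1)) / c)


def heterogeneity(records, beta_fe: float | None = None) -> tuple[float, float]:
    """Cochran's Q (fixed-effect weights) and I^2 in percent."""
    y, se = _as_arrays(records)
    if len(y) < 2:
        raise DataError("heterogeneity needs at least 2 studies")
    w = 1.0 / se**2
    if beta_fe is None:
        beta_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - beta_fe) ** 2))
    k = len(y)
    I2 = 0.0 if Q <= 0 else max(0.0, (Q - (k - 1)) / Q) * 100.0
    return Q, I2


def fit_univariate(
    records,
    method: str = "reml",
    *,
    ci_level: float = 0.95,
) -> UnivariateResult:
    """Random-effects meta-analysis of one level's estimates.

    ``records`` is a sequence of :class:`EffectRecord` or an ``(y, se)`` pair
    of arrays.  ``method`` is ``"reml"`` (default) or ``"dl"``.  The Wald
    confidence interval uses the normal quantile.
    """
    y, se = _as_arrays(records)
    k = len(y)
    if k < 2:
        raise DataError(f"need at least 2 studies, got {k}")
    X = np.ones((k, 1))
    method = method.lower()
    if method == "reml":
        tau2, rll = _reml_tau2(y, se, X)
    elif method == "dl":
        tau2 = _dl_tau2(y, se)
        rll = _restricted_loglik(tau2, y, se, X)
    else:
        raise ValueError(f"unknown estimator {method!r}; use 'reml' or 'dl'")
    coef, vcov, _, _ = _gls(y, X, se**2 + tau2)
    beta = float(coef[0])
    var_beta = float(vcov[0, 0])
    Q, I2 = heterogeneity((y, se))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * math.sqrt(var_beta)
    return UnivariateResult(
        beta_hat=beta,
        var_beta=var_beta,
        tau2_hat=tau2,
        k=k,
        Q=Q,
        I2=I2,
        ci=(beta - half, beta + half),
        method=method,
        restricted_loglik=rll,
    )


def prediction_interval(
    beta_hat: float,
    var_beta: float,
    tau2_hat: float,
    n_for_df: int,
    coverage: float = 0.95,
) -> PredictionInterval:
    """Interval for the true effect in a new study.

    beta-hat +/- t_{N-2} * sqrt(tau^2 + Var(beta-hat)), with N the number of
    studies in the analysis.  Requires N >= 3 so the t distribution has
    positive degrees of freedom.
    """
    df = n_for_df - 2
    if df < 1:
        raise DataError(f"prediction interval needs at least 3 studies (df = {df} <= 0)")
    t = float(stats.t.ppf(0.5 + coverage / 2, df))
    half = t * math.sqrt(tau2_hat + var_beta)
    return PredictionInterval(lo=beta_hat - half, hi=beta_hat + half, df=df, t_crit=t)


def prediction_interval_from_result(
    result: UnivariateResult, coverage: float = 0.95, n_for_df: int | None = None
) -> PredictionInterval:
    n = result.k if n_for_df is None else n_for_df
    return prediction_interval(result.beta_hat, result.var_beta, result.tau2_hat, n, coverage)


def fit_meta_regression(
    records,
    covariates,
    *,
    method: str = "reml",
) -> MetaRegressionResult:
    """Random-effects meta-regression of effect on study-level covariates.

    ``covariates`` is a 1-d array (e.g. each study's cut-point value) or a
    2-d array of columns; an intercept is always prepended.  Fitted by REML
    on the residual between-study variance.
    """
    y, se = _as_arrays(records)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != len(y):
        raise DataError("covariate length must match number of studies")
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            raise DataError(f"covariate column {j} is constant")
    X = np.hstack([np.ones((len(y), 1)), x])
    if len(y) <= X.shape[1] + 1:
        raise DataError(
            f"need more than {X.shape[1] + 1} studies for {X.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("rank-deficient design matrix")
    if method.lower() == "reml":
        tau2, rll = _reml_tau2(y, se, X)
    elif method.lower() == "dl":
        # moment estimator generalised to regression residuals
        coef0, _, _, _ = _gls(y, X, se**2)
        resid = y - X @ coef0
        w = 1.0 / se**2
        Q = float(np.sum(w * resid**2))
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (len(y) - X.shape[1])) / c)
        rll = _restricted_loglik(tau2, y, se, X)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    coef, vcov, _, _ = _gls(y, X, se**2 + tau2)
    return MetaRegressionResult(
        coef=coef, vcov=vcov, tau2_hat=tau2, k=len(y), restricted_loglik=rll
    )
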
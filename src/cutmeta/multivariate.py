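"""Multivariate random-effects meta-analysis across cut-points or methods.

Each study i contributes an observed sub-vector y_i of level-specific log
effect estimates with known within-study covariance matrix S_i.  The true
study effects are theta_i ~ N(beta, Omega), so marginally
y_i ~ N(X_i beta, X_i Omega X_i' + S_i) with X_i the 0/1 matrix selecting
the levels study i reports.  Levels a study does not report simply drop out
of its likelihood contribution (a missing-at-random assumption); the
between-study covariance Omega lets the reported levels "borrow strength"
for the sparsely reported ones.

Omega is estimated by restricted maximum likelihood over an unconstrained
parameterisation (log-Cholesky for the unstructured form) using quasi-Newton
search from dispersed starts.  The between-study correlation is allowed to
reach the +/-1 boundary — a common occurrence with few studies — and is
flagged in the result rather than treated as an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .data_model import DataError, MetaDataset, StudyBlock, assemble_blocks
from .univariate import PredictionInterval, prediction_interval

__all__ = [
    "OmegaSpec",
    "MVResult",
    "restricted_loglik",
    "profile_restricted_loglik",
    "fit_mv",
    "mv_prediction_interval",
    "sensitivity_within_corr",
]

_LOG2PI = math.log(2 * math.pi)
#: correlations within this distance of +/-1 are reported as boundary hits
BOUNDARY_TOL = 1e-6
_LOGSD_BOUNDS = (-12.0, 5.0)
_OFFDIAG_BOUNDS = (-50.0, 50.0)


@dataclass(frozen=True)
class OmegaSpec:
    """Structure of the between-study covariance matrix.

    ``unstructured``: T variances and T(T-1)/2 covariances (log-Cholesky).
    ``common_var_common_corr``: one variance, one correlation shared by all
    pairs.  ``ar1``: tau_jk = tau^2 * rho^|j-k| over the ordered level index.
    """

    structure: str = "unstructured"
    dim: int = 2

    def __post_init__(self) -> None:
        if self.structure not in ("unstructured", "common_var_common_corr", "ar1"):
            raise ValueError(f"unknown Omega structure {self.structure!r}")
        if self.dim < 1:
            raise ValueError("dimension must be >= 1")

    @property
    def n_params(self) -> int:
        T = self.dim
        if self.structure == "unstructured":
            return T + T * (T - 1) // 2
        return 1 if T == 1 else 2

    def build(self, params: np.ndarray) -> np.ndarray:
        T = self.dim
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {params.shape}")
        if self.structure == "unstructured":
            L = np.zeros((T, T))
            L[np.diag_indices(T)] = np.exp(params[:T])
            if T > 1:
                L[np.tril_indices(T, -1)] = params[T:]
            return L @ L.T
        tau2 = math.exp(2 * params[0])
        if T == 1:
            return np.array([[tau2]])
        if self.structure == "common_var_common_corr":
            lo = -1.0 / (T - 1)  # PSD range for a compound-symmetric correlation
            rho = lo + (1 - lo) * expit(params[1])
            R = np.full((T, T), rho)
            np.fill_diagonal(R, 1.0)
            return tau2 * R
        rho = math.tanh(params[1])
        idx = np.arange(T)
        return tau2 * rho ** np.abs(idx[:, None] - idx[None, :])

    def bounds(self) -> list[tuple[float, float]]:
        T = self.dim
        if self.structure == "unstructured":
            return [_LOGSD_BOUNDS] * T + [_OFFDIAG_BOUNDS] * (T * (T - 1) // 2)
        return [_LOGSD_BOUNDS] + ([(-20.0, 20.0)] if T > 1 else [])

    def initial_params(self, diag_tau2: np.ndarray) -> list[np.ndarray]:
        """Dispersed starting points: moment-style diagonal, small variances,
        and inflated variances (all at zero correlation)."""
        T = self.dim
        d = np.sqrt(np.maximum(np.asarray(diag_tau2, dtype=float), 1e-4))
        starts = []
        for scale in (1.0, 0.1, 4.0):
            if self.structure == "unstructured":
                p = np.zeros(self.n_params)
                p[:T] = np.log(d * scale)
                starts.append(p)
            else:
                p = np.zeros(self.n_params)
                p[0] = math.log(float(np.mean(d)) * scale)
                starts.append(p)
        return starts


@dataclass(frozen=True)
class MVResult:
    levels: tuple[str, ...]
    beta_hat: np.ndarray
    var_beta: np.ndarray
    omega_hat: np.ndarray
    restricted_loglik: float
    converged: bool
    n_studies: dict[str, int]
    k: int
    spec: OmegaSpec
    ci_level: float = 0.95
    boundary: bool = field(default=False)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.var_beta))

    @property
    def tau2(self) -> np.ndarray:
        return np.diag(self.omega_hat)

    @property
    def tau(self) -> np.ndarray:
        return np.sqrt(self.tau2)

    @property
    def between_corr(self) -> np.ndarray:
        d = np.sqrt(np.clip(self.tau2, 1e-300, None))
        return self.omega_hat / np.outer(d, d)

    @property
    def summary_ratio(self) -> np.ndarray:
        return np.exp(self.beta_hat)

    def ci(self, level: str | int | None = None) -> np.ndarray:
        """Wald z confidence intervals on the log scale, one row per level."""
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        se = self.se_beta
        out = np.column_stack([self.beta_hat - z * se, self.beta_hat + z * se])
        if level is None:
            return out
        return out[self._index(level)]

    def _index(self, level: str | int) -> int:
        return level if isinstance(level, int) else self.levels.index(level)

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci()
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "beta": self.beta_hat,
                "se": self.se_beta,
                "ratio": np.exp(self.beta_hat),
                "ci_lo_ratio": np.exp(ci[:, 0]),
                "ci_hi_ratio": np.exp(ci[:, 1]),
                "tau": self.tau,
                "n_studies": [self.n_studies[lv] for lv in self.levels],
            }
        )


def _prepare(blocks: Sequence[StudyBlock], levels: Sequence[str] | None):
    if levels is None:
        seen: list[str] = []
        for b in blocks:
            for lab in b.levels:
                if lab not in seen:
                    seen.append(lab)
        levels = seen
    index = {lab: i for i, lab in enumerate(levels)}
    prepped = []
    for b in blocks:
        try:
            idx = np.array([index[lab] for lab in b.levels], dtype=int)
        except KeyError as err:
            raise DataError(f"study {b.study_id!r} reports unregistered level {err}") from err
        prepped.append((b.study_id, idx, b.y, b.S))
    return tuple(levels), prepped


def _criterion(omega: np.ndarray, prepped, T: int):
    """Profiled REML criterion: returns (rll, beta, var_beta) or None if a
    study's total covariance is singular."""
    XtVX = np.zeros((T, T))
    XtVy = np.zeros(T)
    logdet_sum = 0.0
    pieces = []
    for sid, idx, y, S in prepped:
        V = omega[np.ix_(idx, idx)] + S
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet_sum += 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = np.linalg.inv(V)
        XtVX[np.ix_(idx, idx)] += Vinv
        XtVy[idx] += Vinv @ y
        pieces.append((idx, y, Vinv))
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    var_beta = np.linalg.inv(XtVX)
    beta = var_beta @ XtVy
    quad = 0.0
    n_obs = 0
    for idx, y, Vinv in pieces:
        r = y - beta[idx]
        quad += float(r @ Vinv @ r)
        n_obs += len(y)
    rll = -0.5 * (logdet_sum + logdet_X + quad + (n_obs - T) * _LOG2PI)
    return rll, beta, var_beta


def restricted_loglik(
    beta: np.ndarray,
    omega: np.ndarray,
    blocks: Sequence[StudyBlock],
    levels: Sequence[str] | None = None,
) -> float:
    """Restricted log-likelihood at a given mean vector and Omega.

    Sum over studies of the multivariate-normal log density of the observed
    sub-vector with covariance sub-Omega + S_i, plus the REML adjustment
    -1/2 log|sum_i X_i' V_i^-1 X_i| for estimating the level means.
    """
    levels, prepped = _prepare(blocks, levels)
    T = len(levels)
    beta = np.asarray(beta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    XtVX = np.zeros((T, T))
    total = 0.0
    for sid, idx, y, S in prepped:
        V = omega[np.ix_(idx, idx)] + S
        try:
            total += stats.multivariate_normal.logpdf(y, mean=beta[idx], cov=V)
        except np.linalg.LinAlgError as err:
            raise DataError(f"singular total covariance for study {sid!r}") from err
        XtVX[np.ix_(idx, idx)] += np.linalg.inv(V)
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise DataError("singular generalised-least-squares information matrix")
    return float(total) - 0.5 * logdet_X + 0.5 * T * _LOG2PI


def profile_restricted_loglik(
    omega: np.ndarray,
    blocks: Sequence[StudyBlock],
    levels: Sequence[str] | None = None,
) -> float:
    """Restricted log-likelihood at Omega with beta profiled out by GLS."""
    levels, prepped = _prepare(blocks, levels)
    out = _criterion(np.asarray(omega, dtype=float), prepped, len(levels))
    if out is None:
        raise DataError("singular covariance in restricted likelihood")
    return out[0]


def _moment_diag(prepped, T: int) -> np.ndarray:
    """Per-level DerSimonian-Laird variances used to seed the optimiser."""
    from .univariate import _dl_tau2

    diag = np.full(T, 0.01)
    for j in range(T):
        ys, ses = [], []
        for _, idx, y, S in prepped:
            pos = np.where(idx == j)[0]
            if len(pos):
                ys.append(y[pos[0]])
                ses.append(math.sqrt(S[pos[0], pos[0]]))
        if len(ys) >= 2:
            diag[j] = max(_dl_tau2(np.array(ys), np.array(ses)), 1e-4)
    return diag


def fit_mv(
    blocks: Sequence[StudyBlock],
    spec: OmegaSpec | None = None,
    *,
    levels: Sequence[str] | None = None,
    ci_level: float = 0.95,
    restarts: int = 3,
    tol: float = 1e-8,
) -> MVResult:
    """REML fit of the multivariate random-effects model.

    Every level must be observed in at least one study and at least two
    studies must contribute overall.  Studies reporting a single level enter
    as 1x1 blocks.  Returns level summaries (GLS at the estimated Omega),
    their covariance, and the estimated between-study covariance.
    """
    if len(blocks) < 2:
        raise DataError(f"need at least 2 studies, got {len(blocks)}")
    levels, prepped = _prepare(blocks, levels)
    T = len(levels)
    n_studies = {lab: 0 for lab in levels}
    for _, idx, _, _ in prepped:
        for j in idx:
            n_studies[levels[j]] += 1
    empty = [lab for lab, n in n_studies.items() if n == 0]
    if empty:
        raise DataError(f"levels observed in no study: {empty}")
    if spec is None:
        spec = OmegaSpec("unstructured", T)
    elif spec.dim != T:
        raise DataError(f"OmegaSpec dimension {spec.dim} != number of levels {T}")

    def nll(params: np.ndarray) -> float:
        out = _criterion(spec.build(params), prepped, T)
        return math.inf if out is None else -out[0]

    starts = spec.initial_params(_moment_diag(prepped, T))[: max(restarts, 1)]
    best = None
    any_success = False
    for p0 in starts:
        res = optimize.minimize(
            nll,
            p0,
            method="L-BFGS-B",
            bounds=spec.bounds(),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not math.isfinite(best.fun):
        raise DataError("multivariate REML failed to find a valid Omega from any start")
    omega = spec.build(best.x)
    rll, beta, var_beta = _criterion(omega, prepped, T)
    d = np.sqrt(np.clip(np.diag(omega), 1e-300, None))
    corr = omega / np.outer(d, d)
    off = corr[np.triu_indices(T, 1)] if T > 1 else np.array([])
    boundary = bool(np.any(np.abs(off) > 1 - BOUNDARY_TOL))
    return MVResult(
        levels=levels,
        beta_hat=beta,
        var_beta=var_beta,
        omega_hat=omega,
        restricted_loglik=rll,
        converged=any_success,
        n_studies=n_studies,
        k=len(blocks),
        spec=spec,
        ci_level=ci_level,
        boundary=boundary,
    )


def mv_prediction_interval(
    result: MVResult,
    level: str | int,
    coverage: float = 0.95,
    n_for_df: int | None = None,
) -> PredictionInterval:
    """Per-level prediction interval from a multivariate fit.

    beta_j +/- t_{N-2} sqrt(tau_j^2 + Var(beta_j)) with N the total number
    of studies in the multivariate analysis.
    """
    j = result._index(level)
    n = result.k if n_for_df is None else n_for_df
    return prediction_interval(
        float(result.beta_hat[j]),
        float(result.var_beta[j, j]),
        float(result.omega_hat[j, j]),
        n,
        coverage,
    )


def sensitivity_within_corr(
    dataset: MetaDataset,
    rho_grid: Sequence[float],
    spec: OmegaSpec | None = None,
    *,
    override: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the multivariate model under a grid of assumed within-study
    correlations.

    By default each grid value fills only the *unstated* pairwise
    covariances, leaving stated (bootstrap or patient-level) values as
    given.  With ``override=True`` every pairwise correlation — stated or
    not — is replaced by the grid value, answering "would assuming a
    within-study correlation of +0.9 everywhere change the summary?".
    """
    rows = []
    for rho in rho_grid:
        if not -1 < rho < 1:
            raise DataError(f"grid correlation must lie in (-1, 1), got {rho}")
        blocks = assemble_blocks(dataset, impute_rho=rho, warn_missing=False)
        if override:
            new = []
            for b in blocks:
                se = np.sqrt(np.diag(b.S))
                S = rho * np.outer(se, se)
                np.fill_diagonal(S, se**2)
                new.append(StudyBlock(b.study_id, b.levels, b.y, S))
            blocks = new
        res = fit_mv(blocks, spec, levels=dataset.registry.labels, **fit_kwargs)
        for i, lab in enumerate(res.levels):
            rows.append(
                {
                    "assumed_rho": rho,
                    "level": lab,
                    "beta": float(res.beta_hat[i]),
                    "se": float(res.se_beta[i]),
                    "ratio": float(np.exp(res.beta_hat[i])),
                    "tau": float(res.tau[i]),
                }
            )
    return pd.DataFrame(rows)
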
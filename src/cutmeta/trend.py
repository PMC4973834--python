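"""Cut-point trend meta-analysis: a functional relationship between the
prognostic effect and the cut-point value.

Rather than estimating a separate summary effect per cut-point, the model
assumes y_ij = alpha_i + gamma * f(x_j) + e_ij, where f is a linear or
fractional-polynomial transform of the cut-point, alpha_i ~ N(alpha,
tau_alpha^2) is a study-specific random intercept, and the within-study
errors e_i have known covariance S_i.  This collapses the mean structure to
two fixed parameters however many cut-points the studies report, which is
what makes the approach usable when most studies contribute only one or two
cut-points.  Random slopes are available but off by default: with sparse
cut-points per study the slope heterogeneity is rarely identifiable (and in
the motivating application it was estimated as zero).

A method-stratified variant fits a separate intercept and slope per
measurement method, optionally with method-specific intercept variances and
a between-method intercept correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import DataError, StudyBlock
from .univariate import PredictionInterval, prediction_interval

__all__ = [
    "TransformSpec",
    "TrendResult",
    "transform_cutpoints",
    "fit_trend",
    "predict_cutpoint",
    "select_function",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class TransformSpec:
    """Cut-point transform: identity or a one-term fractional polynomial.

    ``powers`` holds the FP power (0 means log).  ``shift`` is added to the
    cut-point before negative/log powers so the transform is defined at 0;
    ``shift="auto"`` resolves to +1 when any cut-point is <= 0.
    """

    family: str = "linear"
    powers: tuple[float, ...] = (1.0,)
    shift: float | str = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "fractional_polynomial"):
            raise ValueError(f"unknown transform family {self.family!r}")
        if self.family == "fractional_polynomial":
            if len(self.powers) != 1:
                raise ValueError("one-term fractional polynomials only")
            if self.powers[0] not in FP_POWERS:
                raise ValueError(f"FP power must be one of {FP_POWERS}")

    def resolve_shift(self, x: np.ndarray) -> float:
        if self.shift == "auto":
            return 1.0 if float(np.min(x)) <= 0 else 0.0
        return float(self.shift)

    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        p = self.powers[0]
        return f"fp({'log' if p == 0 else p:g})" if p != 0 else "fp(log)"


def transform_cutpoints(x, spec: TransformSpec) -> np.ndarray:
    """Apply the transform; errors if a negative/log power meets a
    non-positive shifted cut-point."""
    x = np.asarray(x, dtype=float)
    if spec.family == "linear":
        return x.copy()
    p = spec.powers[0]
    xs = x + spec.resolve_shift(x)
    if p <= 0 and np.any(xs <= 0):
        bad = x[xs <= 0]
        raise DataError(
            f"transform {spec.label()} undefined at cut-point(s) {bad.tolist()} "
            f"(shifted values must be positive)"
        )
    return np.log(xs) if p == 0 else xs**p


@dataclass(frozen=True)
class TrendResult:
    coef: np.ndarray               # fixed effects, ordered as coef_names
    vcov: np.ndarray
    coef_names: tuple[str, ...]
    tau_alpha2: float | np.ndarray
    tau_gamma2: float | None
    intercept_corr: float | None   # between-method intercept correlation
    restricted_loglik: float
    loglik_ml: float
    aic: float
    transform: TransformSpec
    k: int
    x_range: tuple[float, float]
    groups: tuple[str, ...] | None = None

    @property
    def alpha_hat(self) -> float:
        return float(self.coef[0])

    @property
    def gamma_hat(self) -> float:
        return float(self.coef[1])

    @property
    def tau_alpha(self) -> float:
        return float(np.sqrt(np.max(self.tau_alpha2)))

    def ci(self, idx: int = 0, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        se = math.sqrt(self.vcov[idx, idx])
        return (float(self.coef[idx]) - z * se, float(self.coef[idx]) + z * se)


def _study_design(block: StudyBlock, fx_by_level: dict[str, float]):
    try:
        f = np.array([fx_by_level[lab] for lab in block.levels])
    except KeyError as err:
        raise DataError(
            f"study {block.study_id!r}: no cut-point value for level {err}"
        ) from err
    return f


def _fit_lmm(designs, var_builder, n_varpar: int, starts, reml: bool, tol: float = 1e-8):
    """Generic profiled (RE)ML over variance parameters for the trend models.

    ``designs`` is a list of (X_i, Z_i, y_i, S_i); ``var_builder`` maps the
    unconstrained variance parameter vector to the random-effect covariance
    G.  Returns (params, ll, coef, vcov).
    """
    p = designs[0][0].shape[1]

    def criterion(vp: np.ndarray):
        G = var_builder(vp)
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        pieces = []
        for X, Z, y, S in designs:
            V = Z @ G @ Z.T + S
            try:
                c = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Vinv = np.linalg.inv(V)
            XtVX += X.T @ Vinv @ X
            XtVy += X.T @ Vinv @ y
            pieces.append((X, y, Vinv))
        sign, logdet_X = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        vcov = np.linalg.inv(XtVX)
        coef = vcov @ XtVy
        quad = 0.0
        n_obs = 0
        for X, y, Vinv in pieces:
            r = y - X @ coef
            quad += float(r @ Vinv @ r)
            n_obs += len(y)
        if reml:
            ll = -0.5 * (logdet + logdet_X + quad + (n_obs - p) * math.log(2 * math.pi))
        else:
            ll = -0.5 * (logdet + quad + n_obs * math.log(2 * math.pi))
        return ll, coef, vcov

    def nll(vp):
        out = criterion(vp)
        return math.inf if out is None else -out[0]

    best = None
    for vp0 in starts:
        res = optimize.minimize(
            nll,
            np.asarray(vp0, dtype=float),
            method="L-BFGS-B",
            bounds=[(-12.0, 5.0)] * n_varpar if n_varpar else None,
            options={"ftol": tol, "maxiter": 500},
        ) if n_varpar else None
        if n_varpar == 0:
            out = criterion(np.zeros(0))
            return np.zeros(0), *out
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise DataError("trend model failed to converge from any start")
    out = criterion(best.x)
    return best.x, out[0], out[1], out[2]


def fit_trend(
    blocks: Sequence[StudyBlock],
    cutpoints: dict[str, float],
    spec: TransformSpec | None = None,
    *,
    random_slope: bool = False,
    group: dict[str, str] | None = None,
    group_variances: bool = False,
    compute_ml: bool = True,
) -> TrendResult:
    """REML fit of the random-intercept trend model over transformed
    cut-points.

    ``cutpoints`` maps level labels to cut-point values.  When ``group``
    maps levels to method labels, a separate fixed intercept and slope is
    fitted per method; ``group_variances`` additionally gives each method
    its own intercept variance and a between-method intercept correlation.
    """
    if spec is None:
        spec = TransformSpec("linear")
    labels = sorted(cutpoints, key=cutpoints.get)
    x_all = np.array([cutpoints[lab] for lab in labels])
    if len(np.unique(x_all)) < 2:
        raise DataError("need at least 2 distinct cut-points (design is singular)")
    fx = transform_cutpoints(x_all, spec)
    fx_by_level = dict(zip(labels, fx))

    groups: tuple[str, ...] | None = None
    if group is not None:
        groups = tuple(dict.fromkeys(group.values()))
        if len(groups) < 2:
            group = None
            groups = None

    designs = []
    for b in blocks:
        f = _study_design(b, fx_by_level)
        if group is None:
            X = np.column_stack([np.ones(b.dim), f])
            Zi = np.ones((b.dim, 1))
            if random_slope:
                Zi = np.column_stack([Zi, f])
        else:
            g_idx = np.array([groups.index(group[lab]) for lab in b.levels])
            X = np.zeros((b.dim, 2 * len(groups)))
            for r, gi in enumerate(g_idx):
                X[r, 2 * gi] = 1.0
                X[r, 2 * gi + 1] = f[r]
            if group_variances:
                Zi = np.zeros((b.dim, len(groups)))
                Zi[np.arange(b.dim), g_idx] = 1.0
            else:
                Zi = np.ones((b.dim, 1))
            if random_slope:
                Zi = np.column_stack([Zi, f])
        designs.append((X, Zi, b.y, b.S))

    p_fixed = designs[0][0].shape[1]
    n_obs = sum(len(d[2]) for d in designs)
    if n_obs <= p_fixed:
        raise DataError("more fixed-effect parameters than observations")
    X_stack = np.vstack([d[0] for d in designs])
    if np.linalg.matrix_rank(X_stack) < p_fixed:
        raise DataError("singular trend design (a method may lack distinct cut-points)")

    # ---- variance parameterisation ----------------------------------------
    if group is not None and group_variances:
        nG = len(groups)
        n_var = nG + (1 if nG > 1 else 0) + (1 if random_slope else 0)

        def var_builder(vp):
            taus = np.exp(vp[:nG])
            rho = math.tanh(vp[nG]) if nG > 1 else 0.0
            G = np.outer(taus, taus) * rho
            np.fill_diagonal(G, taus**2)
            if random_slope:
                G = np.block(
                    [[G, np.zeros((nG, 1))], [np.zeros((1, nG)), [[math.exp(2 * vp[-1])]]]]
                )
            return G

    else:
        n_var = 1 + (1 if random_slope else 0)

        def var_builder(vp):
            if random_slope:
                return np.diag([math.exp(2 * vp[0]), math.exp(2 * vp[1])])
            return np.array([[math.exp(2 * vp[0])]])

    starts = [np.full(n_var, s) for s in (-1.0, -3.0, 0.5)]
    vp, rll, coef, vcov = _fit_lmm(designs, var_builder, n_var, starts, reml=True)
    if compute_ml:
        _, ll_ml, _, _ = _fit_lmm(designs, var_builder, n_var, [vp], reml=False)
    else:
        ll_ml = float("nan")
    G = var_builder(vp)

    if group is not None and group_variances:
        nG = len(groups)
        tau_alpha2 = np.diag(G)[:nG].copy()
        icorr = float(G[0, 1] / math.sqrt(G[0, 0] * G[1, 1])) if nG > 1 else None
    else:
        tau_alpha2 = float(G[0, 0])
        icorr = None
    tau_gamma2 = float(G[-1, -1]) if random_slope else None

    if group is None:
        names: tuple[str, ...] = ("alpha", "gamma")
    else:
        names = tuple(n for g in groups for n in (f"alpha[{g}]", f"gamma[{g}]"))
    n_par = p_fixed + n_var
    aic = float(-2 * ll_ml + 2 * n_par) if compute_ml else float("nan")
    return TrendResult(
        coef=coef,
        vcov=vcov,
        coef_names=names,
        tau_alpha2=tau_alpha2,
        tau_gamma2=tau_gamma2,
        intercept_corr=icorr,
        restricted_loglik=rll,
        loglik_ml=ll_ml,
        aic=aic,
        transform=spec,
        k=len(blocks),
        x_range=(float(x_all.min()), float(x_all.max())),
        groups=groups,
    )


def predict_cutpoint(
    result: TrendResult,
    x: float,
    coverage: float = 0.95,
    n_for_df: int | None = None,
    *,
    group: str | None = None,
    allow_extrapolation: bool = False,
) -> tuple[float, tuple[float, float], PredictionInterval]:
    """Summary effect at cut-point x: point estimate alpha + gamma*f(x),
    delta-method z confidence interval, and a t-based prediction interval
    adding the intercept heterogeneity under the root (df = k - 2).

    Refuses x outside the observed cut-point range unless
    ``allow_extrapolation`` — the fitted function has no support there.
    """
    lo, hi = result.x_range
    if not allow_extrapolation and not (lo <= x <= hi):
        raise DataError(
            f"cut-point {x} outside the observed range [{lo}, {hi}]; "
            "pass allow_extrapolation=True to override"
        )
    fxv = float(transform_cutpoints(np.array([x]), result.transform)[0])
    c = np.zeros(len(result.coef))
    if result.groups is None:
        c[0], c[1] = 1.0, fxv
        tau2 = float(np.max(np.atleast_1d(result.tau_alpha2)))
    else:
        if group is None:
            raise DataError(f"fit is stratified by method; pass group= one of {result.groups}")
        gi = result.groups.index(group)
        c[2 * gi], c[2 * gi + 1] = 1.0, fxv
        t2 = np.atleast_1d(result.tau_alpha2)
        tau2 = float(t2[gi]) if t2.size > 1 else float(t2[0])
    est = float(c @ result.coef)
    var = float(c @ result.vcov @ c)
    z = stats.norm.ppf(0.5 + coverage / 2)
    ci = (est - z * math.sqrt(var), est + z * math.sqrt(var))
    n = result.k if n_for_df is None else n_for_df
    pi = prediction_interval(est, var, tau2, n, coverage)
    return est, ci, pi


def predict_table(
    result: TrendResult, xs: Sequence[float], coverage: float = 0.95, **kwargs
) -> pd.DataFrame:
    """Per-cut-point summary table (ratio scale) for a fitted trend."""
    rows = []
    for x in xs:
        est, ci, pi = predict_cutpoint(result, x, coverage, **kwargs)
        rows.append(
            {
                "cutpoint": x,
                "summary_ratio": math.exp(est),
                "ci_lo": math.exp(ci[0]),
                "ci_hi": math.exp(ci[1]),
                "pi_lo": pi.lo_ratio,
                "pi_hi": pi.hi_ratio,
            }
        )
    return pd.DataFrame(rows)


def select_function(
    blocks: Sequence[StudyBlock],
    cutpoints: dict[str, float],
    candidates: Sequence[TransformSpec],
    **fit_kwargs,
) -> pd.DataFrame:
    """Rank candidate transforms by AIC under full maximum likelihood.

    All candidates share the same random-effects structure, so their
    likelihoods are comparable; REML values are not (the mean structure
    changes with the transform), hence ML here.  Candidates whose transform
    is undefined on the data's cut-point range are skipped with a warning.
    Ties keep input order.
    """
    if len(candidates) < 1:
        raise DataError("need at least one candidate transform")
    rows = []
    results = {}
    for pos, cand in enumerate(candidates):
        try:
            res = fit_trend(blocks, cutpoints, cand, compute_ml=True, **fit_kwargs)
        except DataError as err:
            warnings.warn(f"candidate {cand.label()} skipped: {err}", stacklevel=2)
            continue
        rows.append(
            {
                "transform": cand.label(),
                "position": pos,
                "aic": res.aic,
                "loglik_ml": res.loglik_ml,
                "alpha": res.alpha_hat if res.groups is None else float("nan"),
                "gamma": res.gamma_hat if res.groups is None else float("nan"),
            }
        )
        results[pos] = res
    if not rows:
        raise DataError("every candidate transform failed")
    table = pd.DataFrame(rows).sort_values(["aic", "position"], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["results"] = results
    return table.reset_index(drop=True)
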
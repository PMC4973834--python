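"""Synthetic datasets with the statistical structure the meta-analysis
models assume.

Two generators are provided.  ``simulate_from_model`` draws directly from
the normal hierarchy: true per-study level effects theta_i ~ N(beta, Omega)
(or a study-specific intercept around a cut-point trend), observed estimates
y_i ~ N(theta_i, S_i) with study-specific within-study covariance built from
a log-uniform standard-error range — mimicking the spread of precision seen
across real cohorts — and a common within-study correlation.
``simulate_cohorts`` works at the participant level: a continuous factor per
subject, a binary outcome from a logistic model in the factor, and the 2x2
tables at each requested cut-point, exercising the reconstruction/bootstrap
machinery end to end.

``apply_missingness`` deletes level results under MCAR, MAR (probability
depending on the study's observed result at a reference level) or an
MNAR-by-significance mechanism in which non-significant results are
preferentially unreported — the selective-reporting pattern that motivates
the multivariate "borrowing of strength" analysis.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import (
    DataError,
    EffectRecord,
    MetaDataset,
    WithinCovariance,
    make_level_id,
    registry_from_records,
)
from .trend import TransformSpec, transform_cutpoints
from .within_corr import IntervalCounts, TwoByTwo, log_odds_ratio, tables_to_intervals

__all__ = [
    "SimulationTruth",
    "simulate_from_model",
    "simulate_trend_model",
    "simulate_cohorts",
    "apply_missingness",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a simulated dataset."""

    beta: np.ndarray | None
    omega: np.ndarray
    theta: np.ndarray          # per-study latent effects, k x T
    trend: tuple[float, float] | None  # (alpha, gamma) when trend-generated
    transform: TransformSpec | None
    se_range: tuple[float, float]
    within_rho: float
    seed: int
    missingness: str = "none"
    missingness_params: dict = field(default_factory=dict)


def _check_omega(omega: np.ndarray, T: int) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (T, T):
        raise DataError(f"Omega must be {T}x{T}")
    if not np.allclose(omega, omega.T):
        raise DataError("Omega must be symmetric")
    if np.linalg.eigvalsh(omega).min() < -1e-10:
        raise DataError("Omega must be positive semi-definite")
    return omega


def _se_matrix(rng, k: int, T: int, se_range: tuple[float, float]) -> np.ndarray:
    lo, hi = se_range
    if not (0 < lo <= hi):
        raise DataError("se_range must satisfy 0 < lo <= hi")
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=(k, T)))


def _sample_observed(rng, theta: np.ndarray, ses: np.ndarray, within_rho: float) -> np.ndarray:
    k, T = theta.shape
    R = np.full((T, T), within_rho)
    np.fill_diagonal(R, 1.0)
    y = np.empty((k, T))
    for i in range(k):
        S = R * np.outer(ses[i], ses[i])
        y[i] = rng.multivariate_normal(theta[i], S)
    return y


def _dataset_from_matrix(
    y: np.ndarray,
    ses: np.ndarray,
    level_cutpoints: Sequence[float] | None,
    level_methods: Sequence[str] | None,
    within_rho: float,
    scale: str,
) -> MetaDataset:
    k, T = y.shape
    records = []
    within = []
    labels = []
    for j in range(T):
        cut = None if level_cutpoints is None else float(level_cutpoints[j])
        meth = None if level_methods is None else str(level_methods[j])
        labels.append(make_level_id(cut, meth))
    for i in range(k):
        sid = f"S{i + 1:03d}"
        for j in range(T):
            cut = None if level_cutpoints is None else float(level_cutpoints[j])
            meth = None if level_methods is None else str(level_methods[j])
            records.append(
                EffectRecord(sid, labels[j], float(y[i, j]), float(ses[i, j]),
                             cutpoint=cut, method=meth, scale=scale)
            )
        if within_rho != 0.0:
            for a in range(T):
                for b in range(a + 1, T):
                    within.append(
                        WithinCovariance(sid, labels[a], labels[b], rho=within_rho,
                                         provenance="imputed")
                    )
    return MetaDataset(records=records, within_cov=within)


def simulate_from_model(
    k: int,
    beta: Sequence[float],
    omega: np.ndarray,
    *,
    level_cutpoints: Sequence[float] | None = None,
    level_methods: Sequence[str] | None = None,
    se_range: tuple[float, float] = (0.15, 0.45),
    within_rho: float = 0.5,
    scale: str = "log_odds",
    seed: int = 0,
) -> tuple[MetaDataset, SimulationTruth]:
    """Draw a complete multi-level dataset from the multivariate hierarchy.

    theta_i ~ N(beta, Omega); y_i ~ N(theta_i, S_i) with S_i from per-study
    log-uniform standard errors and common within-study correlation.  Levels
    default to cut-points 1..T when neither cut-points nor methods are given.
    """
    if k < 2:
        raise DataError("need k >= 2 studies")
    beta = np.asarray(beta, dtype=float)
    T = len(beta)
    omega = _check_omega(omega, T)
    if level_cutpoints is None and level_methods is None:
        level_cutpoints = list(range(1, T + 1))
    rng = np.random.default_rng(seed)
    theta = rng.multivariate_normal(beta, omega, size=k, method="svd")
    ses = _se_matrix(rng, k, T, se_range)
    y = _sample_observed(rng, theta, ses, within_rho)
    ds = _dataset_from_matrix(y, ses, level_cutpoints, level_methods, within_rho, scale)
    truth = SimulationTruth(
        beta=beta, omega=omega, theta=theta, trend=None, transform=None,
        se_range=se_range, within_rho=within_rho, seed=seed,
    )
    return ds, truth


def simulate_trend_model(
    k: int,
    cutpoints: Sequence[float],
    alpha: float,
    gamma: float,
    tau_alpha2: float,
    *,
    transform: TransformSpec | None = None,
    se_range: tuple[float, float] = (0.15, 0.45),
    within_rho: float = 0.5,
    scale: str = "log_odds",
    seed: int = 0,
) -> tuple[MetaDataset, SimulationTruth]:
    """Draw from the random-intercept trend hierarchy:
    theta_ij = alpha_i + gamma * f(x_j), alpha_i ~ N(alpha, tau_alpha^2)."""
    if k < 2:
        raise DataError("need k >= 2 studies")
    if tau_alpha2 < 0:
        raise DataError("tau_alpha2 must be >= 0")
    if transform is None:
        transform = TransformSpec("linear")
    x = np.asarray(cutpoints, dtype=float)
    fx = transform_cutpoints(x, transform)
    rng = np.random.default_rng(seed)
    alphas = rng.normal(alpha, math.sqrt(tau_alpha2), size=k)
    theta = alphas[:, None] + gamma * fx[None, :]
    ses = _se_matrix(rng, k, len(x), se_range)
    y = _sample_observed(rng, theta, ses, within_rho)
    ds = _dataset_from_matrix(y, ses, list(x), None, within_rho, scale)
    truth = SimulationTruth(
        beta=None, omega=np.array([[tau_alpha2]]), theta=theta,
        trend=(alpha, gamma), transform=transform,
        se_range=se_range, within_rho=within_rho, seed=seed,
    )
    return ds, truth


def simulate_cohorts(
    k: int,
    cutpoints: Sequence[float],
    *,
    cohort_sizes: tuple[int, int] = (200, 800),
    factor_mean: float = 0.0,
    factor_sd: float = 1.0,
    outcome_intercept: float = -1.0,
    outcome_slope: float = -1.0,
    seed: int = 0,
) -> tuple[dict[str, IntervalCounts], MetaDataset, SimulationTruth]:
    """Participant-level generator for the bootstrap machinery.

    Per study: a normal continuous factor per subject, a Bernoulli outcome
    with logit(p) = intercept + slope * factor, and the 2x2 table at every
    cut-point.  A negative ``outcome_slope`` makes low factor values risky
    (odds ratios > 1 for the <=-cut-point group).  Returns the reconstructed
    interval counts per study plus the derived log-odds-ratio dataset.
    """
    if k < 1:
        raise DataError("need at least one cohort")
    lo, hi = cohort_sizes
    if lo < 20:
        raise DataError("cohort sizes must be >= 20")
    p_check = 1 / (1 + math.exp(-outcome_intercept))
    if not 0 < p_check < 1:
        raise DataError("baseline risk must be in (0, 1)")
    x = np.asarray(cutpoints, dtype=float)
    span = (factor_mean - 4 * factor_sd, factor_mean + 4 * factor_sd)
    if np.any(x < span[0]) or np.any(x > span[1]):
        raise DataError(f"cut-points {x.tolist()} outside the factor support {span}")
    rng = np.random.default_rng(seed)
    interval_sets: dict[str, IntervalCounts] = {}
    records, within = [], []
    theta_rows = []
    for i in range(k):
        sid = f"C{i + 1:03d}"
        n = int(rng.integers(lo, hi + 1))
        factor = rng.normal(factor_mean, factor_sd, size=n)
        p = 1.0 / (1.0 + np.exp(-(outcome_intercept + outcome_slope * factor)))
        event = rng.random(n) < p
        tables = []
        for cp in x:
            low = factor <= cp
            tables.append(
                TwoByTwo(
                    int(np.sum(event & low)), int(np.sum(~event & low)),
                    int(np.sum(event & ~low)), int(np.sum(~event & ~low)),
                )
            )
        interval_sets[sid] = tables_to_intervals(tables, list(x))
        row = []
        for cp, t in zip(x, tables):
            if t.n_low == 0 or t.n_high == 0:
                raise DataError(
                    f"cohort {sid}: cut-point {cp} leaves an empty group; "
                    "move cut-points toward the factor centre or enlarge cohorts"
                )
            lor, var, _ = log_odds_ratio(t)
            records.append(
                EffectRecord(sid, make_level_id(float(cp), None), lor, math.sqrt(var),
                             cutpoint=float(cp), scale="log_odds")
            )
            row.append(lor)
        theta_rows.append(row)
    ds = MetaDataset(records=records, within_cov=within)
    truth = SimulationTruth(
        beta=None, omega=np.zeros((len(x), len(x))), theta=np.array(theta_rows),
        trend=(outcome_intercept, outcome_slope), transform=None,
        se_range=(0.0, 0.0), within_rho=float("nan"), seed=seed,
    )
    return interval_sets, ds, truth


def apply_missingness(
    dataset: MetaDataset,
    mechanism: str,
    *,
    p: float = 0.5,
    target_level: str | None = None,
    reference_level: str | None = None,
    slope: float = 1.0,
    alpha: float = 0.05,
    protect: Sequence[str] = (),
    seed: int = 0,
) -> MetaDataset:
    """Delete level results under a stated missingness mechanism.

    ``mcar``: each eligible record deleted independently with probability
    ``p`` (restricted to ``target_level`` if given).  ``mar_by_level``:
    deletion probability of the target level follows a logistic curve in the
    study's *observed* estimate at ``reference_level`` (missing at random:
    depends only on observed data).  ``mnar_significance``: records whose
    |y|/se fails the two-sided ``alpha`` significance test are deleted with
    probability ``p``; significant records are always kept — the selective
    reporting pattern.  Studies in ``protect`` are never touched.  Dropped
    records take their within-study covariance rows with them.
    """
    if not 0 <= p <= 1:
        raise DataError(f"deletion probability must be in [0, 1], got {p}")
    mechanism = mechanism.lower()
    if mechanism not in ("mcar", "mar_by_level", "mnar_significance"):
        raise DataError(f"unknown mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    protect = set(protect)
    zcrit = float(stats.norm.ppf(1 - alpha / 2))

    ref_y = {
        r.study_id: r.y for r in dataset.records if r.level_id == reference_level
    }
    keep: list[EffectRecord] = []
    for r in dataset.records:
        if r.study_id in protect:
            keep.append(r)
            continue
        if target_level is not None and r.level_id != target_level:
            keep.append(r)
            continue
        if mechanism == "mcar":
            drop = rng.random() < p
        elif mechanism == "mar_by_level":
            if reference_level is None:
                raise DataError("mar_by_level needs a reference_level")
            if r.level_id == reference_level or r.study_id not in ref_y:
                keep.append(r)
                continue
            prob = 1.0 / (1.0 + math.exp(-slope * (ref_y[r.study_id] - np.mean(list(ref_y.values())))))
            drop = rng.random() < prob * p
        else:  # mnar_significance
            significant = abs(r.y) / r.se > zcrit
            drop = (not significant) and rng.random() < p
        if not drop:
            keep.append(r)
    if not keep:
        raise DataError("missingness mechanism deleted every record")
    kept_keys = {(r.study_id, r.level_id) for r in keep}
    within = [
        w for w in dataset.within_cov
        if (w.study_id, w.level_a) in kept_keys and (w.study_id, w.level_b) in kept_keys
    ]
    kept_levels = {r.level_id for r in keep}
    import warnings as _warnings

    for lab in dataset.registry.labels:
        if lab not in kept_levels:
            _warnings.warn(
                f"level {lab!r} lost every study; downstream fits will refuse it",
                stacklevel=2,
            )
    return MetaDataset(records=keep, within_cov=within)
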
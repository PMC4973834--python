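"""Within-study correlations of log odds ratios across cut-points.

When a cohort reports a 2x2 table at each of several ordered cut-points
(events/non-events at or below vs above the cut-point), the participant-level
data are fully determined: successive differencing of the "<= cut-point"
margins yields the count of events and non-events in every interval between
adjacent cut-points.  Non-parametric bootstrap of the reconstructed subjects
then gives the joint sampling distribution of the per-cut-point log odds
ratios, whose empirical correlation/covariance is exactly the within-study
correlation the multivariate model needs.

Sparse tables are handled with the opposite-group-reciprocal continuity
correction: when a 2x2 table contains a zero cell, 1/(size of the opposite
group) is added to every cell of each group before computing the log odds
ratio and its variance.

For estimates that cannot be reconstructed (adjusted effects, hazard
ratios), the patient-level correlation between two measurement methods can
serve as an approximation to the within-study correlation, giving
cov = rho_patient * se_a * se_b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DataError, WithinCovariance

__all__ = [
    "TwoByTwo",
    "IntervalCounts",
    "BootstrapCorrResult",
    "tables_to_intervals",
    "continuity_correct",
    "log_odds_ratio",
    "bootstrap_within_corr",
    "approx_cov_from_patient_corr",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts at one cut-point: a, b = events / non-events with factor <=
    cut-point; c, d = events / non-events above it."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 counts must be non-negative")
        if self.a + self.b + self.c + self.d <= 0:
            raise DataError("2x2 table is empty")

    @property
    def n_low(self) -> int:
        return self.a + self.b

    @property
    def n_high(self) -> int:
        return self.c + self.d

    @property
    def total_events(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class IntervalCounts:
    """Events / non-events per interval between adjacent ordered cut-points
    (first interval: factor <= x_1; last: factor > x_T)."""

    cutpoints: tuple[float, ...]
    events: tuple[int, ...]
    nonevents: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.events) != len(self.cutpoints) + 1 or len(self.nonevents) != len(self.events):
            raise DataError("interval counts must have one more entry than cut-points")
        if min(self.events) < 0 or min(self.nonevents) < 0:
            raise DataError("interval counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.events) + sum(self.nonevents)

    def to_tables(self) -> list[TwoByTwo]:
        """Cumulative re-aggregation: the exact inverse of
        :func:`tables_to_intervals`."""
        out = []
        for j in range(len(self.cutpoints)):
            a = sum(self.events[: j + 1])
            b = sum(self.nonevents[: j + 1])
            out.append(
                TwoByTwo(a=a, b=b, c=sum(self.events) - a, d=sum(self.nonevents) - b)
            )
        return out

    def to_ipd(self) -> np.ndarray:
        """One row per subject: (interval index, event indicator)."""
        rows = []
        for j, (e, ne) in enumerate(zip(self.events, self.nonevents)):
            rows.extend([(j, 1)] * e)
            rows.extend([(j, 0)] * ne)
        return np.array(rows, dtype=int)


@dataclass(frozen=True)
class BootstrapCorrResult:
    cutpoints: tuple[float, ...]
    corr: np.ndarray
    cov: np.ndarray
    mean_log_or: np.ndarray
    se_log_or: np.ndarray
    n_boot: int
    seed: int
    n_corrected: int

    def to_within_covariances(
        self, study_id: str, *, use_cov: bool = True
    ) -> list[WithinCovariance]:
        """Pairwise entries consumable by the data model.  By default the
        bootstrap *covariance* is passed on; ``use_cov=False`` passes the
        correlation instead (to be combined with analytic SEs)."""
        out = []
        T = len(self.cutpoints)
        for i in range(T):
            for j in range(i + 1, T):
                la, lb = f"{self.cutpoints[i]:g}", f"{self.cutpoints[j]:g}"
                if use_cov:
                    out.append(
                        WithinCovariance(study_id, la, lb, cov=float(self.cov[i, j]),
                                         provenance="bootstrap")
                    )
                else:
                    out.append(
                        WithinCovariance(study_id, la, lb, rho=float(self.corr[i, j]),
                                         provenance="bootstrap")
                    )
        return out


def tables_to_intervals(
    tables: Sequence[TwoByTwo], cutpoints: Sequence[float]
) -> IntervalCounts:
    """Reconstruct interval counts from one cohort's 2x2 tables at ordered
    cut-points, by successive differencing of the <=-side margins."""
    if len(tables) != len(cutpoints):
        raise DataError("need one 2x2 table per cut-point")
    order = np.argsort(cutpoints)
    cps = [float(cutpoints[i]) for i in order]
    tbs = [tables[i] for i in order]
    if len(set(cps)) != len(cps):
        raise DataError("cut-points must be distinct")
    totals = {(t.total, t.total_events) for t in tbs}
    if len(totals) != 1:
        raise DataError(
            "2x2 tables disagree on the cohort's grand total or total events; "
            "they cannot come from one cohort"
        )
    events, nonevents = [], []
    prev_a = prev_b = 0
    for j, t in enumerate(tbs):
        de, dn = t.a - prev_a, t.b - prev_b
        if de < 0 or dn < 0:
            raise DataError(
                f"<=-side counts decrease between cut-points "
                f"{cps[j - 1] if j else '-inf'} and {cps[j]}; tables are inconsistent"
            )
        events.append(de)
        nonevents.append(dn)
        prev_a, prev_b = t.a, t.b
    events.append(tbs[-1].c)
    nonevents.append(tbs[-1].d)
    return IntervalCounts(tuple(cps), tuple(events), tuple(nonevents))


def continuity_correct(table: TwoByTwo) -> tuple[float, float, float, float]:
    """Sweeting-style pseudo-counts: if any cell is zero, add 1/(size of the
    opposite group) to each cell; otherwise return the counts unchanged."""
    if table.n_low == 0 or table.n_high == 0:
        raise DataError("continuity correction undefined when a group is empty")
    if min(table.a, table.b, table.c, table.d) > 0:
        return (float(table.a), float(table.b), float(table.c), float(table.d))
    inc_low = 1.0 / table.n_high
    inc_high = 1.0 / table.n_low
    return (table.a + inc_low, table.b + inc_low, table.c + inc_high, table.d + inc_high)


def log_odds_ratio(table: TwoByTwo) -> tuple[float, float, bool]:
    """Log odds ratio (<= cut-point vs above) and its variance from a 2x2
    table, continuity-corrected when a cell is zero.  Returns
    (log_or, var, corrected)."""
    corrected = min(table.a, table.b, table.c, table.d) == 0
    a, b, c, d = continuity_correct(table)
    lor = math.log(a * d / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return lor, var, corrected


def bootstrap_within_corr(
    intervals: IntervalCounts,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    max_redraw_factor: int = 10,
) -> BootstrapCorrResult:
    """Bootstrap the within-study correlation matrix of per-cut-point log
    odds ratios from reconstructed participant data.

    Whole subjects (interval label x event status) are resampled with
    replacement; each replicate's 2x2 table at every cut-point gives a log
    odds ratio (continuity-corrected when a cell is zero).  Replicates with
    an undefined odds ratio at any cut-point (an empty <= or > group) are
    redrawn, up to ``max_redraw_factor * n_boot`` attempts in total.
    """
    if n_boot < 100:
        raise DataError(f"n_boot must be >= 100, got {n_boot}")
    if intervals.total < 10:
        raise DataError(f"need at least 10 subjects, got {intervals.total}")
    rng = np.random.default_rng(seed)
    T = len(intervals.cutpoints)
    nI = T + 1
    counts = np.concatenate([intervals.events, intervals.nonevents]).astype(float)
    n = intervals.total
    probs = counts / n

    lors = np.empty((n_boot, T))
    n_corrected = 0
    kept = 0
    attempts = 0
    cap = max_redraw_factor * n_boot
    while kept < n_boot:
        if attempts >= cap:
            raise DataError(
                f"exceeded {cap} bootstrap attempts; cohort too sparse for "
                "well-defined odds ratios at every cut-point"
            )
        attempts += 1
        draw = rng.multinomial(n, probs)
        ev, ne = draw[:nI], draw[nI:]
        cum_e, cum_n = np.cumsum(ev), np.cumsum(ne)
        tot_e, tot_n = cum_e[-1], cum_n[-1]
        ok = True
        row = np.empty(T)
        for j in range(T):
            a, b = int(cum_e[j]), int(cum_n[j])
            c, d = int(tot_e - a), int(tot_n - b)
            if a + b == 0 or c + d == 0:
                ok = False
                break
            lor, _, corr_used = log_odds_ratio(TwoByTwo(a, b, c, d))
            n_corrected += corr_used
            row[j] = lor
        if ok:
            lors[kept] = row
            kept += 1
    cov = np.cov(lors, rowvar=False).reshape(T, T)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return BootstrapCorrResult(
        cutpoints=intervals.cutpoints,
        corr=corr,
        cov=cov,
        mean_log_or=lors.mean(axis=0),
        se_log_or=lors.std(axis=0, ddof=1),
        n_boot=n_boot,
        seed=-1 if seed is None else int(seed),
        n_corrected=int(n_corrected),
    )


def approx_cov_from_patient_corr(
    rho_patient: float, se_a: float, se_b: float
) -> float:
    """Within-study covariance approximated from a patient-level correlation
    between two measurement methods: rho * se_a * se_b."""
    if not abs(rho_patient) <= 1:
        raise DataError(f"|patient-level correlation| must be <= 1, got {rho_patient}")
    if se_a <= 0 or se_b <= 0:
        raise DataError("standard errors must be positive")
    return rho_patient * se_a * se_b


def load_tables_csv(path) -> dict[str, tuple[list[TwoByTwo], list[float]]]:
    """Read a 2x2-table CSV (columns study_id, cutpoint, a, b, c, d) into
    per-study table lists."""
    df = pd.read_csv(path)
    need = {"study_id", "cutpoint", "a", "b", "c", "d"}
    missing = need - {c.strip().lower() for c in df.columns}
    if missing:
        raise DataError(f"2x2 CSV missing columns: {sorted(missing)}")
    df = df.rename(columns=lambda c: c.strip().lower())
    out: dict[str, tuple[list[TwoByTwo], list[float]]] = {}
    for sid, grp in df.groupby("study_id", sort=False):
        tables = [
            TwoByTwo(int(r.a), int(r.b), int(r.c), int(r.d)) for r in grp.itertuples()
        ]
        out[str(sid)] = (tables, [float(c) for c in grp["cutpoint"]])
    return out
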
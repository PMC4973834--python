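"""Domain types and long-format I/O for cut-point / method meta-analysis.

The central objects are :class:`EffectRecord` (one log odds- or hazard-ratio
estimate at one *level* — a cut-point value, a measurement method, or a
method-at-cut-point combination — in one study), :class:`WithinCovariance`
(the within-study covariance or correlation between two such estimates from
the same cohort), and :class:`MetaDataset`, which bundles the records with a
:class:`LevelRegistry` ordering the levels.  :func:`assemble_blocks` turns a
dataset into per-study observed vectors with their within-study covariance
matrices, the form consumed by the multivariate and trend engines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "EffectRecord",
    "WithinCovariance",
    "Level",
    "LevelRegistry",
    "StudyBlock",
    "MetaDataset",
    "load_long_table",
    "write_long_table",
    "assemble_blocks",
]

VALID_SCALES = ("log_odds", "log_hazard")

#: correlations this close to +/-1 are pulled inside the interval so the
#: assembled within-study covariance matrix stays positive semi-definite
RHO_BOUNDARY_TOL = 1e-9
RHO_CLIP = 1.0 - 1e-9


class DataError(ValueError):
    """Invalid or inconsistent meta-analysis input data."""


def _norm_label(value) -> str:
    """Canonical string form of a study/level identifier (integers and
    integer-valued floats print without a decimal point)."""
    if isinstance(value, float):
        return f"{value:g}"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value).strip()


def make_level_id(cutpoint: float | None, method: str | None) -> str:
    """Canonical level label from a cut-point and/or method name."""
    if cutpoint is not None and method:
        return f"{method}@{cutpoint:g}"
    if cutpoint is not None:
        return f"{cutpoint:g}"
    if method:
        return str(method)
    raise DataError("a level needs a cutpoint, a method, or both")


@dataclass(frozen=True)
class EffectRecord:
    """One prognostic effect estimate at one level in one study.

    ``y`` is a log odds ratio or log hazard ratio comparing subjects with
    factor value <= cut-point against those above it (or comparing groups
    defined by the measurement method); ``se`` is its standard error.
    """

    study_id: str
    level_id: str
    y: float
    se: float
    cutpoint: float | None = None
    method: str | None = None
    scale: str = "log_odds"

    def __post_init__(self) -> None:
        if not (self.se > 0) or not math.isfinite(self.se):
            raise DataError(
                f"study {self.study_id!r} level {self.level_id!r}: se must be > 0, got {self.se}"
            )
        if not math.isfinite(self.y):
            raise DataError(f"study {self.study_id!r} level {self.level_id!r}: non-finite y")
        if self.scale not in VALID_SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")


@dataclass(frozen=True)
class WithinCovariance:
    """Within-study covariance between two effect estimates of one study.

    Exactly one of ``cov`` and ``rho`` is supplied; the other is derived via
    cov = rho * se_a * se_b once the record standard errors are known.
    ``provenance`` records how the number was obtained (bootstrap of
    reconstructed participant data, patient-level-correlation approximation,
    or imputation/sensitivity value).
    """

    study_id: str
    level_a: str
    level_b: str
    cov: float | None = None
    rho: float | None = None
    provenance: str = "imputed"

    def __post_init__(self) -> None:
        if (self.cov is None) == (self.rho is None):
            raise DataError(
                f"study {self.study_id!r} pair ({self.level_a!r}, {self.level_b!r}): "
                "supply exactly one of cov and rho"
            )
        if self.rho is not None and abs(self.rho) > 1:
            raise DataError(
                f"study {self.study_id!r} pair ({self.level_a!r}, {self.level_b!r}): "
                f"|rho| = {abs(self.rho)} > 1"
            )

    def resolve(self, se_a: float, se_b: float) -> tuple[float, float]:
        """Return (cov, rho) given the two standard errors, clipping rho
        toward the interior when it sits numerically on +/-1."""
        if self.rho is not None:
            rho = self.rho
        else:
            rho = self.cov / (se_a * se_b)
            if abs(rho) > 1 + 1e-6:
                raise DataError(
                    f"study {self.study_id!r} pair ({self.level_a!r}, {self.level_b!r}): "
                    f"stated cov implies |rho| = {abs(rho):.4f} > 1"
                )
        if abs(rho) > RHO_CLIP - RHO_BOUNDARY_TOL:
            rho = math.copysign(RHO_CLIP, rho)
        return rho * se_a * se_b, rho


@dataclass(frozen=True)
class Level:
    """A registered analysis level: cut-point value and/or method label."""

    label: str
    cutpoint: float | None = None
    method: str | None = None


@dataclass(frozen=True)
class LevelRegistry:
    """Ordered registry of levels (cut-points ascending, then method name)."""

    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate level labels in registry")
        cuts = [lv.cutpoint for lv in self.levels if lv.cutpoint is not None]
        if any(b < a for a, b in zip(cuts, cuts[1:])):
            raise DataError("registry cut-points must be sorted ascending")
        keys = [(lv.cutpoint, lv.method) for lv in self.levels]
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (cut-point, method) level in registry")

    @property
    def labels(self) -> list[str]:
        return [lv.label for lv in self.levels]

    @property
    def n_cutpoints(self) -> int:
        return len({lv.cutpoint for lv in self.levels if lv.cutpoint is not None})

    @property
    def n_methods(self) -> int:
        return len({lv.method for lv in self.levels if lv.method is not None})

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def cutpoints(self) -> dict[str, float]:
        return {lv.label: lv.cutpoint for lv in self.levels if lv.cutpoint is not None}


@dataclass(frozen=True)
class StudyBlock:
    """A study's observed effect vector with within-study covariance matrix.

    ``levels`` is the ordered sub-tuple of registry labels the study reports;
    ``y`` the observed estimates and ``S`` the (symmetric, positive
    semi-definite) within-study covariance matrix over those levels, with
    se^2 on the diagonal.
    """

    study_id: str
    levels: tuple[str, ...]
    y: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "S", S)
        if y.shape != (len(self.levels),) or S.shape != (len(self.levels), len(self.levels)):
            raise DataError(f"study {self.study_id!r}: block dimensions disagree")
        if not np.allclose(S, S.T):
            raise DataError(f"study {self.study_id!r}: S not symmetric")
        if np.linalg.eigvalsh(S).min() < -1e-10 * max(1.0, np.abs(S).max()):
            raise DataError(f"study {self.study_id!r}: S not positive semi-definite")

    @property
    def dim(self) -> int:
        return len(self.levels)


@dataclass
class MetaDataset:
    """Validated collection of effect records, within-study covariances and
    the level registry they refer to."""

    records: list[EffectRecord]
    within_cov: list[WithinCovariance] = field(default_factory=list)
    registry: LevelRegistry | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("no records")
        if self.registry is None:
            self.registry = registry_from_records(self.records)
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        scales = set()
        labels = set(self.registry.labels)
        for r in self.records:
            key = (r.study_id, r.level_id)
            if key in seen:
                raise DataError(f"duplicate (study, level) pair {key}")
            seen.add(key)
            scales.add(r.scale)
            if r.level_id not in labels:
                raise DataError(f"record level {r.level_id!r} not in registry")
        if len(scales) > 1:
            raise DataError(
                "mixed effect scales (log_odds and log_hazard) in one dataset; "
                "analyse each scale separately"
            )
        for wc in self.within_cov:
            for lv in (wc.level_a, wc.level_b):
                if (wc.study_id, lv) not in seen:
                    raise DataError(
                        f"within-study covariance refers to missing record "
                        f"({wc.study_id!r}, {lv!r})"
                    )

    @property
    def scale(self) -> str:
        return self.records[0].scale

    @property
    def study_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.study_id not in out:
                out.append(r.study_id)
        return out

    def record(self, study_id: str, level_id: str) -> EffectRecord:
        for r in self.records:
            if r.study_id == study_id and r.level_id == level_id:
                return r
        raise KeyError((study_id, level_id))

    def subset_level(self, level_id: str) -> list[EffectRecord]:
        """Records for one level only (the input of a univariate analysis)."""
        out = [r for r in self.records if r.level_id == level_id]
        if not out:
            raise DataError(f"no records at level {level_id!r}")
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        eff = pd.DataFrame(
            {
                "study_id": [r.study_id for r in self.records],
                "cutpoint": [r.cutpoint for r in self.records],
                "method": [r.method for r in self.records],
                "y": [r.y for r in self.records],
                "se": [r.se for r in self.records],
                "scale": [r.scale for r in self.records],
            }
        )
        corr = pd.DataFrame(
            {
                "study_id": [w.study_id for w in self.within_cov],
                "level_a": [w.level_a for w in self.within_cov],
                "level_b": [w.level_b for w in self.within_cov],
                "rho": [w.rho for w in self.within_cov],
                "cov": [w.cov for w in self.within_cov],
                "provenance": [w.provenance for w in self.within_cov],
            }
        )
        return eff, corr


def registry_from_records(records: Iterable[EffectRecord]) -> LevelRegistry:
    """Build the level registry from records, cut-points sorted ascending."""
    seen: dict[str, Level] = {}
    for r in records:
        if r.level_id not in seen:
            seen[r.level_id] = Level(r.level_id, r.cutpoint, r.method)
    ordered = sorted(
        seen.values(),
        key=lambda lv: (
            lv.cutpoint if lv.cutpoint is not None else math.inf,
            lv.method or "",
        ),
    )
    return LevelRegistry(tuple(ordered))


def _parse_effects_frame(
    df: pd.DataFrame, *, default_scale: str, log_transform: bool, flip_sign: bool
) -> list[EffectRecord]:
    cols = {c.strip().lower() for c in df.columns}
    df = df.rename(columns=lambda c: c.strip().lower())
    if "study_id" not in cols:
        raise DataError("missing required column 'study_id'")
    if "se" not in cols:
        raise DataError("missing required column 'se'")
    if "y" not in cols and "effect_ratio" not in cols:
        raise DataError("missing required column 'y' (or 'effect_ratio')")
    records = []
    for _, row in df.iterrows():
        cut = row.get("cutpoint")
        cut = None if cut is None or (isinstance(cut, float) and math.isnan(cut)) else float(cut)
        method = row.get("method")
        if method is not None and (not isinstance(method, str) or not method.strip()):
            method = None
        if isinstance(method, float) and math.isnan(method):
            method = None
        if "y" in cols and not pd.isna(row.get("y")):
            y = float(row["y"])
        else:
            ratio = float(row["effect_ratio"])
            if ratio <= 0:
                raise DataError(f"effect_ratio must be positive, got {ratio}")
            y = math.log(ratio)
        if log_transform and "y" not in cols:
            pass  # already logged above
        if flip_sign:
            y = -y
        scale = row.get("scale")
        if not isinstance(scale, str) or not scale.strip():
            scale = default_scale
        records.append(
            EffectRecord(
                study_id=_norm_label(row["study_id"]),
                level_id=make_level_id(cut, method),
                y=y,
                se=float(row["se"]),
                cutpoint=cut,
                method=method,
                scale=scale,
            )
        )
    return records


def _parse_corr_frame(df: pd.DataFrame) -> list[WithinCovariance]:
    df = df.rename(columns=lambda c: c.strip().lower())
    for col in ("study_id", "level_a", "level_b"):
        if col not in df.columns:
            raise DataError(f"correlation table missing required column {col!r}")
    out = []
    for i, row in df.iterrows():
        rho = row.get("rho")
        cov = row.get("cov")
        rho = None if rho is None or pd.isna(rho) else float(rho)
        cov = None if cov is None or pd.isna(cov) else float(cov)
        if rho is not None and abs(rho) > 1:
            raise DataError(f"correlation row {i}: |rho| = {abs(rho)} > 1")
        prov = row.get("provenance")
        if not isinstance(prov, str) or not prov.strip():
            prov = "imputed"
        out.append(
            WithinCovariance(
                study_id=_norm_label(row["study_id"]),
                level_a=_norm_label(row["level_a"]),
                level_b=_norm_label(row["level_b"]),
                rho=rho,
                cov=cov,
                provenance=prov,
            )
        )
    return out


def load_long_table(
    path: str | Path,
    corr_path: str | Path | None = None,
    *,
    default_scale: str = "log_odds",
    log_transform: bool = False,
    flip_sign: bool = False,
) -> MetaDataset:
    """Read a long-format effects CSV (and optional correlation CSV).

    Expected effect columns: ``study_id``, ``cutpoint`` and/or ``method``,
    ``y`` (log scale) or ``effect_ratio`` (exponentiated; logged on load),
    ``se``, optional ``scale``.  Correlation columns: ``study_id``,
    ``level_a``, ``level_b`` and exactly one of ``rho`` / ``cov``.

    ``flip_sign`` negates every estimate on load, for sources that define the
    comparison group the opposite way round (above vs below the cut-point).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataError("no records")
    records = _parse_effects_frame(
        df, default_scale=default_scale, log_transform=log_transform, flip_sign=flip_sign
    )
    within = _parse_corr_frame(pd.read_csv(corr_path)) if corr_path is not None else []
    return MetaDataset(records=records, within_cov=within)


def write_long_table(
    dataset: MetaDataset, path: str | Path, corr_path: str | Path | None = None
) -> None:
    """Write a dataset back to the long CSV dialect (round-trip safe)."""
    eff, corr = dataset.to_frames()
    eff.to_csv(path, index=False, float_format="%.12g")
    if corr_path is not None:
        corr.to_csv(corr_path, index=False, float_format="%.12g")


def assemble_blocks(
    dataset: MetaDataset,
    *,
    impute_rho: float | None = None,
    warn_missing: bool = True,
) -> list[StudyBlock]:
    """Build per-study effect vectors and within-study covariance matrices.

    Diagonals are se^2; off-diagonals come from the dataset's stated
    covariances/correlations.  Pairs with no stated value default to 0 (with
    a warning) unless ``impute_rho`` supplies a global sensitivity value.
    Studies reporting a single level yield 1x1 blocks.
    """
    order = {lab: i for i, lab in enumerate(dataset.registry.labels)}
    wc_map: dict[tuple[str, str, str], WithinCovariance] = {}
    for wc in dataset.within_cov:
        a, b = sorted((wc.level_a, wc.level_b), key=lambda lab: order[lab])
        wc_map[(wc.study_id, a, b)] = wc

    blocks = []
    for sid in dataset.study_ids:
        recs = sorted(
            (r for r in dataset.records if r.study_id == sid),
            key=lambda r: order[r.level_id],
        )
        labels = tuple(r.level_id for r in recs)
        y = np.array([r.y for r in recs])
        se = np.array([r.se for r in recs])
        S = np.diag(se**2)
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                key = (sid, labels[i], labels[j])
                if key in wc_map:
                    cov, _ = wc_map[key].resolve(se[i], se[j])
                elif impute_rho is not None:
                    cov = impute_rho * se[i] * se[j]
                else:
                    if warn_missing:
                        warnings.warn(
                            f"study {sid!r}: no within-study covariance for pair "
                            f"({labels[i]!r}, {labels[j]!r}); assuming 0",
                            stacklevel=2,
                        )
                    cov = 0.0
                S[i, j] = S[j, i] = cov
        try:
            blocks.append(StudyBlock(study_id=sid, levels=labels, y=y, S=S))
        except DataError as err:
            raise DataError(f"assembling study {sid!r}: {err}") from err
    return blocks


def set_imputed_rho(dataset: MetaDataset, rho: float) -> MetaDataset:
    """Return a copy whose *unstated* pairwise covariances are filled with a
    common correlation ``rho`` (sensitivity-analysis helper)."""
    if not -1 < rho < 1:
        raise DataError(f"imputed rho must lie in (-1, 1), got {rho}")
    order = {lab: i for i, lab in enumerate(dataset.registry.labels)}
    stated = {
        (w.study_id, *sorted((w.level_a, w.level_b), key=lambda lab: order[lab]))
        for w in dataset.within_cov
    }
    extra: list[WithinCovariance] = []
    for sid in dataset.study_ids:
        labs = sorted(
            (r.level_id for r in dataset.records if r.study_id == sid),
            key=lambda lab: order[lab],
        )
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                if (sid, labs[i], labs[j]) not in stated:
                    extra.append(
                        WithinCovariance(
                            study_id=sid,
                            level_a=labs[i],
                            level_b=labs[j],
                            rho=rho,
                            provenance="imputed",
                        )
                    )
    return MetaDataset(
        records=list(dataset.records),
        within_cov=list(dataset.within_cov) + extra,
        registry=dataset.registry,
    )
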
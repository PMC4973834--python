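"""Text tables and figures for fitted meta-analyses."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DataError, StudyBlock
from .multivariate import MVResult, mv_prediction_interval
from .trend import TrendResult, transform_cutpoints
from .univariate import PredictionInterval, UnivariateResult

__all__ = ["univariate_text", "mv_text", "render_trend_plot"]


def _fmt_ci(lo: float, hi: float) -> str:
    return f"[{lo:.2f}, {hi:.2f}]"


def univariate_text(
    result: UnivariateResult, label: str = "", pi: PredictionInterval | None = None
) -> str:
    """Forest-table style one-level summary (log and exponentiated scales)."""
    lines = [
        f"Random-effects meta-analysis ({result.method.upper()}), k = {result.k}"
        + (f" — level {label}" if label else ""),
        f"  Summary log ratio (SE): {result.beta_hat:.2f} ({result.se_beta:.3f})",
        f"  Summary ratio [95% CI]: {result.summary_ratio:.2f} "
        + _fmt_ci(*result.ci_ratio),
        f"  tau: {result.tau_hat:.3f}   Q: {result.Q:.2f}   I2: {result.I2:.1f}%",
    ]
    if pi is not None:
        lines.append(
            f"  95% prediction interval (ratio): {pi.lo_ratio:.2f} to {pi.hi_ratio:.2f}"
            f"  (t df = {pi.df})"
        )
    return "\n".join(lines)


def mv_text(result: MVResult, coverage: float = 0.95) -> str:
    """Multi-level summary mirroring the per-cut-point table layout."""
    lines = [
        f"Multivariate random-effects meta-analysis (REML), "
        f"{result.k} studies, {len(result.levels)} levels "
        f"[{result.spec.structure}]",
    ]
    ci = result.ci()
    for j, lab in enumerate(result.levels):
        pi = mv_prediction_interval(result, j, coverage)
        lines.append(
            f"  {lab:>12}: log ratio {result.beta_hat[j]:.2f} "
            f"({result.se_beta[j]:.3f}); ratio {math.exp(result.beta_hat[j]):.2f} "
            + _fmt_ci(math.exp(ci[j, 0]), math.exp(ci[j, 1]))
            + f"; tau {result.tau[j]:.3f}; PI {pi.lo_ratio:.2f} to {pi.hi_ratio:.2f}"
            f"; n = {result.n_studies[lab]}"
        )
    T = len(result.levels)
    if T > 1:
        corr = result.between_corr
        pairs = ", ".join(
            f"({result.levels[i]},{result.levels[j]}) {corr[i, j]:+.3f}"
            for i in range(T) for j in range(i + 1, T)
        )
        lines.append(f"  between-study correlation: {pairs}")
        if result.boundary:
            lines.append("  note: between-study correlation at the +/-1 boundary")
    return "\n".join(lines)


def render_trend_plot(
    results: Sequence[TrendResult],
    blocks: Sequence[StudyBlock],
    cutpoints: dict[str, float],
    path: str | Path,
    *,
    n_grid: int = 100,
) -> Path:
    """Scatter of per-study log estimates against cut-point with fitted
    trend curve(s) overlaid.  With fewer than two studies the curves are
    suppressed (a single study cannot identify the between-study model)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise DataError("no fitted trend results to plot")
    fig, ax = plt.subplots(figsize=(7, 5))
    for b in blocks:
        xs = [cutpoints[lab] for lab in b.levels]
        ax.plot(xs, b.y, "o-", color="grey", alpha=0.5, markersize=4, linewidth=0.8)
    if len(blocks) >= 2:
        lo = min(cutpoints.values())
        hi = max(cutpoints.values())
        grid = np.linspace(lo, hi, n_grid)
        for res in results:
            fx = transform_cutpoints(grid, res.transform)
            if res.groups is None:
                ax.plot(grid, res.alpha_hat + res.gamma_hat * fx,
                        linewidth=2, label=res.transform.label())
            else:
                for gi, g in enumerate(res.groups):
                    ax.plot(grid, res.coef[2 * gi] + res.coef[2 * gi + 1] * fx,
                            linewidth=2, label=f"{res.transform.label()} [{g}]")
        ax.legend()
    else:
        import warnings

        warnings.warn("single study: fitted curve suppressed", stacklevel=2)
    ax.set_xlabel("cut-point")
    ax.set_ylabel("log effect ratio")
    ax.axhline(0.0, color="black", linewidth=0.5)
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def results_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
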
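"""Descriptive summaries and the standard diagnostic / CI figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .factors import FactorAnalysis, qq_residuals

#: Variables summarised in the descriptive table, with display names.
DESCRIPTIVE_VARIABLES: dict[str, str] = {
    "carbon_tC_ha": "Carbon (tC/ha)",
    "stem_volume_m3_ha": "Stem volume (m3/ha)",
    "mean_dbh_cm": "dbh (cm/plot)",
    "altitude_m": "Altitude (m)",
    "tree_count": "Tree frequency",
}


def descriptive_table(
    subplots: pd.DataFrame, variables: dict[str, str] | None = None
) -> pd.DataFrame:
    """Min/max/median/mean/sd per variable (sd with the n−1 denominator)."""
    variables = variables or DESCRIPTIVE_VARIABLES
    if len(subplots) == 0:
        raise ValueError("cannot summarise an empty table")
    rows = []
    for col, label in variables.items():
        if col not in subplots.columns:
            continue
        s = subplots[col].astype(float)
        rows.append(
            {
                "variable": label,
                "min": s.min(),
                "max": s.max(),
                "median": s.median(),
                "mean": s.mean(),
                "sd": s.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def community_share_pct(subplots: pd.DataFrame) -> float:
    """Share of community-owned subplots, in percent rounded to 2 dp."""
    n = len(subplots)
    if n == 0:
        raise ValueError("empty table")
    return round(100.0 * float((subplots["ownership"] == "community").sum()) / n, 2)


def qq_plot(resid, path: str | Path) -> Path:
    """Normal QQ plot of (standardised) residuals with the y = x diagonal."""
    theo, ordered = qq_residuals(resid)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(theo, ordered, s=12, color="black")
    lim = [min(theo.min(), ordered.min()), max(theo.max(), ordered.max())]
    ax.plot(lim, lim, color="firebrick", lw=1)
    ax.set_xlabel("Theoretical normal quantiles")
    ax.set_ylabel("Standardised residuals")
    ax.set_title("Residual QQ plot")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def ci_plot(
    analysis: FactorAnalysis, factors: list[str], path: str | Path
) -> Path:
    """Adjusted-mean CI panels: one panel per factor.

    Black dots are adjusted level means with 95% CI bars, green dots crude
    level means, the red horizontal line the overall mean of the analysed
    carbon values.
    """
    fig, axes = plt.subplots(
        1, len(factors), figsize=(3.2 * len(factors), 4), sharey=True, squeeze=False
    )
    for ax, factor in zip(axes[0], factors):
        tbl = analysis.contrasts[factor]
        x = np.arange(len(tbl))
        ax.vlines(x, tbl["ci_low"], tbl["ci_high"], color="black", lw=1.5)
        ax.scatter(x, tbl["adjusted_mean"], color="black", zorder=3, label="adjusted")
        ax.scatter(x, tbl["crude_mean"], color="forestgreen", zorder=3, label="crude")
        ax.axhline(analysis.overall_mean, color="firebrick", lw=1)
        ax.set_xticks(x)
        ax.set_xticklabels(tbl["level"], rotation=45, ha="right", fontsize=8)
        ax.set_title(factor, fontsize=10)
    axes[0][0].set_ylabel("Carbon stock (tC/ha)")
    axes[0][-1].legend(fontsize=8, loc="best")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
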
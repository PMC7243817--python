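"""Summary tables and figures for a completed analysis.

Everything here is regenerable from the intermediate CSVs, so a report
directory can be rebuilt without re-running the bootstrap or the MCMC.
CSV output is deterministic (fixed row and column order, fixed float
formatting) so fixed-seed runs reproduce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .compare import ComparisonResult, StopoverTrendResult

__all__ = ["write_report", "plot_quantile_slopes", "plot_passage_changes",
           "plot_comparison"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def _forest(ax, labels, slopes, lo, hi, title):
    ypos = range(len(labels))
    ax.errorbar(slopes, ypos,
                xerr=[[s - l for s, l in zip(slopes, lo)],
                      [h - s for s, h in zip(slopes, hi)]],
                fmt="o", color="black", capsize=2)
    ax.axvline(0.0, ls=":", color="gray")
    ax.set_yticks(list(ypos), labels)
    ax.set_xlabel("days per decade")
    ax.set_title(title)


def plot_quantile_slopes(phenology: pd.DataFrame, path) -> None:
    """Forest plots of quantile slopes, one panel per quantity."""
    quantities = [q for q in phenology["quantity"].unique()]
    fig, axes = plt.subplots(1, len(quantities),
                             figsize=(3.2 * len(quantities), 0.5 + 0.3
                                      * phenology.groupby("quantity").size().max()),
                             squeeze=False)
    for ax, q in zip(axes[0], quantities):
        sub = phenology[phenology["quantity"] == q]
        labels = [f"{s} {n}" for s, n in zip(sub["species"], sub["season"])]
        _forest(ax, labels, sub["slope_dpd"].tolist(), sub["ci_lo"].tolist(),
                sub["ci_hi"].tolist(), q)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_passage_changes(phenology: pd.DataFrame, path) -> None:
    """Passage-duration-change panel (the contrast rows only)."""
    sub = phenology[phenology["quantity"] == "passage_change"]
    fig, ax = plt.subplots(figsize=(4, 0.5 + 0.3 * max(len(sub), 1)))
    labels = [f"{s} {n}" for s, n in zip(sub["species"], sub["season"])]
    _forest(ax, labels, sub["slope_dpd"].tolist(), sub["ci_lo"].tolist(),
            sub["ci_hi"].tolist(), "passage-duration change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comparison(comparison: ComparisonResult, path) -> None:
    """Stopover-trend vs passage-change scatter with the 1:1 line."""
    t = comparison.table
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for season, marker in (("spring", "o"), ("fall", "s")):
        sub = t[t["season"] == season]
        ax.scatter(sub["stopover_slope_dpd"], sub["passage_change_dpd"],
                   marker=marker, label=season,
                   facecolors="none" if season == "spring" else "black",
                   edgecolors="black")
    lim = max(1e-6, float(t[["stopover_slope_dpd", "passage_change_dpd"]]
                          .abs().to_numpy().max())) * 1.1
    ax.plot([-lim, lim], [-lim, lim], ls=":", color="gray", label="1:1")
    ax.set_xlabel("stopover-duration trend (days/decade)")
    ax.set_ylabel("passage-duration change (days/decade)")
    ax.set_title(f"r = {comparison.pearson_r:.3f}, p = {comparison.p_value:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(outdir,
                 phenology: pd.DataFrame | None = None,
                 stopover_trends: list[StopoverTrendResult] | None = None,
                 comparison: ComparisonResult | None = None) -> list[Path]:
    """Write summary CSVs and figures; returns the paths written.

    Missing inputs are skipped with a warning naming what was absent; an
    entirely empty call produces an empty report directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if phenology is not None and len(phenology):
        p = outdir / "phenology_trends.csv"
        phenology.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
        for fn, name in ((plot_quantile_slopes, "quantile_slopes.png"),
                         (plot_passage_changes, "passage_changes.png")):
            fp = outdir / name
            fn(phenology, fp)
            written.append(fp)
    else:
        logger.warning("report: no phenology results provided")

    if stopover_trends:
        p = outdir / "stopover_trends.csv"
        pd.DataFrame([vars(t) for t in stopover_trends]).to_csv(
            p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    else:
        logger.warning("report: no stopover trends provided")

    if comparison is not None:
        p = outdir / "comparison.csv"
        comparison.table.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
        stats = outdir / "comparison_stats.csv"
        pd.DataFrame([{"pearson_r": comparison.pearson_r,
                       "p_value": comparison.p_value,
                       "magnitude_ratio": comparison.magnitude_ratio,
                       "n_pairs": len(comparison.table)}]).to_csv(
            stats, index=False, float_format=_FLOAT_FMT)
        written.append(stats)
        fp = outdir / "comparison.png"
        plot_comparison(comparison, fp)
        written.append(fp)
    else:
        logger.warning("report: no comparison provided")
    return written
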
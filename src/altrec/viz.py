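"""Plots: event histories, joint-CDF contours, marginal/conditional lines.

Event plots draw one horizontal bar per subject, alternating colored
segments for time in the Type I and Type II states, with subjects sorted
by total follow-up (ascending, bottom to top).  Subgroup panels can be
requested with ``by=``: each *categorical* covariate (six or fewer
levels) gets its own panel set; continuous covariates are dropped with a
message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import EpisodeTable
from .nonparam import (
    ConditionalCDFEstimate,
    JointCDFEstimate,
    MarginalSurvivalEstimate,
    NPResult,
)

logger = logging.getLogger("altrec")

TYPE1_COLOR = "#c0392b"   # in care / Type I state
TYPE2_COLOR = "#2e6da4"   # break / Type II state
MAX_BY_LEVELS = 6


@dataclass
class PlotSpec:
    """Declarative plot request used by the command-line layer."""

    kind: str = "events"
    by: tuple[str, ...] = ()
    ascending: bool = True
    palette: tuple[str, str] = (TYPE1_COLOR, TYPE2_COLOR)
    labels: tuple[str, str] = ("Type I", "Type II")
    path: str | None = None
    format: str = "png"


def _qualifying_by(table: EpisodeTable, by: Sequence[str]) -> list[str]:
    """Categorical covariates with <= 6 levels; others dropped, logged."""
    keep = []
    for cov in by:
        if cov not in table.covariate_names:
            logger.info("covariate %r not in the table; dropped from 'by'", cov)
            continue
        vals = table.df[cov]
        n_levels = vals.nunique(dropna=True)
        is_numeric = pd.api.types.is_numeric_dtype(vals)
        if is_numeric and n_levels > MAX_BY_LEVELS:
            logger.info(
                "%s is automatically dropped from the by statement "
                "(possibly continuous: %d distinct numeric values)",
                cov,
                n_levels,
            )
            continue
        if n_levels > MAX_BY_LEVELS:
            logger.info(
                "%s dropped from the by statement (> %d levels)", cov, MAX_BY_LEVELS
            )
            continue
        keep.append(cov)
    return keep


def _draw_events(ax, table: EpisodeTable, spec: PlotSpec):
    order = np.argsort(table.follow_up, kind="stable")
    if not spec.ascending:
        order = order[::-1]
    ids = table.subject_ids[order]
    for pos, sid in enumerate(ids):
        grp = table.df[table.df["id"] == sid]
        left = 0.0
        for _, row in grp.iterrows():
            ax.barh(pos, row["xij"], left=left, color=spec.palette[0], height=0.8)
            left += row["xij"]
            ax.barh(pos, row["yij"], left=left, color=spec.palette[1], height=0.8)
            left += row["yij"]
    ax.set_xlabel("time since entry")
    ax.set_ylabel("subjects (sorted by follow-up)")
    ax.set_yticks([])


def plot_events(table: EpisodeTable, spec: PlotSpec | None = None):
    """Event-history plot(s); returns a list of (name, Figure) pairs.

    Without ``by``: a single figure.  With ``by``: one figure per
    qualifying categorical covariate, one panel per level (covariates
    are paneled separately, never crossed).
    """
    spec = spec or PlotSpec()
    figures = []
    by = _qualifying_by(table, spec.by)
    if not spec.by or not by:
        fig, ax = plt.subplots(figsize=(7, 5))
        _draw_events(ax, table, spec)
        _legend(ax, spec)
        fig.tight_layout()
        figures.append(("events", fig))
    for cov in by:
        first = table.df.groupby("id", sort=False)[cov].first()
        levels = sorted(first.dropna().unique().tolist())
        fig, axes = plt.subplots(
            1, len(levels), figsize=(4 * len(levels), 5), squeeze=False
        )
        for ax, lev in zip(axes[0], levels):
            ids = first.index[first == lev]
            sub = EpisodeTable(
                table.df[table.df["id"].isin(ids)].reset_index(drop=True),
                table.covariate_names,
            )
            _draw_events(ax, sub, spec)
            ax.set_title(f"{cov} = {lev}")
        _legend(axes[0][0], spec)
        fig.tight_layout()
        figures.append((f"events_by_{cov}", fig))
    if spec.path:
        _save(figures, spec)
    return figures


def _legend(ax, spec: PlotSpec):
    import matplotlib.patches as mpatches

    ax.legend(
        handles=[
            mpatches.Patch(color=spec.palette[0], label=spec.labels[0]),
            mpatches.Patch(color=spec.palette[1], label=spec.labels[1]),
        ],
        loc="lower right",
        fontsize="small",
    )


def _save(figures, spec: PlotSpec):
    base = str(spec.path)
    for name, fig in figures:
        out = base if len(figures) == 1 else _suffixed(base, name)
        fig.savefig(out, format=spec.format if "." not in out.split("/")[-1] else None)


def _suffixed(base: str, name: str) -> str:
    if "." in base.split("/")[-1]:
        stem, ext = base.rsplit(".", 1)
        return f"{stem}_{name}.{ext}"
    return f"{base}_{name}"


def plot_joint_contour(est: JointCDFEstimate, path: str | None = None, ax=None):
    """Contour of the joint CDF; cells beyond the censoring support
    (NaN-flagged) are left blank."""
    if len(est.x) == 0:
        raise ValueError("empty estimate grid")
    u1 = np.unique(est.x)
    u2 = np.unique(est.y)
    grid = est.estimate.reshape(len(u1), len(u2))
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    masked = np.ma.masked_invalid(grid.T)
    cs = ax.contourf(u1, u2, masked, levels=10, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="joint CDF")
    ax.set_xlabel("Type I gap time")
    ax.set_ylabel("Type II gap time")
    ax.set_title("Joint CDF of (Type I, Type II) gap times")
    if path:
        fig.savefig(path)
    return fig


def _line_with_band(ax, t, est, lo, hi, level, color, ylabel):
    ax.step(t, est, where="post", color=color)
    if lo is not None:
        ax.fill_between(
            t,
            lo,
            hi,
            step="post",
            alpha=0.25,
            color=color,
            label=f"{level * 100:.0f}% CI",
        )
        ax.legend(fontsize="small")
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel(ylabel)


def plot_marginal(est: MarginalSurvivalEstimate, path: str | None = None, ax=None):
    if len(est.times) == 0:
        raise ValueError("empty estimate grid")
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    _line_with_band(
        ax, est.times, est.survival, est.ci_low, est.ci_high, est.level,
        TYPE1_COLOR, "marginal survival of Type I gaps",
    )
    ax.set_xlabel("Type I gap time")
    if path:
        fig.savefig(path)
    return fig


def plot_conditional(est: ConditionalCDFEstimate, path: str | None = None, ax=None):
    if len(est.y_grid) == 0:
        raise ValueError("empty estimate grid")
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    v1, v2 = est.interval
    _line_with_band(
        ax, est.y_grid, est.cdf, est.ci_low, est.ci_high, est.level,
        TYPE2_COLOR, f"Pr(Y ≤ y | {v1:g} ≤ X ≤ {v2:g})",
    )
    ax.set_xlabel("Type II gap time")
    if path:
        fig.savefig(path)
    return fig


def plot_nonparametric(result: NPResult, path: str | None = None):
    """Single-call panel of every estimate in an NPResult."""
    k = 2 + (result.conditional is not None)
    fig, axes = plt.subplots(1, k, figsize=(5 * k, 4))
    plot_joint_contour(result.joint, ax=axes[0])
    plot_marginal(result.marginal, ax=axes[1])
    if result.conditional is not None:
        plot_conditional(result.conditional, ax=axes[2])
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
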
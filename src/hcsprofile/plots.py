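"""Plot helpers: plate heatmaps, count scatters, DNA-content overlays,
radial fingerprints and embedded dose trajectories.

All functions return a matplotlib Figure and never call ``show``; rendering
choices (e.g. the +0.5 radial offset that keeps residual fingerprints inside
the plot) are display-only and do not feed back into any analysis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data_model import PlateLayout

__all__ = [
    "plate_heatmap",
    "count_scatter",
    "dna_content_overlay",
    "radial_fingerprint",
    "trajectory_plot",
]


def plate_heatmap(wells: pd.DataFrame, layout: PlateLayout, feature: str,
                  title: str | None = None):
    """Well-median heatmap of one feature on one physical plate."""
    rows = list(layout.inner_row_range())
    cols = list(layout.inner_col_range())
    mat = np.full((len(rows), len(cols)), np.nan)
    for rec in wells.itertuples():
        mat[rows.index(rec.row), cols.index(rec.col)] = getattr(rec, feature)
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(range(len(rows)), [chr(ord("A") + r - 1) for r in rows])
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(title or feature)
    fig.colorbar(im, ax=ax, label=feature)
    return fig


def count_scatter(well_counts: pd.DataFrame, control_id: str = "DMSO"):
    """Cell counts per well, controls and treatments side by side, with
    control min/median/max reference lines."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, mask, label in (
        (axes[0], well_counts["treatment"] == control_id, "control wells"),
        (axes[1], well_counts["treatment"] != control_id, "treatment wells"),
    ):
        sub = well_counts[mask].reset_index(drop=True)
        ax.scatter(sub.index, sub["cell_count"], s=6, alpha=0.6)
        ax.set_title(label)
        ax.set_xlabel("well (ordered by plate, replicate)")
        for stat in ("control_min", "control_median", "control_max"):
            ax.axhline(well_counts[stat].iloc[0], ls="--", c="grey", lw=0.8)
    axes[0].set_ylabel("cell count")
    fig.tight_layout()
    return fig


def dna_content_overlay(distributions: pd.DataFrame, compound: str):
    """Dose-series DNA-content density overlay against the global control."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ctl = distributions[distributions["condition"] == "control"]
    ax.plot(ctl["bin_center"], ctl["density"], c="black", lw=2, label="global control")
    sub = distributions[distributions["compound"] == compound]
    for conc, grp in sub.groupby("concentration"):
        ax.plot(grp["bin_center"], grp["density"], lw=1, label=f"{conc:g} uM")
    ax.set_xlabel("DNA content (standardized)")
    ax.set_ylabel("density")
    ax.set_title(compound)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def radial_fingerprint(fingerprints: pd.DataFrame, features, sample_ids=None,
                       offset: float = 0.0, title: str | None = None):
    """Radial (spider) plot of fingerprint rows over the feature axes.

    ``offset`` shifts all values radially for display (use 0.5 for residual
    fingerprints so negative residuals stay visible).
    """
    feats = list(features)
    angles = np.linspace(0, 2 * np.pi, len(feats), endpoint=False)
    angles_c = np.concatenate([angles, angles[:1]])
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"polar": True})
    rows = fingerprints
    if sample_ids is not None:
        rows = rows[rows["sample_id"].isin(set(sample_ids))]
    for rec in rows.itertuples():
        vals = np.array([getattr(rec, f) for f in feats], dtype=float) + offset
        ax.plot(angles_c, np.concatenate([vals, vals[:1]]), lw=0.8, alpha=0.7,
                label=rec.sample_id if len(rows) <= 8 else None)
    ax.set_xticks(angles)
    ax.set_xticklabels(feats, fontsize=6)
    if len(rows) <= 8:
        ax.legend(fontsize=6, loc="lower right")
    if title:
        ax.set_title(title)
    return fig


def trajectory_plot(trajectories: pd.DataFrame, dims=(1, 2), control_points=None):
    """Per-compound dose trajectories in the embedded space."""
    xcol, ycol = f"umap{dims[0]}", f"umap{dims[1]}"
    fig, ax = plt.subplots(figsize=(6, 5))
    if control_points is not None:
        ax.scatter(control_points[:, dims[0] - 1], control_points[:, dims[1] - 1],
                   marker="^", s=12, c="grey", alpha=0.5, label="controls")
    for cpd, grp in trajectories.groupby("compound"):
        grp = grp.sort_values("dose_rank")
        ax.plot(grp[xcol], grp[ycol], lw=0.8, alpha=0.7)
        sc = ax.scatter(grp[xcol], grp[ycol],
                        c=grp.get("pct_of_control"), cmap="RdYlBu", s=18,
                        vmin=0, vmax=120)
        ax.annotate(cpd, (grp[xcol].iloc[-1], grp[ycol].iloc[-1]), fontsize=6)
    fig.colorbar(sc, ax=ax, label="% of control cell count")
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
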
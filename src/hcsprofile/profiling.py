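"""EMD phenotypic profiling against a pooled global control.

After standardization, all control cells of all plates are pooled into a
single *global control* population per feature.  Each sample — every control
well individually, and each treatment condition (compound at one
concentration) with its replicates merged — is then scored per feature by
the EMD between its BZ distribution and the global control, yielding the
samples x features *EMD profile* with per-row metadata (cell counts,
percent-of-control, compound, dose).

Controls are profiled per individual well rather than merged: the spread of
their near-zero entries is the technical-variation band that later anchors
the residual fingerprints.  Cell-count summaries and the cytotoxicity flag
(merged condition count below 30% of the control mean on the plates carrying
that condition, i.e. more than 70% cell reduction) are computed from the raw
(pre-normalization) counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import CONTROL_ID, feature_columns
from .metrics import emd_to_sorted

__all__ = [
    "build_global_control",
    "merge_replicates",
    "emd_profile",
    "cell_count_summary",
    "flag_toxic",
    "dna_content_distributions",
    "PROFILE_META",
]

PROFILE_META = ["sample_id", "kind", "compound", "concentration",
                "plate", "replicate", "row", "col", "cell_count"]


def build_global_control(bz_cells: pd.DataFrame, control_id: str = CONTROL_ID,
                         features=None) -> dict[str, np.ndarray]:
    """Pool the standardized control cells of all plates, per feature.

    Returns feature -> sorted value array (sorted once so repeated EMD
    evaluations are cheap).  Pooling is order-invariant.  By the BZ
    construction the pooled values have median ~0 and MAD ~1.
    """
    ctl = bz_cells[bz_cells["treatment"] == control_id]
    if ctl.empty:
        raise ValueError("no control cells to build the global control from")
    feats = features or feature_columns(bz_cells)
    return {f: np.sort(ctl[f].dropna().values) for f in feats}


def merge_replicates(bz_cells: pd.DataFrame, compound: str, concentration: float,
                     features=None) -> dict[str, np.ndarray]:
    """Concatenate the per-cell values of all replicates of one condition."""
    mask = (bz_cells["treatment"] == compound) & (bz_cells["concentration"] == concentration)
    sub = bz_cells[mask]
    if sub.empty:
        raise ValueError(f"no cells for condition {compound} @ {concentration}")
    feats = features or feature_columns(bz_cells)
    return {f: sub[f].dropna().values for f in feats}


def emd_profile(bz_cells: pd.DataFrame, global_control: dict[str, np.ndarray],
                control_id: str = CONTROL_ID) -> pd.DataFrame:
    """Samples x features EMD profile versus the global control.

    Rows are every individual control well plus every merged treatment
    condition; entries are >= 0 and carry BZ units.  Metadata columns are
    :data:`PROFILE_META`; feature columns follow.
    """
    feats = [f for f in feature_columns(bz_cells) if f in global_control]
    records = []

    ctl = bz_cells[bz_cells["treatment"] == control_id]
    for (plate, rep, row, col), sub in ctl.groupby(["plate", "replicate", "row", "col"]):
        rec = {"sample_id": f"control_{plate}_r{rep}_{row},{col}", "kind": "control",
               "compound": control_id, "concentration": np.nan,
               "plate": plate, "replicate": rep, "row": row, "col": col,
               "cell_count": len(sub)}
        for f in feats:
            vals = sub[f].dropna().values
            rec[f] = emd_to_sorted(vals, global_control[f]) if vals.size else np.nan
        records.append(rec)

    trt = bz_cells[bz_cells["treatment"] != control_id]
    dropped = []
    for (cpd, conc), sub in trt.groupby(["treatment", "concentration"], dropna=False):
        if len(sub) == 0:
            dropped.append((cpd, conc))
            continue
        rec = {"sample_id": f"{cpd}_{conc:g}", "kind": "treatment",
               "compound": cpd, "concentration": conc,
               "plate": sub["plate"].iloc[0], "replicate": np.nan,
               "row": np.nan, "col": np.nan, "cell_count": len(sub)}
        for f in feats:
            vals = sub[f].dropna().values
            rec[f] = emd_to_sorted(vals, global_control[f]) if vals.size else np.nan
        records.append(rec)
    if dropped:
        warnings.warn(f"conditions with zero cells dropped: {dropped}", stacklevel=2)
    return pd.DataFrame.from_records(records)[PROFILE_META + feats]


def cell_count_summary(cells: pd.DataFrame, control_id: str = CONTROL_ID
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw per-well counts and per-condition percent-of-control.

    Returns ``(well_counts, condition_counts)``.  ``well_counts`` has one row
    per well with its raw cell count plus the control reference statistics
    (min, max, median, mean of control well counts) of its plate position.
    ``condition_counts`` aggregates treatment conditions (replicates merged):
    total and mean per-well count and ``pct_of_control`` = mean well count as
    a percent of the mean control well count on the plate position carrying
    the condition.
    """
    counts = (cells.groupby(["plate", "replicate", "row", "col"])
              .agg(treatment=("treatment", "first"),
                   concentration=("concentration", "first"),
                   cell_count=("treatment", "size"))
              .reset_index())
    ctl_stats = (counts[counts["treatment"] == control_id]
                 .groupby("plate")["cell_count"]
                 .agg(control_min="min", control_max="max",
                      control_median="median", control_mean="mean")
                 .reset_index())
    well_counts = counts.merge(ctl_stats, on="plate", how="left")

    trt = counts[counts["treatment"] != control_id]
    cond = (trt.groupby(["treatment", "concentration"], dropna=False)
            .agg(plate=("plate", "first"), n_wells=("cell_count", "size"),
                 total_count=("cell_count", "sum"), mean_count=("cell_count", "mean"))
            .reset_index()
            .rename(columns={"treatment": "compound"}))
    cond = cond.merge(ctl_stats[["plate", "control_mean"]], on="plate", how="left")
    cond["pct_of_control"] = 100.0 * cond["mean_count"] / cond["control_mean"]
    return well_counts, cond


def flag_toxic(condition_counts: pd.DataFrame, threshold: float = 0.30
               ) -> set[tuple[str, float]]:
    """Conditions with merged counts strictly below ``threshold`` of the
    control mean (default: more than 70% cell reduction).  Flagged
    conditions are excluded from feature reduction but stay in the profile.
    """
    toxic = condition_counts[condition_counts["pct_of_control"] < 100.0 * threshold]
    return {(r.compound, r.concentration) for r in toxic.itertuples()}


def dna_content_distributions(cells: pd.DataFrame, feature: str,
                              bins: int = 64, control_id: str = CONTROL_ID
                              ) -> pd.DataFrame:
    """Binned DNA-content (total nucleus intensity) densities per condition.

    One row per (condition, bin) with the density over a common bin grid; the
    ``control`` condition is the pooled global control.  Works on raw or BZ
    values; no cell-cycle phase calling is attempted — the export is the
    overlay payload for dose-series distribution plots.
    """
    if feature not in cells.columns:
        raise KeyError(f"DNA-content feature not present: {feature}")
    vals = cells[feature].dropna()
    edges = np.histogram_bin_edges(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    records = []

    def add(label, compound, conc, v):
        dens, _ = np.histogram(v, bins=edges, density=True)
        for c, d in zip(centers, dens):
            records.append({"condition": label, "compound": compound,
                            "concentration": conc, "bin_center": c, "density": d})

    ctl = cells.loc[cells["treatment"] == control_id, feature].dropna().values
    add("control", control_id, np.nan, ctl)
    trt = cells[cells["treatment"] != control_id]
    for (cpd, conc), sub in trt.groupby(["treatment", "concentration"], dropna=False):
        add(f"{cpd}_{conc:g}", cpd, conc, sub[feature].dropna().values)
    return pd.DataFrame.from_records(records)
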
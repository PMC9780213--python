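"""Positional-effect removal and two-level data standardization.

The correction model is additive: a well median on plate k decomposes as

    m_ij = overall + row_i + col_j + residual_ij

estimated by Tukey's median polish.  For every (plate, feature) pair flagged
by the positional QC, all inner wells (controls *and* treatments) are
adjusted by subtracting the fitted row and column effects; the adjustment
amount ``-(row_i + col_j)`` is stored per well and later applied verbatim to
every cell of that well (the cell-level propagation is strictly additive).

Two standardizations follow:

* the **B score** (well level): polish residuals divided by their per-plate
  median absolute deviation, a plate-comparable QC track;
* the **BZ score** (cell level): each position-adjusted cell value is
  centered on the median and scaled by the MAD of the pooled
  position-adjusted control cells of its plate,

      BZ_ijk = (x_ijk + adj_ij - med(x_control,k)) / mad(x_control,k).

By construction the pooled control cells of every plate have median 0 and
MAD 1 after standardization, which harmonizes feature distributions across
plates and replicates.  MADs are unscaled throughout.  Features with a zero
control MAD are excluded (not epsilon-padded) and reported, to avoid
manufacturing arbitrarily large scores from degenerate scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CONTROL_ID, META_COLUMNS, PlateLayout, feature_columns

__all__ = [
    "PolishDecomposition",
    "median_polish",
    "adjust_wells",
    "b_score",
    "standardize_cells",
]

PLATE_KEYS = ["plate", "replicate"]


@dataclass
class PolishDecomposition:
    """Additive decomposition of a two-way table by median polish."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (self.overall
                + self.row_effects[:, None]
                + self.col_effects[None, :])

    def reconstruct(self) -> np.ndarray:
        """overall + row + col + residual; equals the input up to float error."""
        return self.fitted() + self.residuals


def median_polish(matrix, max_iter: int = 100, tol: float = 1e-6) -> PolishDecomposition:
    """Tukey's median polish of a rows x columns table (NaN gaps allowed).

    Rows are swept first.  Iteration stops when the sum of absolute
    residuals changes by less than ``tol`` (relative), or after
    ``max_iter`` sweeps.  At convergence the medians of the row and column
    effect vectors are ~0 and the decomposition reconstructs the input
    exactly (floating error only).
    """
    res = np.array(matrix, dtype=float)
    if res.ndim != 2:
        raise ValueError("median_polish expects a 2-D table")
    n_r, n_c = res.shape
    ok_rows = np.sum(~np.all(np.isnan(res), axis=1))
    ok_cols = np.sum(~np.all(np.isnan(res), axis=0))
    if np.any(np.all(np.isnan(res), axis=0)) or np.any(np.all(np.isnan(res), axis=1)):
        raise ValueError("median_polish: a row or column is entirely missing")
    if ok_rows < 2 or ok_cols < 2:
        raise ValueError("median_polish needs >=2 rows and >=2 columns with data")

    overall = 0.0
    row = np.zeros(n_r)
    col = np.zeros(n_c)
    old_sum = 0.0
    converged = False
    it = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices guarded above
        for it in range(1, max_iter + 1):
            rdelta = np.nanmedian(res, axis=1)
            res -= rdelta[:, None]
            row += rdelta
            delta = np.median(col)
            col -= delta
            overall += delta

            cdelta = np.nanmedian(res, axis=0)
            res -= cdelta[None, :]
            col += cdelta
            delta = np.median(row)
            row -= delta
            overall += delta

            new_sum = np.nansum(np.abs(res))
            if new_sum == 0 or abs(new_sum - old_sum) < tol * new_sum:
                converged = True
                break
            old_sum = new_sum
    return PolishDecomposition(float(overall), row, col, res, it, converged)


def b_score(residuals: np.ndarray) -> np.ndarray:
    """Per-plate B scores: polish residuals / MAD of the plate's residuals.

    Scale-free: multiplying all residuals by a constant leaves the B scores
    unchanged.  Raises on a zero MAD (degenerate scale).
    """
    res = np.asarray(residuals, dtype=float)
    vals = res[~np.isnan(res)]
    scale = np.median(np.abs(vals - np.median(vals)))
    if scale == 0:
        raise ValueError("b_score: MAD of residuals is zero")
    return res / scale


def _well_matrix(wells_plate: pd.DataFrame, layout: PlateLayout, feature: str):
    rows = list(layout.inner_row_range())
    cols = list(layout.inner_col_range())
    mat = np.full((len(rows), len(cols)), np.nan)
    r_idx = {r: i for i, r in enumerate(rows)}
    c_idx = {c: j for j, c in enumerate(cols)}
    for _, rec in wells_plate.iterrows():
        mat[r_idx[int(rec["row"])], c_idx[int(rec["col"])]] = rec[feature]
    return mat, r_idx, c_idx


def adjust_wells(wells: pd.DataFrame, report: pd.DataFrame, layout: PlateLayout,
                 fit_on: str = "controls") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged positional effects from well medians by median polish.

    Parameters
    ----------
    wells
        Well summary (raw medians).
    report
        Positional QC report with boolean ``flag`` per (plate, replicate,
        feature); detection runs on controls only, correction applies to the
        whole plate.
    fit_on
        "controls" (default): fit the polish on the control-well matrix (the
        diagonal design covers every row and column) and apply the estimated
        row/column effects to every well.  Controls are unbiased sensors of
        positional artifacts; treatment wells would bias the fit whenever
        treatment effects are spatially structured (dilution series run along
        rows), re-introducing artifacts into the corrected controls.
        "all": polish the full inner-plate matrix, controls and treatments
        together.

    Returns
    -------
    (adjusted wells, adjustments)
        ``adjustments`` is long-format: plate, replicate, row, col, feature,
        adjustment (0 for unflagged pairs); the adjusted median is always
        ``raw + adjustment``.
    """
    if fit_on not in ("all", "controls"):
        raise ValueError("fit_on must be 'all' or 'controls'")
    feats = [c for c in feature_columns(wells) if c != "cell_count"]
    adjusted = wells.copy()
    adj_records = []
    flagged = report[report["flag"]] if len(report) else report
    for (plate, rep), sub in wells.groupby(PLATE_KEYS):
        plate_flags = set()
        if len(flagged):
            mask = (flagged["plate"] == plate) & (flagged["replicate"] == rep)
            plate_flags = set(flagged.loc[mask, "feature"])
        for feature in feats:
            if feature not in plate_flags:
                continue
            fit_sub = sub if fit_on == "all" else sub[sub["treatment"] == CONTROL_ID]
            mat, r_idx, c_idx = _well_matrix(fit_sub, layout, feature)
            try:
                polish = median_polish(mat)
            except ValueError as err:
                raise ValueError(
                    f"positional adjustment failed for plate={plate} rep={rep} "
                    f"feature={feature}: {err}") from err
            ri = sub["row"].map(lambda r: polish.row_effects[r_idx[int(r)]])
            cj = sub["col"].map(lambda c: polish.col_effects[c_idx[int(c)]])
            adj = -(ri + cj)
            adjusted.loc[sub.index, feature] = sub[feature] + adj.values
            adj_records.append(pd.DataFrame({
                "plate": plate, "replicate": rep,
                "row": sub["row"].values, "col": sub["col"].values,
                "feature": feature, "adjustment": adj.values,
            }))
    if adj_records:
        adjustments = pd.concat(adj_records, ignore_index=True)
    else:
        adjustments = pd.DataFrame(
            columns=["plate", "replicate", "row", "col", "feature", "adjustment"])
    return adjusted, adjustments


def standardize_cells(cells: pd.DataFrame, adjustments: pd.DataFrame,
                      control_id: str = CONTROL_ID) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell BZ standardization (position adjustment + control scaling).

    Every cell value becomes
    ``(x + well adjustment - med(controls_k)) / mad(controls_k)`` where the
    median/MAD are computed from the position-adjusted control cells pooled
    across all control wells of physical plate k.  Features whose control MAD
    is zero on any plate are dropped with a warning.

    Returns
    -------
    (bz_cells, params)
        ``params`` records per (plate, replicate, feature) the control median
        and MAD actually used.
    """
    feats = feature_columns(cells)
    out = cells.copy()

    # apply well-level adjustments to cells (additive propagation)
    if len(adjustments):
        for feature, adj_f in adjustments.groupby("feature"):
            key = ["plate", "replicate", "row", "col"]
            merged = out[key].merge(adj_f[key + ["adjustment"]], on=key, how="left")
            out[feature] = out[feature] + merged["adjustment"].fillna(0.0).values

    params = []
    drop: set[str] = set()
    for (plate, rep), sub in out.groupby(PLATE_KEYS):
        ctrl = sub[sub["treatment"] == control_id]
        if ctrl.empty:
            raise ValueError(f"no control cells on plate={plate} rep={rep}")
        for feature in feats:
            vals = ctrl[feature].dropna().values
            med = float(np.median(vals))
            scale = float(np.median(np.abs(vals - med)))
            params.append({"plate": plate, "replicate": rep, "feature": feature,
                           "control_median": med, "control_mad": scale})
            if scale == 0:
                drop.add(feature)
                continue
            out.loc[sub.index, feature] = (sub[feature] - med) / scale
    if drop:
        warnings.warn(
            f"features excluded (zero control MAD on some plate): {sorted(drop)}",
            stacklevel=2)
        out = out.drop(columns=sorted(drop))
    return out, pd.DataFrame.from_records(params)
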
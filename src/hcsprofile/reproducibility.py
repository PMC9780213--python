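"""Replicate reproducibility scoring and irreproducible-feature flagging.

Replicate agreement is quantified per feature by scoring every pair of
replicate wells with the three dissimilarity metrics (EMD, KS, |robust Z|)
on their standardized (BZ) cell populations.  Features are then ranked by
their mean pairwise EMD — a high mean EMD means a feature disagrees between
replicates of the *same* condition — and flagged as irreproducible by the
Tukey upper-fence rule (strictly above Q3 + 1.5 x IQR of the per-feature
mean-EMD distribution).

Pair enumeration supports two schemes:

``paired_plates``
    The two-plate screening design: control wells occupy the same positions
    on both plate positions, so each control well id is compared across
    positions over all replicate combinations (R x R pairs, 9 for R = 3);
    each treatment well id exists on a single position and is compared across
    replicates (C(R, 2) pairs, 3 for R = 3).
``within_position``
    Generic design: C(R, 2) within-position replicate pairs for every well,
    controls included.

The default ``auto`` picks ``paired_plates`` when exactly two plate positions
share the same control positions, else ``within_position``.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from . import metrics
from .data_model import CONTROL_ID, feature_columns

__all__ = ["enumerate_pairs", "score_pairs", "flag_irreproducible"]

WELL_KEY = ["plate", "replicate", "row", "col"]


def _well_index(wells: pd.DataFrame) -> pd.DataFrame:
    w = wells[WELL_KEY + ["treatment", "concentration"]].drop_duplicates()
    return w.reset_index(drop=True)


def enumerate_pairs(wells: pd.DataFrame, scheme: str = "auto",
                    control_id: str = CONTROL_ID) -> pd.DataFrame:
    """List the replicate well pairs to score.

    ``wells`` needs the columns plate, replicate, row, col, treatment,
    concentration (a well summary or a cell table both work).  Returns one
    row per unordered pair with ``*_a`` / ``*_b`` well keys and the
    ``condition`` label (``control`` or ``compound_concentration``).  Well
    ids missing a replicate simply contribute fewer pairs (with a warning
    when a treatment well id has a single copy).
    """
    idx = _well_index(wells)
    plates = sorted(idx["plate"].unique())
    if scheme == "auto":
        if len(plates) == 2:
            ctl = [set(map(tuple, idx[(idx["plate"] == p)
                                      & (idx["treatment"] == control_id)][["row", "col"]].values))
                   for p in plates]
            scheme = "paired_plates" if ctl[0] == ctl[1] and ctl[0] else "within_position"
        else:
            scheme = "within_position"
    if scheme not in ("paired_plates", "within_position"):
        raise ValueError(f"unknown pairing scheme: {scheme}")

    records = []

    def emit(a, b, condition):
        records.append({
            "condition": condition,
            "plate_a": a.plate, "replicate_a": a.replicate, "row_a": a.row, "col_a": a.col,
            "plate_b": b.plate, "replicate_b": b.replicate, "row_b": b.row, "col_b": b.col,
        })

    is_ctl = idx["treatment"] == control_id
    if scheme == "paired_plates":
        ctl = idx[is_ctl]
        for (r, c), grp in ctl.groupby(["row", "col"]):
            a_side = grp[grp["plate"] == plates[0]]
            b_side = grp[grp["plate"] == plates[1]]
            for a in a_side.itertuples():
                for b in b_side.itertuples():
                    emit(a, b, "control")
    else:
        ctl = idx[is_ctl]
        for (p, r, c), grp in ctl.groupby(["plate", "row", "col"]):
            for a, b in itertools.combinations(grp.itertuples(), 2):
                emit(a, b, "control")

    trt = idx[~is_ctl]
    n_single = 0
    for (p, r, c), grp in trt.groupby(["plate", "row", "col"]):
        rows = list(grp.itertuples())
        if len(rows) < 2:
            n_single += 1
            continue
        cond = f"{rows[0].treatment}_{rows[0].concentration:g}"
        for a, b in itertools.combinations(rows, 2):
            emit(a, b, cond)
    if n_single:
        warnings.warn(f"{n_single} treatment well ids had a single replicate; skipped",
                      stacklevel=2)
    return pd.DataFrame.from_records(records)


def score_pairs(bz_cells: pd.DataFrame, pairs: pd.DataFrame,
                features=None) -> pd.DataFrame:
    """Score every pair per feature with EMD, KS and |robust Z|.

    One output row per (pair, feature) with the two sample sizes; pairs where
    either well has no cells for a feature are skipped and logged.
    """
    feats = features or feature_columns(bz_cells)
    # gather per-well feature arrays once
    store: dict[tuple, dict[str, np.ndarray]] = {}
    for key, sub in bz_cells.groupby(WELL_KEY):
        store[key] = {f: sub[f].dropna().values for f in feats}

    records = []
    n_skipped = 0
    for p in pairs.itertuples():
        ka = (p.plate_a, p.replicate_a, p.row_a, p.col_a)
        kb = (p.plate_b, p.replicate_b, p.row_b, p.col_b)
        da = store.get(ka)
        db = store.get(kb)
        if da is None or db is None:
            n_skipped += len(feats)
            continue
        for f in feats:
            a, b = da[f], db[f]
            if a.size == 0 or b.size == 0:
                n_skipped += 1
                continue
            try:
                z = abs(metrics.robust_z(a, b))
            except ValueError:
                z = np.nan
            records.append({
                "feature": f, "condition": p.condition,
                "plate_a": p.plate_a, "replicate_a": p.replicate_a,
                "well_a": f"{p.row_a},{p.col_a}",
                "plate_b": p.plate_b, "replicate_b": p.replicate_b,
                "well_b": f"{p.row_b},{p.col_b}",
                "n1": a.size, "n2": b.size,
                "ks": metrics.ks_stat(a, b),
                "emd": metrics.emd(a, b),
                "z": z,
            })
    if n_skipped:
        warnings.warn(f"{n_skipped} pair-feature scores skipped (empty wells)",
                      stacklevel=2)
    return pd.DataFrame.from_records(records)


def flag_irreproducible(scores: pd.DataFrame, iqr_factor: float = 1.5,
                        conditions: str = "all") -> pd.DataFrame:
    """Per-feature mean pairwise EMD with Tukey upper-fence outlier flags.

    A feature is flagged when its mean EMD lies *strictly* above
    Q3 + ``iqr_factor`` x IQR of the per-feature mean-EMD distribution
    (quartiles by linear interpolation).  ``conditions`` restricts the pairs
    used ("all" pools control and treatment pairs; "control" uses controls
    only).  Needs >= 4 features for the quartiles to be meaningful.
    """
    sub = scores if conditions == "all" else scores[scores["condition"] == "control"]
    mean_emd = sub.groupby("feature")["emd"].mean().sort_values(ascending=False)
    if len(mean_emd) < 4:
        raise ValueError("flag_irreproducible needs >= 4 features")
    q1, q3 = np.percentile(mean_emd.values, [25, 75])
    fence = q3 + iqr_factor * (q3 - q1)
    out = mean_emd.reset_index().rename(columns={"emd": "mean_emd"})
    out["fence"] = fence
    out["flag"] = out["mean_emd"] > fence
    return out
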
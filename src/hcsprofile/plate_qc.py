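"""Detection of plate positional (row/column) effects on control wells.

For each physical plate and each feature, the control-well medians are
modeled additively as a function of the two categorical factors row and
column with a two-way ANOVA (no interaction; the diagonal control design is
unbalanced, so Type-II sums of squares are used).  A feature is flagged as
positionally affected on a plate when either factor's -log(P) exceeds the
detection threshold; the companion correction (see :mod:`.normalize`) then
adjusts the whole plate for that feature.

The threshold convention is the natural logarithm with default
-log(P) > 10, i.e. P < e^-10 ~ 4.5e-5 (consistent with a "P < 0.0001"
working significance level); the base is configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_model import CONTROL_ID, FeatureCatalog, PlateLayout, feature_columns

__all__ = ["anova_positional", "positional_report", "qc_summary", "DEFAULT_NEGLOGP"]

#: Default flagging threshold on -log(P) (natural log).
DEFAULT_NEGLOGP = 10.0

_P_FLOOR = 1e-300  # keep -log(P) finite when the F statistic overflows


def anova_positional(medians: pd.DataFrame, value: str = "value"
                     ) -> tuple[float, float, float, float]:
    """Two-way additive ANOVA of control-well medians on row and column.

    Parameters
    ----------
    medians
        One row per control well with integer ``row``/``col`` positions and
        the well median in column ``value``.

    Returns
    -------
    (F_row, P_row, F_col, P_col)
        Type-II F statistics and P values.  A factor with (numerically) zero
        explained variance reports F = 0, P = 1; a saturated noiseless fit
        reports P at a tiny positive floor.

    Raises
    ------
    ValueError
        fewer than 2 distinct control rows/columns, or no residual degree of
        freedom (degenerate design).
    """
    df = medians.copy()
    n_r = df["row"].nunique()
    n_c = df["col"].nunique()
    if n_r < 2 or n_c < 2:
        raise ValueError("anova_positional: need >=2 distinct control rows and columns")
    df_resid = len(df) - 1 - (n_r - 1) - (n_c - 1)
    if df_resid < 1:
        raise ValueError("anova_positional: no residual degrees of freedom")
    df = df.rename(columns={value: "y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on near-perfect fits
        fit = smf.ols("y ~ C(row) + C(col)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)

    def _extract(term: str) -> tuple[float, float]:
        ss = float(table.loc[term, "sum_sq"])
        f = table.loc[term, "F"]
        p = table.loc[term, "PR(>F)"]
        total = float(np.var(df["y"])) * len(df)
        if total == 0 or ss <= 1e-12 * max(total, 1.0):
            return 0.0, 1.0  # factor explains (numerically) nothing
        if not np.isfinite(f):  # zero residual variance: perfect additive fit
            return float("inf"), _P_FLOOR
        return float(f), float(max(p, _P_FLOOR))

    f_r, p_r = _extract("C(row)")
    f_c, p_c = _extract("C(col)")
    return f_r, p_r, f_c, p_c


def positional_report(wells: pd.DataFrame, layout: PlateLayout,
                      features=None, threshold: float = DEFAULT_NEGLOGP,
                      log_base: float = np.e,
                      control_id: str = CONTROL_ID) -> pd.DataFrame:
    """Run the positional ANOVA per (physical plate, feature) on control wells.

    Returns a long report with F/P/-log(P) for both factors and the flags
    ``flag_row``, ``flag_col`` and ``flag`` (= row OR column exceeds the
    threshold).  Degenerate (plate, feature) designs are skipped with a
    warning.  Flags are invariant to affine rescaling of a feature.
    """
    feats = features or [c for c in feature_columns(wells) if c != "cell_count"]
    scale = np.log(log_base)
    records = []
    for (plate, rep), sub in wells.groupby(["plate", "replicate"]):
        ctrl = sub[sub["treatment"] == control_id]
        for feature in feats:
            data = ctrl[["row", "col", feature]].dropna().rename(columns={feature: "value"})
            try:
                f_r, p_r, f_c, p_c = anova_positional(data)
            except ValueError as err:
                warnings.warn(f"plate={plate} rep={rep} feature={feature} skipped: {err}",
                              stacklevel=2)
                continue
            nl_r = -np.log(p_r) / scale
            nl_c = -np.log(p_c) / scale
            records.append({
                "plate": plate, "replicate": rep, "feature": feature,
                "f_row": f_r, "p_row": p_r, "neglogp_row": nl_r,
                "f_col": f_c, "p_col": p_c, "neglogp_col": nl_c,
                "flag_row": nl_r > threshold, "flag_col": nl_c > threshold,
                "flag": (nl_r > threshold) or (nl_c > threshold),
            })
    return pd.DataFrame.from_records(records)


def qc_summary(report: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Share of (plate, feature) pairs flagged, per marker and feature class.

    The long ``report`` itself is the plotting payload for the per-feature
    -log(P) curves; this summary condenses it to prevalence figures (e.g.
    intensity features typically dominate the flagged share).
    """
    if report.empty:
        raise ValueError("qc_summary: empty report")
    ann = catalog.table[["feature", "marker", "feature_class"]]
    merged = report.merge(ann, on="feature", how="left")
    out = (merged.groupby(["marker", "feature_class"])
           .agg(n_tests=("flag", "size"),
                n_flagged=("flag", "sum"),
                n_flagged_row=("flag_row", "sum"),
                n_flagged_col=("flag_col", "sum"))
           .reset_index())
    out["flagged_share"] = out["n_flagged"] / out["n_tests"]
    return out
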
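"""Four-filter feature-reduction cascade.

Features are removed, in a fixed order, when they are

1. **irreproducible** — flagged by the replicate mean-EMD Tukey fence;
2. **biologically irrelevant** — their (marker, compartment) pairing is
   marked irrelevant in the feature catalog (nuclear markers measured in the
   cytoplasm and vice versa, plus assay-specific exclusions such as
   bleed-through channels, which are catalog data, not algorithm);
3. **redundant** — from every pair of profile columns with |Pearson r| at or
   above the threshold (default 0.9), the weaker member (lower variance
   across non-toxic treatment rows of the EMD profile) is removed;
4. **inactive** — treatment-row variance below twice the control-row
   variance ("active" features must respond at least twice as strongly to
   treatments as the technical variation among controls).

The correlation and variance filters operate on the EMD profile (not raw
per-cell values), restricted to non-toxic treatment rows.  Every decision is
deterministic given the profile; ties break by feature name.  The cascade
emits a ledger whose set algebra always balances and which is idempotent on
its own output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureCatalog

__all__ = [
    "ReductionLedger",
    "filter_irreproducible",
    "filter_irrelevant",
    "filter_correlated",
    "filter_low_variance",
    "run_cascade",
]


@dataclass
class ReductionLedger:
    """Ordered record of the cascade: per filter, what was removed."""

    initial: list[str]
    steps: list[tuple[str, list[str]]] = field(default_factory=list)

    def record(self, name: str, removed) -> None:
        self.steps.append((name, sorted(removed)))

    @property
    def final(self) -> list[str]:
        remaining = list(self.initial)
        for _, removed in self.steps:
            remaining = [f for f in remaining if f not in set(removed)]
        return remaining

    def counts(self) -> pd.DataFrame:
        rows = []
        remaining = len(self.initial)
        for name, removed in self.steps:
            remaining -= len(removed)
            rows.append({"filter": name, "n_removed": len(removed),
                         "n_remaining": remaining})
        return pd.DataFrame.from_records(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": "initial", "feature": f} for f in self.initial]
        for name, removed in self.steps:
            rows += [{"filter": name, "feature": f} for f in removed]
        rows += [{"filter": "active", "feature": f} for f in self.final]
        return pd.DataFrame.from_records(rows)


def filter_irreproducible(reproducibility_flags: pd.DataFrame,
                          features=None) -> list[str]:
    """Features flagged by the replicate mean-EMD IQR fence."""
    flagged = reproducibility_flags.loc[reproducibility_flags["flag"], "feature"]
    pool = set(features) if features is not None else None
    return sorted(f for f in flagged if pool is None or f in pool)


def filter_irrelevant(catalog: FeatureCatalog, features=None) -> list[str]:
    """Features whose catalog entry is marked biologically irrelevant."""
    table = catalog.table
    if table["relevant"].isna().any():
        bad = table.loc[table["relevant"].isna(), "feature"].tolist()
        raise ValueError(f"catalog entries missing relevance flag: {bad}")
    out = table.loc[~table["relevant"].astype(bool), "feature"]
    pool = set(features) if features is not None else None
    return sorted(f for f in out if pool is None or f in pool)


def _treatment_matrix(profile: pd.DataFrame, features, exclude_toxic=frozenset()
                      ) -> pd.DataFrame:
    rows = profile[profile["kind"] == "treatment"]
    if exclude_toxic:
        keep = [not ((r.compound, r.concentration) in exclude_toxic)
                for r in rows.itertuples()]
        rows = rows[keep]
    return rows[list(features)]


def filter_correlated(profile: pd.DataFrame, features, threshold: float = 0.9,
                      exclude_toxic=frozenset()) -> list[str]:
    """Greedy removal of the weaker member of highly correlated column pairs.

    Pairs with |Pearson r| >= ``threshold`` are visited in descending |r|;
    if neither member has been removed yet, the one with lower variance
    across (non-toxic) treatment rows goes (tie: lexicographically later
    name).  Constant columns have undefined correlations; they are left to
    the variance filter, with a warning.
    """
    feats = list(features)
    mat = _treatment_matrix(profile, feats, exclude_toxic)
    if len(mat) < 3:
        raise ValueError("correlation filter needs >= 3 treatment rows")
    variances = mat.var(ddof=1)
    constant = [f for f in feats if variances[f] == 0]
    if constant:
        warnings.warn(f"constant profile columns (correlation undefined): {constant}",
                      stacklevel=2)
    corr = mat.corr().values
    order = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                order.append((abs(r), feats[i], feats[j]))
    order.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[str] = set()
    for _, fa, fb in order:
        if fa in removed or fb in removed:
            continue
        va, vb = variances[fa], variances[fb]
        if va < vb:
            removed.add(fa)
        elif vb < va:
            removed.add(fb)
        else:
            removed.add(max(fa, fb))
    return sorted(removed)


def filter_low_variance(profile: pd.DataFrame, features, ratio: float = 2.0,
                        exclude_toxic=frozenset()) -> list[str]:
    """Remove features whose treatment variance is below ``ratio`` x their
    control variance (boundary: exactly ``ratio`` x is kept — "at least
    double" is inclusive)."""
    feats = list(features)
    trt = _treatment_matrix(profile, feats, exclude_toxic)
    ctl = profile.loc[profile["kind"] == "control", feats]
    if len(trt) < 2 or len(ctl) < 2:
        raise ValueError("variance filter needs >= 2 control and >= 2 treatment rows")
    v_t = trt.var(ddof=1)
    v_c = ctl.var(ddof=1)
    return sorted(f for f in feats if v_t[f] < ratio * v_c[f])


def run_cascade(profile: pd.DataFrame, catalog: FeatureCatalog,
                reproducibility_flags: pd.DataFrame,
                toxic_conditions=frozenset(),
                corr_threshold: float = 0.9,
                variance_ratio: float = 2.0) -> ReductionLedger:
    """Apply the four filters in order and return the ledger.

    Toxic conditions are excluded from the correlation and variance steps
    (their profiles remain in the EMD profile itself).  Re-running the
    cascade on its own reduced output removes nothing further for the
    catalog- and reproducibility-driven steps, and nothing at all when the
    profile statistics are unchanged.
    """
    meta = [c for c in profile.columns if c in
            ("sample_id", "kind", "compound", "concentration", "plate",
             "replicate", "row", "col", "cell_count")]
    features = [c for c in profile.columns if c not in meta]
    ledger = ReductionLedger(initial=list(features))
    remaining = list(features)

    removed = filter_irreproducible(reproducibility_flags, remaining)
    ledger.record("irreproducible", removed)
    remaining = [f for f in remaining if f not in set(removed)]

    removed = filter_irrelevant(catalog, remaining)
    ledger.record("irrelevant", removed)
    remaining = [f for f in remaining if f not in set(removed)]

    removed = filter_correlated(profile, remaining, corr_threshold,
                                exclude_toxic=toxic_conditions)
    ledger.record("correlated", removed)
    remaining = [f for f in remaining if f not in set(removed)]

    removed = filter_low_variance(profile, remaining, variance_ratio,
                                  exclude_toxic=toxic_conditions)
    ledger.record("low_variance", removed)
    return ledger
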
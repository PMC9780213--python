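"""Phenotypic fingerprints, clustering, embedding and dose trajectories.

An EMD profile becomes a *fingerprint* in two steps: entries are
log1p-transformed (EMD entries can be exactly zero) and each feature column
is min-max scaled to [0, 1] over the combined control + treatment sample
set.  *Residual* fingerprints subtract the per-feature median of the control
rows, so control residuals fluctuate around zero and every treatment row is
directly comparable to the control band.  A +0.5 offset for radial plots is
rendering-only and never enters analysis.

Similarity analysis uses hierarchical clustering (Euclidean distance,
average linkage / UPGMA) and a 3-D UMAP embedding (wrapping the published
algorithm's reference implementation, seeded for determinism).  Per-compound
*dose trajectories* are the embedded coordinates ordered by ascending
concentration, annotated with percent-of-control cell counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .profiling import PROFILE_META

__all__ = [
    "scale_profile",
    "residual_fingerprints",
    "hcluster",
    "linkage_to_newick",
    "embed_umap",
    "extract_trajectories",
    "profile_features",
]


def profile_features(profile: pd.DataFrame) -> list[str]:
    return [c for c in profile.columns if c not in PROFILE_META]


def scale_profile(profile: pd.DataFrame, features=None) -> pd.DataFrame:
    """log1p + per-feature min-max scaling to [0, 1] over all rows.

    Within a column the ordering of entries is preserved and both 0 and 1
    are attained.  A constant column cannot be scaled and maps to all zeros
    (with a warning).
    """
    feats = features or profile_features(profile)
    out = profile.copy()
    degenerate = []
    for f in feats:
        v = np.log1p(out[f].values.astype(float))
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            degenerate.append(f)
            out[f] = 0.0
        else:
            out[f] = (v - lo) / (hi - lo)
    if degenerate:
        warnings.warn(f"constant profile columns scaled to 0: {degenerate}",
                      stacklevel=2)
    return out


def residual_fingerprints(scaled: pd.DataFrame, features=None) -> pd.DataFrame:
    """Scaled profile minus the per-feature median over control rows.

    The per-feature median of the control residuals is exactly zero by
    construction.
    """
    feats = features or profile_features(scaled)
    ctl = scaled[scaled["kind"] == "control"]
    if ctl.empty:
        raise ValueError("residual_fingerprints: no control rows")
    med = ctl[feats].median()
    out = scaled.copy()
    out[feats] = scaled[feats] - med
    return out


def hcluster(matrix: pd.DataFrame | np.ndarray, k: int = 4
             ) -> tuple[np.ndarray, np.ndarray]:
    """UPGMA clustering: Euclidean distance, average linkage.

    Returns the scipy linkage matrix and the labels from cutting the
    dendrogram into ``k`` clusters.  Rows with undefined entries are
    rejected.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("hcluster needs a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("hcluster: matrix contains undefined entries")
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, labels


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Export a scipy linkage matrix as a Newick string (branch lengths from
    merge heights)."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def embed_umap(matrix: pd.DataFrame | np.ndarray, n_dims: int = 3,
               seed: int = 0, n_neighbors: int = 15,
               min_dist: float = 0.1) -> np.ndarray:
    """UMAP embedding of fingerprint rows (deterministic given ``seed``).

    Thin wrapper over umap-learn; hyperparameter defaults are the library's
    usual choices and are overridable.  Requires at least ``n_dims + 2``
    rows.
    """
    X = np.asarray(matrix, dtype=float)
    if len(X) < n_dims + 2:
        raise ValueError(f"embed_umap needs >= {n_dims + 2} rows, got {len(X)}")
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(n_components=n_dims, random_state=seed,
                        n_neighbors=min(n_neighbors, len(X) - 1),
                        min_dist=min_dist)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a seed disables parallelism
        return reducer.fit_transform(X)


def extract_trajectories(embedding: np.ndarray, metadata: pd.DataFrame,
                         condition_counts: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Dose-ordered embedded trajectories, one polyline per compound.

    ``metadata`` must align row-wise with ``embedding`` and carry ``kind``,
    ``compound`` and ``concentration``.  Rows are returned sorted by compound
    then ascending concentration, with ``dose_rank`` (1 = lowest dose) and,
    when ``condition_counts`` is given, the percent-of-control cell count.
    Single-dose compounds yield single-point trajectories (warned).
    """
    emb = np.asarray(embedding, dtype=float)
    meta = metadata.reset_index(drop=True)
    if len(emb) != len(meta):
        raise ValueError("embedding and metadata row counts differ")
    cols = {f"umap{d + 1}": emb[:, d] for d in range(emb.shape[1])}
    df = pd.concat([meta[["kind", "compound", "concentration"]],
                    pd.DataFrame(cols)], axis=1)
    df = df[df["kind"] == "treatment"].copy()
    if condition_counts is not None:
        df = df.merge(condition_counts[["compound", "concentration", "pct_of_control"]],
                      on=["compound", "concentration"], how="left")
    df = df.sort_values(["compound", "concentration"]).reset_index(drop=True)
    df["dose_rank"] = df.groupby("compound")["concentration"].rank(method="first").astype(int)
    singles = df.groupby("compound").size()
    singles = singles[singles == 1].index.tolist()
    if singles:
        warnings.warn(f"single-dose trajectories: {singles}", stacklevel=2)
    return df
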
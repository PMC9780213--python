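"""End-to-end orchestration of the profiling pipeline.

Stages run in the fixed order

    positional QC -> well adjustment + BZ standardization ->
    replicate reproducibility -> EMD profiling (+ counts, toxicity) ->
    feature reduction -> fingerprints / clustering / embedding / trajectories

All thresholds carry the published defaults (-log(P) > 10 for positional
detection, |r| >= 0.9 correlation, 2x variance ratio, 30% of control counts
for toxicity, 1.5 x IQR reproducibility fence) and every run records them in
a manifest together with seeds and per-stage row/feature counts.  Stages
never mutate each other's outputs; re-running downstream stages from cached
upstream results is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (CONTROL_ID, FeatureCatalog, PlateLayout,
                         summarize_wells, write_csv_with_header)
from .feature_reduction import ReductionLedger, run_cascade
from .fingerprints import (embed_umap, extract_trajectories, hcluster,
                           linkage_to_newick, profile_features,
                           residual_fingerprints, scale_profile)
from .normalize import adjust_wells, standardize_cells
from .plate_qc import DEFAULT_NEGLOGP, positional_report, qc_summary
from .profiling import (build_global_control, cell_count_summary, emd_profile,
                        flag_toxic)
from .reproducibility import enumerate_pairs, flag_irreproducible, score_pairs

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and seeds for one pipeline run (published defaults)."""

    neglogp_threshold: float = DEFAULT_NEGLOGP
    corr_threshold: float = 0.9
    variance_ratio: float = 2.0
    toxicity_cut: float = 0.30      # flag below this fraction of control counts
    iqr_factor: float = 1.5
    n_clusters: int = 4
    umap_dims: int = 3
    umap_seed: int = 7
    pairing_scheme: str = "auto"
    control_id: str = CONTROL_ID


@dataclass
class PipelineResult:
    wells: pd.DataFrame
    qc_report: pd.DataFrame
    qc_by_class: pd.DataFrame
    adjusted_wells: pd.DataFrame
    adjustments: pd.DataFrame
    bz_cells: pd.DataFrame
    standardization: pd.DataFrame
    pair_scores: pd.DataFrame
    reproducibility: pd.DataFrame
    profile: pd.DataFrame
    well_counts: pd.DataFrame
    condition_counts: pd.DataFrame
    toxic: set
    ledger: ReductionLedger
    scaled: pd.DataFrame
    residuals: pd.DataFrame
    linkage: np.ndarray
    cluster_labels: np.ndarray
    embedding: np.ndarray
    trajectories: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(cells: pd.DataFrame, layout: PlateLayout, catalog: FeatureCatalog,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a validated cell table and return all artifacts."""
    cfg = config or PipelineConfig()
    manifest: dict = {
        "version": __version__,
        "thresholds": asdict(cfg),
        "n_cells": int(len(cells)),
    }

    wells = summarize_wells(cells)
    manifest["n_wells"] = int(len(wells))

    report = positional_report(wells, layout, threshold=cfg.neglogp_threshold,
                               control_id=cfg.control_id)
    by_class = qc_summary(report, catalog)
    manifest["n_flagged_plate_features"] = int(report["flag"].sum())

    adjusted, adjustments = adjust_wells(wells, report, layout)
    bz_cells, standardization = standardize_cells(cells, adjustments,
                                                  control_id=cfg.control_id)

    pairs = enumerate_pairs(wells, scheme=cfg.pairing_scheme,
                            control_id=cfg.control_id)
    scores = score_pairs(bz_cells, pairs)
    rep_flags = flag_irreproducible(scores, iqr_factor=cfg.iqr_factor)
    manifest["n_pairs"] = int(len(pairs))
    manifest["n_irreproducible"] = int(rep_flags["flag"].sum())

    gc = build_global_control(bz_cells, control_id=cfg.control_id)
    profile = emd_profile(bz_cells, gc, control_id=cfg.control_id)
    well_counts, cond_counts = cell_count_summary(cells, control_id=cfg.control_id)
    toxic = flag_toxic(cond_counts, threshold=cfg.toxicity_cut)
    manifest["n_profile_rows"] = int(len(profile))
    manifest["n_toxic_conditions"] = len(toxic)

    ledger = run_cascade(profile, catalog, rep_flags, toxic_conditions=toxic,
                         corr_threshold=cfg.corr_threshold,
                         variance_ratio=cfg.variance_ratio)
    active = ledger.final
    if not active:
        # a screen with no responsive features (e.g. a clean negative control
        # run) still gets fingerprints, on the unreduced feature set
        warnings.warn("feature reduction removed every feature; "
                      "visualization stages use the full feature set")
        active = ledger.initial
    manifest["feature_counts"] = {
        "initial": len(ledger.initial),
        **{name: len(removed) for name, removed in ledger.steps},
        "active": len(ledger.final),
    }
    manifest["n_visualized_features"] = len(active)

    scaled = scale_profile(profile[[c for c in profile.columns
                                    if c not in profile_features(profile)
                                    or c in active]])
    residuals = residual_fingerprints(scaled)
    Z, labels = hcluster(scaled[active].values, k=cfg.n_clusters)
    emb = embed_umap(scaled[active].values, n_dims=cfg.umap_dims, seed=cfg.umap_seed)
    traj = extract_trajectories(emb, scaled, cond_counts)
    manifest["n_clusters"] = int(len(set(labels)))

    return PipelineResult(
        wells=wells, qc_report=report, qc_by_class=by_class,
        adjusted_wells=adjusted, adjustments=adjustments,
        bz_cells=bz_cells, standardization=standardization,
        pair_scores=scores, reproducibility=rep_flags,
        profile=profile, well_counts=well_counts,
        condition_counts=cond_counts, toxic=toxic, ledger=ledger,
        scaled=scaled, residuals=residuals,
        linkage=Z, cluster_labels=labels, embedding=emb, trajectories=traj,
        manifest=manifest,
    )


def write_outputs(result: PipelineResult, out_dir, active_only: bool = False) -> None:
    """Persist every stage artifact as '#'-headed CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": result.manifest.get("version", "")}
    write_csv_with_header(result.wells, out / "well_summary.csv", meta)
    write_csv_with_header(result.qc_report, out / "positional_report.csv", meta)
    write_csv_with_header(result.qc_by_class, out / "positional_summary.csv", meta)
    write_csv_with_header(result.adjusted_wells, out / "adjusted_wells.csv", meta)
    write_csv_with_header(result.standardization, out / "standardization_params.csv", meta)
    write_csv_with_header(result.pair_scores, out / "replicate_pair_scores.csv", meta)
    write_csv_with_header(result.reproducibility, out / "feature_reproducibility.csv", meta)
    write_csv_with_header(result.profile, out / "emd_profile.csv", meta)
    write_csv_with_header(result.well_counts, out / "well_counts.csv", meta)
    write_csv_with_header(result.condition_counts, out / "condition_counts.csv", meta)
    write_csv_with_header(result.ledger.to_frame(), out / "reduction_ledger.csv", meta)
    write_csv_with_header(result.scaled, out / "fingerprints_scaled.csv", meta)
    write_csv_with_header(result.residuals, out / "fingerprints_residual.csv", meta)
    write_csv_with_header(result.trajectories, out / "trajectories.csv", meta)
    emb = pd.DataFrame(result.embedding,
                       columns=[f"umap{i + 1}" for i in range(result.embedding.shape[1])])
    emb.insert(0, "sample_id", result.scaled["sample_id"].values)
    emb["cluster"] = result.cluster_labels
    write_csv_with_header(emb, out / "embedding.csv", meta)
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(linkage_to_newick(result.linkage, result.scaled["sample_id"]))
    with open(out / "manifest.json", "w") as fh:
        json.dump({**result.manifest,
                   "toxic_conditions": sorted(f"{c}_{k:g}" for c, k in result.toxic)},
                  fh, indent=2)
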
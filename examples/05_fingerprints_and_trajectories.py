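"""Phenotypic fingerprints, clustering and embedded dose trajectories.

Scales the EMD profile to [0,1] fingerprints, clusters control + strongly
active rows, and prints how far each compound's UMAP trajectory travels along
its concentration gradient (dose-responsive and toxic compounds move; the
low-stress ones stay put).  Also writes the radial-fingerprint and trajectory
figures next to this script.
"""

import warnings
from pathlib import Path

import numpy as np

import hcsprofile as h
from hcsprofile import plots
from hcsprofile.simulate import default_config

cfg = default_config(seed=0)
cells, truth = h.simulate_screen(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = h.run_pipeline(cells, cfg.layouts()[0], cfg.catalog())

feats = res.ledger.final
ctl_med = res.scaled.loc[res.scaled.kind == "control", feats].median()
print("control-median fingerprint (scaled to [0,1]):")
print(ctl_med.round(2).to_string())

print("\nUMAP trajectory travel per compound (top-dose vs lowest-dose point):")
for cpd, grp in res.trajectories.groupby("compound"):
    grp = grp.sort_values("dose_rank")
    xyz = grp[["umap1", "umap2", "umap3"]].values
    travel = float(np.linalg.norm(xyz[-1] - xyz[0]))
    pct = grp["pct_of_control"].iloc[-1]
    print(f"  {cpd:<14} travel={travel:6.2f}   top-dose count={pct:5.1f}% of control")

out = Path(__file__).parent
fig = plots.radial_fingerprint(res.residuals, feats,
                               sample_ids=[f"{c}_{k:g}" for c, k in
                                           [("doseresp_1", 10), ("lowstress_1", 10)]],
                               offset=0.5, title="residual fingerprints (+0.5 offset)")
fig.savefig(out / "radial_fingerprints.png", dpi=120)
fig = plots.trajectory_plot(res.trajectories,
                            control_points=res.embedding[
                                (res.scaled["kind"] == "control").values])
fig.savefig(out / "dose_trajectories.png", dpi=120)
print("\nwrote radial_fingerprints.png and dose_trajectories.png")
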
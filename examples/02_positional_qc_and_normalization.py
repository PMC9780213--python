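"""Detect and remove plate positional effects, then standardize to BZ scores.

Row/column artifacts are planted mostly on intensity features; the two-way
ANOVA on control-well medians finds them, median polish removes them, and the
per-cell BZ standardization leaves every plate's pooled control cells at
median 0 / MAD 1.
"""

import numpy as np

import hcsprofile as h
from hcsprofile.simulate import default_config

cfg = default_config(seed=0)
cells, truth = h.simulate_screen(cfg)
layout = cfg.layouts()[0]

wells = h.summarize_wells(cells)
report = h.positional_report(wells, layout)          # -log(P) > 10 flags
summary = h.qc_summary(report, cfg.catalog())
print("flagged (plate, feature) pairs:", int(report['flag'].sum()), "of", len(report))
print("\nflagged share by feature class (intensity should dominate):")
print(summary.groupby("feature_class")["flagged_share"].mean().round(2).to_string())

adjusted, adjustments = h.adjust_wells(wells, report, layout)
post = h.positional_report(adjusted, layout)
print("\nmax -log(P) on previously flagged pairs after median polish:",
      round(post.merge(report.loc[report.flag, ['plate', 'replicate', 'feature']])
            [["neglogp_row", "neglogp_col"]].values.max(), 2), "(threshold 10)")

bz, params = h.standardize_cells(cells, adjustments)
ctl = bz[bz.treatment == h.CONTROL_ID]
feats = h.feature_columns(bz)
meds = ctl.groupby(["plate", "replicate"])[feats].median()
print("\nBZ contract: max |control median| over plates/features:",
      float(np.abs(meds.values).max()))
print("(every plate's pooled control cells sit at median 0, MAD 1 by construction)")
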
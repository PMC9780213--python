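"""Simulate a desk-scale screen and inspect its design.

Generates the default synthetic screen (14 features, 8 planted compounds,
two 384-well plate positions x 3 replicates) and prints the design
bookkeeping and raw cell-count structure.
"""

import hcsprofile as h
from hcsprofile.simulate import default_config, design_summary

cfg = default_config(seed=0)
cells, truth = h.simulate_screen(cfg)

d = design_summary(cfg)
print("analyzable inner wells per plate :", d["inner_wells_per_plate"])
print("control wells per plate          :", d["control_wells_per_plate"])
print("control samples (wells x plates x reps):", d["n_control_samples"])
print("treatment conditions (compound x dose) :", d["n_treatment_conditions"])
print("cells simulated                  :", len(cells))

wells = h.summarize_wells(cells)
ctl = wells[wells.treatment == h.CONTROL_ID]
print(f"control cells/well: min={ctl.cell_count.min()} "
      f"median={int(ctl.cell_count.median())} max={ctl.cell_count.max()}")

# The two planted cytotoxic compounds lose most cells at their top doses;
# expected surviving fractions come straight from the ground truth record.
toxic = truth.count_fractions.query("fraction < 0.30")
print("planted toxic conditions (>70% cell loss):")
print(toxic.to_string(index=False))
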
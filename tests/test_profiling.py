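"""Global control, replicate merging, EMD profiles, counts and toxicity."""

import numpy as np
import pandas as pd
import pytest

import hcsprofile as h
from hcsprofile.data_model import CONTROL_ID
from hcsprofile.profiling import (build_global_control, cell_count_summary,
                                  dna_content_distributions, emd_profile,
                                  flag_toxic, merge_replicates)
from conftest import toy_cells


class TestGlobalControl:
    def test_pooled_count_and_order_invariance(self):
        recs = [("p", 1, 2, 2, CONTROL_ID, np.nan, float(i), 0.5) for i in range(3)]
        recs += [("p", 1, 4, 4, CONTROL_ID, np.nan, float(i), 0.5) for i in range(3)]
        cells = toy_cells(recs)
        gc = build_global_control(cells)
        assert len(gc["f1"]) == 6
        gc_rev = build_global_control(cells.iloc[::-1].reset_index(drop=True))
        np.testing.assert_array_equal(gc["f1"], gc_rev["f1"])

    def test_pooled_bz_controls_are_standard(self, default_run):
        _, _, _, res = default_run
        gc = build_global_control(res.bz_cells)
        for f, vals in gc.items():
            assert abs(np.median(vals)) < 0.05
            assert abs(np.median(np.abs(vals - np.median(vals))) - 1) < 0.05

    def test_no_controls_rejected(self):
        cells = toy_cells([("p", 1, 2, 2, "cpd", 1.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="control"):
            build_global_control(cells)


class TestMergeReplicates:
    def test_published_example_sizes(self):
        """Replicates of 348, 386 and 366 cells merge to a 1100-cell sample."""
        rng = np.random.default_rng(0)
        recs = []
        for rep, n in zip((1, 2, 3), (348, 386, 366)):
            recs += [("p", rep, 3, 3, "vincristine", 20.0, rng.normal(), 0.0)
                     for _ in range(n)]
        merged = merge_replicates(toy_cells(recs), "vincristine", 20.0)
        assert len(merged["f1"]) == 1100

    def test_single_replicate_is_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=40)
        recs = [("p", 1, 3, 3, "cpd", 1.0, v, 0.0) for v in vals]
        merged = merge_replicates(toy_cells(recs), "cpd", 1.0)
        np.testing.assert_array_equal(np.sort(merged["f1"]), np.sort(vals))

    def test_unknown_condition_rejected(self):
        cells = toy_cells([("p", 1, 2, 2, CONTROL_ID, np.nan, 0.0, 0.0)])
        with pytest.raises(ValueError, match="no cells"):
            merge_replicates(cells, "ghost", 1.0)


class TestEMDProfile:
    def test_profile_shape_and_metadata(self, default_run):
        cfg, _, _, res = default_run
        from hcsprofile.simulate import design_summary
        d = design_summary(cfg)
        prof = res.profile
        assert (prof.kind == "control").sum() == d["n_control_samples"]
        assert (prof.kind == "treatment").sum() == d["n_treatment_conditions"]
        feats = h.feature_columns(res.bz_cells)
        assert (prof[feats].values >= 0).all()

    def test_control_rows_concentrate_near_zero(self, default_run):
        """Reproducible features: control wells sit at the EMD sampling floor.
        (The feature with planted well-level jitter is excluded — its large
        control EMDs are exactly what the reproducibility fence flags.)"""
        cfg, _, _, res = default_run
        jittered = {f.name for f in cfg.features if f.well_jitter > 0}
        feats = [f for f in h.feature_columns(res.bz_cells) if f not in jittered]
        ctl = res.profile.loc[res.profile.kind == "control", feats]
        assert ctl.values.max() < 0.8
        assert np.median(ctl.values) < 0.25

    def test_planted_shift_recovered_as_profile_entry(self, default_run):
        """A pure location shift of d (BZ units) must appear as an EMD entry
        of ~d (translation property of W1)."""
        cfg, _, truth, res = default_run
        ce = truth.condition_effects
        ce = ce[ce.pure_shift & (ce.expected_bz_shift > 1.0)]
        prof = (res.profile[res.profile.kind == "treatment"]
                .set_index(["compound", "concentration"]))
        for r in ce.itertuples():
            got = prof.loc[(r.compound, r.concentration), r.feature]
            assert got == pytest.approx(r.expected_bz_shift, rel=0.15)

    def test_internal_consistency_with_metrics_module(self, default_run):
        _, _, _, res = default_run
        gc = build_global_control(res.bz_cells)
        row = res.profile[res.profile.kind == "treatment"].iloc[0]
        merged = merge_replicates(res.bz_cells, row["compound"], row["concentration"])
        f = h.feature_columns(res.bz_cells)[0]
        assert row[f] == pytest.approx(h.emd(merged[f], gc[f]), abs=1e-12)


class TestCounts:
    def _cells(self, ctl_n, trt_n):
        recs = []
        for col, n in zip((2, 4, 6), ctl_n):
            recs += [("p", 1, 2, col, CONTROL_ID, np.nan, 0.0, 0.0)] * n
        for col, n in zip((3, 5, 7), trt_n):
            recs += [("p", 1, 3, col, "cpd", 1.0, 0.0, 0.0)] * n
        return toy_cells(recs)

    def test_treatment_at_control_mean_is_100pct(self):
        wc, cond = cell_count_summary(self._cells((100, 200, 300), (200, 200, 200)))
        assert cond["pct_of_control"].iloc[0] == pytest.approx(100.0)
        row = wc.iloc[0]
        assert (row["control_min"], row["control_median"], row["control_max"]) \
            == (100, 200, 300)

    def test_toxicity_threshold_sides(self):
        cond = pd.DataFrame([
            {"compound": "a", "concentration": 1.0, "pct_of_control": 29.0},
            {"compound": "b", "concentration": 1.0, "pct_of_control": 31.0},
        ])
        assert flag_toxic(cond) == {("a", 1.0)}

    def test_planted_toxicity_recovered(self, default_run):
        _, _, truth, res = default_run
        merged = res.condition_counts.merge(
            truth.count_fractions, left_on=["compound", "concentration"],
            right_on=["compound", "concentration"])
        err = (merged["pct_of_control"] / 100.0 - merged["fraction"]).abs()
        assert err.max() < 0.08


class TestDnaContent:
    DNA = "DNA_TotalIntensity_Circ"

    def test_bimodal_control_shows_two_density_maxima(self, default_run):
        """On standardized (positionally corrected) cells the 2n/4n DNA-content
        modes are both visible in the control density."""
        _, _, _, res = default_run
        dist = dna_content_distributions(res.bz_cells, self.DNA, bins=48)
        ctl = dist[dist.condition == "control"].sort_values("bin_center")
        d = ctl["density"].values
        interior_peaks = [i for i in range(1, len(d) - 1)
                          if d[i] > d[i - 1] and d[i] > d[i + 1] and d[i] > 0.2 * d.max()]
        assert len(interior_peaks) >= 2

    def test_g1_mass_moves_with_dose(self, default_run):
        """doseresp_3 shifts G1 weight down with dose: the standardized mass
        below the inter-mode midpoint decreases from the lowest to the
        highest dose and ends below the control level."""
        _, _, truth, res = default_run
        bz = res.bz_cells
        mid = (1.5 - truth.latent_median[self.DNA]) / truth.latent_mad[self.DNA]
        sub = bz[bz.treatment == "doseresp_3"]
        frac = (sub.assign(g1=sub[self.DNA] < mid)
                .groupby("concentration")["g1"].mean().sort_index())
        assert frac.iloc[-1] < frac.iloc[0] - 0.15
        ctl_frac = (bz.loc[bz.treatment == CONTROL_ID, self.DNA] < mid).mean()
        assert frac.iloc[-1] < ctl_frac

    def test_missing_feature_rejected(self, default_screen):
        _, cells, _ = default_screen
        with pytest.raises(KeyError, match="ghost"):
            dna_content_distributions(cells, "ghost")
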
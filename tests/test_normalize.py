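"""Median polish, B scores and the two-level BZ standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import hcsprofile as h
from hcsprofile.data_model import CONTROL_ID, build_default_layout
from hcsprofile.normalize import b_score, median_polish
from conftest import toy_cells

# 6x8 matrix and its decomposition frozen from an independent run of
# R stats::medpolish (eps=1e-12, maxiter=500) on the same values.
R_MATRIX = np.array([
    [0.304717, -1.039984, 0.750451, 0.940565, -1.951035, -1.30218, 0.12784, -0.316243],
    [-0.016801, -0.853044, 0.879398, 0.777792, 0.066031, 1.127241, 0.467509, -0.859292],
    [0.368751, -0.958883, 0.87845, -0.049926, -0.184862, -0.68093, 1.222541, -0.154529],
    [-0.428328, -0.352134, 0.532309, 0.365444, 0.412733, 0.430821, 2.141648, -0.406415],
    [-0.512243, -0.813773, 0.615979, 1.128972, -0.113947, -0.840156, -0.824481, 0.650593],
    [0.743254, 0.543154, -0.66551, 0.232161, 0.116686, 0.218689, 0.871429, 0.223596],
])
R_OVERALL = 0.03375696874999997
R_ROW = np.array([-0.2334081875, 0.074375875, -0.074375875,
                  0.1844863125, -0.0916361875, 0.385879375])
R_COL = np.array([0.09934190625, -0.79811328125, 0.7225616875, 0.4084299375,
                  -0.1001554375, -0.42062921875, 0.40558440625, -0.1563160625])


class TestMedianPolish:
    def test_exact_additive_input_recovered(self):
        r = np.array([-1.0, 0.0, 2.0, -2.0, 1.0])   # median 0
        c = np.array([1.0, -1.0, 0.0, 2.0, -2.0, 0.0])  # median 0
        m = 10.0 + r[:, None] + c[None, :]
        pol = median_polish(m)
        assert pol.overall == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_allclose(pol.row_effects, r, atol=1e-9)
        np.testing.assert_allclose(pol.col_effects, c, atol=1e-9)
        np.testing.assert_allclose(pol.residuals, 0, atol=1e-9)

    def test_constant_matrix(self):
        pol = median_polish(np.full((4, 5), 7.0))
        assert pol.overall == 7.0
        np.testing.assert_allclose(pol.row_effects, 0)
        np.testing.assert_allclose(pol.col_effects, 0)
        np.testing.assert_allclose(pol.residuals, 0)

    def test_agrees_with_R_medpolish_reference(self):
        pol = median_polish(R_MATRIX, tol=1e-12, max_iter=500)
        assert pol.overall == pytest.approx(R_OVERALL, abs=1e-9)
        np.testing.assert_allclose(pol.row_effects, R_ROW, atol=1e-9)
        np.testing.assert_allclose(pol.col_effects, R_COL, atol=1e-9)

    @given(arrays(float, (5, 7), elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_reconstruction_is_exact(self, m):
        pol = median_polish(m)
        np.testing.assert_allclose(pol.reconstruct(), m, atol=1e-9)

    def test_idempotent_on_own_residuals(self):
        rng = np.random.default_rng(0)
        pol = median_polish(rng.normal(5, 2, (6, 9)), tol=1e-10)
        again = median_polish(pol.residuals, tol=1e-10)
        np.testing.assert_allclose(again.row_effects, 0, atol=1e-7)
        np.testing.assert_allclose(again.col_effects, 0, atol=1e-7)

    def test_handles_missing_cells(self):
        m = 3.0 + np.zeros((4, 4))
        m[1, 2] = np.nan
        pol = median_polish(m)
        assert pol.overall == pytest.approx(3.0)
        assert np.isnan(pol.residuals[1, 2])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.zeros((1, 5)))
        m = np.zeros((3, 3))
        m[:, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            median_polish(m)


class TestBScore:
    def test_hand_computed(self):
        res = np.array([[-1.0, 0.0], [1.0, 2.0]])
        # median 0.5, |dev| = {1.5, .5, .5, 1.5}, MAD = 1
        np.testing.assert_allclose(b_score(res), res / 1.0)
        np.testing.assert_allclose(b_score(np.array([-1.0, 0.0, 1.0])),
                                   [-1.0, 0.0, 1.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        res = rng.normal(0, 2, (4, 4))
        np.testing.assert_allclose(b_score(res), b_score(5 * res), atol=1e-12)

    def test_zero_mad_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            b_score(np.ones((3, 3)))


def _gradient_plate(layout, noise=0.0, seed=0):
    """Well medians with a pure additive row gradient on feature f1."""
    rng = np.random.default_rng(seed)
    rows = list(layout.inner_row_range())
    grad = {r: 2.0 * (r - np.median(rows)) for r in rows}
    recs = []
    for (r, c) in layout.inner_wells():
        role = layout.well_role(r, c)
        trt = CONTROL_ID if role == "control" else "cpd"
        conc = np.nan if role == "control" else 1.0
        recs.append(("p", 1, r, c, trt, conc,
                     5.0 + grad[r] + noise * rng.normal(),
                     1.0 + noise * rng.normal()))
    return toy_cells(recs)


class TestAdjustWells:
    def test_unflagged_features_pass_through(self):
        layout = build_default_layout(compounds=["cpd"])
        wells = h.summarize_wells(_gradient_plate(layout))
        report = pd.DataFrame([{"plate": "p", "replicate": 1, "feature": "f1",
                                "flag": False}])
        adjusted, adjustments = h.adjust_wells(wells, report, layout)
        pd.testing.assert_frame_equal(adjusted, wells)
        assert len(adjustments) == 0

    def test_flagged_gradient_removed_and_anova_clears(self):
        layout = build_default_layout(compounds=["cpd"])
        wells = h.summarize_wells(_gradient_plate(layout, noise=0.05))
        report = h.positional_report(wells, layout)
        row = report[report.feature == "f1"].iloc[0]
        assert row["flag_row"] and not report[report.feature == "f2"].iloc[0]["flag"]
        adjusted, adjustments = h.adjust_wells(wells, report, layout)
        # the stored adjustment is exactly the difference adjusted - raw
        merged = adjustments.merge(wells, on=["plate", "replicate", "row", "col"])
        merged = merged.merge(adjusted, on=["plate", "replicate", "row", "col"],
                              suffixes=("_raw", "_adj"))
        np.testing.assert_allclose(merged["f1_adj"] - merged["f1_raw"],
                                   merged["adjustment"], atol=1e-12)
        # re-running detection on adjusted medians falls below threshold
        report2 = h.positional_report(adjusted, layout)
        assert not report2[report2.feature == "f1"].iloc[0]["flag"]
        ctl = adjusted[adjusted.treatment == CONTROL_ID]
        assert ctl["f1"].std() < 0.2   # gradient (sd ~8) flattened to noise


class TestStandardizeCells:
    def _bz(self, cells):
        empty = pd.DataFrame(columns=["plate", "replicate", "row", "col",
                                      "feature", "adjustment"])
        return h.standardize_cells(cells, empty)

    def test_control_median_zero_mad_one_exactly(self):
        rng = np.random.default_rng(2)
        recs = [("p", 1, 2 + i % 5, 2 + i // 5, CONTROL_ID, np.nan,
                 rng.normal(3, 2), rng.lognormal()) for i in range(200)]
        recs += [("p", 1, 10, 10, "cpd", 1.0, rng.normal(9, 2), 1.0)
                 for _ in range(50)]
        bz, params = self._bz(toy_cells(recs))
        ctl = bz[bz.treatment == CONTROL_ID]
        for f in ("f1", "f2"):
            assert np.median(ctl[f]) == pytest.approx(0.0, abs=1e-12)
            assert np.median(np.abs(ctl[f])) == pytest.approx(1.0, abs=1e-12)

    def test_linearity_of_bz(self):
        ctl_vals = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])  # med 0, MAD 1
        recs = [("p", 1, 2, 2, CONTROL_ID, np.nan, v, 0.0) for v in ctl_vals]
        recs.append(("p", 1, 3, 3, "cpd", 1.0, 2.0, 0.0))  # med + 2*MAD
        with pytest.warns(UserWarning, match="zero control MAD"):
            bz, _ = self._bz(toy_cells(recs))
        assert "f2" not in bz.columns  # constant feature dropped
        assert bz.loc[bz.treatment == "cpd", "f1"].iloc[0] == pytest.approx(2.0)

    def test_treatment_like_controls_is_standard(self):
        rng = np.random.default_rng(3)
        recs = [("p", 1, 2, 2 + i % 8, CONTROL_ID, np.nan, rng.normal(), 1.0 * i)
                for i in range(300)]
        recs += [("p", 1, 9, 9, "cpd", 1.0, rng.normal(), 1.0) for _ in range(300)]
        bz, _ = self._bz(toy_cells(recs))
        trt = bz.loc[bz.treatment == "cpd", "f1"]
        assert abs(np.median(trt)) < 0.2
        assert abs(np.median(np.abs(trt - np.median(trt))) - 1) < 0.2


class TestSimulationClosedLoop:
    """Parameter recovery and the Eq-style contract on the simulated screen."""

    def test_pooled_controls_standard_on_every_plate(self, default_run):
        _, _, _, res = default_run
        feats = h.feature_columns(res.bz_cells)
        ctl = res.bz_cells[res.bz_cells.treatment == CONTROL_ID]
        for _, sub in ctl.groupby(["plate", "replicate"]):
            med = sub[feats].median()
            madv = (sub[feats] - med).abs().median()
            np.testing.assert_allclose(med, 0, atol=1e-9)
            np.testing.assert_allclose(madv, 1, atol=1e-9)

    def test_polish_recovers_injected_effects(self, default_run):
        cfg, cells, truth, res = default_run
        layout = cfg.layouts()[0]
        from hcsprofile.normalize import _well_matrix
        flagged = res.qc_report[res.qc_report["flag"]]
        assert len(flagged) > 0
        ratios = []
        for r in flagged.itertuples():
            sub = res.wells[(res.wells.plate == r.plate)
                            & (res.wells.replicate == r.replicate)
                            & (res.wells.treatment == CONTROL_ID)]
            mat, _, _ = _well_matrix(sub, layout, r.feature)
            pol = median_polish(mat)
            key = (r.plate, r.replicate, r.feature)
            est = np.concatenate([
                pol.row_effects - np.median(pol.row_effects),
                pol.col_effects - np.median(pol.col_effects)])
            true = np.concatenate([
                truth.row_effects[key] - np.median(truth.row_effects[key]),
                truth.col_effects[key] - np.median(truth.col_effects[key])])
            sigma = truth.latent_mad[r.feature] / 0.67448975
            ratios.append(np.sqrt(np.mean((est - true) ** 2)) / sigma)
        assert max(ratios) < 0.5

    def test_cross_plate_control_harmonization(self, default_run):
        """After BZ standardization, same-feature control distributions agree
        across plates (EMD < 0.1) despite injected plate effects."""
        _, _, _, res = default_run
        ctl = res.bz_cells[res.bz_cells.treatment == CONTROL_ID]
        groups = [sub for _, sub in ctl.groupby(["plate", "replicate"])]
        for f in h.feature_columns(res.bz_cells)[:6]:
            vals = [g[f].values for g in groups]
            for i in range(len(vals)):
                for j in range(i + 1, len(vals)):
                    assert h.emd(vals[i], vals[j]) < 0.1
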
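"""Fingerprint scaling, residuals, clustering, embedding and trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from hcsprofile.fingerprints import (embed_umap, extract_trajectories,
                                     hcluster, linkage_to_newick,
                                     residual_fingerprints, scale_profile)


def profile_frame(matrix, kinds, compounds=None, concentrations=None):
    matrix = np.asarray(matrix, float)
    n, p = matrix.shape
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "kind": kinds,
        "compound": compounds or ["DMSO" if k == "control" else f"cpd{i}"
                                  for i, k in enumerate(kinds)],
        "concentration": concentrations or [np.nan] * n,
    })
    for j in range(p):
        df[f"f{j}"] = matrix[:, j]
    return df


class TestScaleProfile:
    def test_two_point_column(self):
        prof = profile_frame([[0.0], [np.e - 1]], ["control", "treatment"])
        scaled = scale_profile(prof)
        np.testing.assert_allclose(scaled["f0"], [0.0, 1.0])

    def test_order_preserved_and_range_attained(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 5, 20)
        prof = profile_frame(col[:, None], ["treatment"] * 20)
        scaled = scale_profile(prof)["f0"].values
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        np.testing.assert_array_equal(np.argsort(scaled), np.argsort(col))

    def test_constant_column_warns_and_zeroes(self):
        prof = profile_frame([[2.0], [2.0]], ["control", "treatment"])
        with pytest.warns(UserWarning, match="constant"):
            scaled = scale_profile(prof)
        assert (scaled["f0"] == 0.0).all()


class TestResiduals:
    def test_control_median_row_maps_to_zero(self):
        prof = profile_frame([[0.1, 0.3], [0.2, 0.4], [0.3, 0.5], [0.9, 0.9]],
                             ["control"] * 3 + ["treatment"])
        res = residual_fingerprints(prof)
        ctl = res[res.kind == "control"]
        np.testing.assert_allclose(ctl[["f0", "f1"]].median(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.iloc[1][["f0", "f1"]].astype(float), 0.0,
                                   atol=1e-12)

    def test_planted_single_feature_treatment_peaks_there(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.3, size=(6, 5))
        base[5, 2] = 0.95  # treatment hits feature f2 only
        prof = profile_frame(base, ["control"] * 5 + ["treatment"])
        res = residual_fingerprints(prof)
        trt = res[res.kind == "treatment"].iloc[0]
        feats = [f"f{j}" for j in range(5)]
        assert max(feats, key=lambda f: trt[f]) == "f2"

    def test_requires_control_rows(self):
        prof = profile_frame([[0.1]], ["treatment"])
        with pytest.raises(ValueError, match="control"):
            residual_fingerprints(prof)


class TestHCluster:
    def test_identical_rows_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z, labels = hcluster(X, k=2)
        assert Z[0, 2] == 0.0
        assert labels[0] == labels[1] != labels[2]

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (8, 3))])
        _, labels = hcluster(X, k=2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_upgma_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        Z, _ = hcluster(rng.normal(size=(15, 4)), k=3)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_undefined_entries_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            hcluster(np.array([[1.0, np.nan], [0.0, 1.0]]), k=2)

    def test_newick_export_round_trips_leaves(self):
        rng = np.random.default_rng(4)
        names = [f"leaf{i}" for i in range(6)]
        Z, _ = hcluster(rng.normal(size=(6, 3)), k=2)
        nwk = linkage_to_newick(Z, names)
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(names)


class TestUMAP:
    def _grouped_data(self, seed=5):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0, 0, 0], [6, 0, 0, 0], [0, 6, 0, 0]])
        X = np.vstack([c + rng.normal(0, 0.3, (20, 4)) for c in centers])
        labels = np.repeat([0, 1, 2], 20)
        return X, labels

    def test_deterministic_given_seed(self):
        X, _ = self._grouped_data()
        a = embed_umap(X, n_dims=2, seed=42)
        b = embed_umap(X, n_dims=2, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_planted_groups_separate(self):
        from sklearn.metrics import silhouette_score
        X, labels = self._grouped_data()
        emb = embed_umap(X, n_dims=2, seed=7)
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            embed_umap(np.zeros((3, 2)), n_dims=3, seed=0)


class TestTrajectories:
    def _embedding(self):
        concs = [10 / 2 ** i for i in range(7)]
        meta = pd.DataFrame({
            "kind": ["treatment"] * 7 + ["control"],
            "compound": ["cpd"] * 7 + ["DMSO"],
            "concentration": concs[::-1] + [np.nan],  # shuffled (ascending input)
        })
        emb = np.arange(8 * 3, dtype=float).reshape(8, 3)
        return emb, meta

    def test_seven_point_path_in_dose_order(self):
        emb, meta = self._embedding()
        traj = extract_trajectories(emb, meta)
        assert len(traj) == 7
        assert traj["concentration"].is_monotonic_increasing
        assert list(traj["dose_rank"]) == list(range(1, 8))

    def test_order_independent_of_row_order(self):
        emb, meta = self._embedding()
        perm = np.random.default_rng(6).permutation(len(meta))
        t1 = extract_trajectories(emb, meta)
        t2 = extract_trajectories(emb[perm], meta.iloc[perm])
        pd.testing.assert_frame_equal(
            t1.reset_index(drop=True),
            t2.reset_index(drop=True))

    def test_single_dose_warns(self):
        meta = pd.DataFrame({"kind": ["treatment"], "compound": ["solo"],
                             "concentration": [1.0]})
        with pytest.warns(UserWarning, match="single-dose"):
            traj = extract_trajectories(np.zeros((1, 3)), meta)
        assert len(traj) == 1

    def test_dose_response_visible_in_screen_trajectories(self, default_run):
        """The planted dose-responsive compound travels along the dose
        gradient (its lowest- and highest-dose points are far apart, and its
        fingerprint departs monotonically from the control band); the
        dose-insensitive compound's trajectory barely moves."""
        _, _, _, res = default_run
        traj = res.trajectories

        def path(cpd):
            sub = traj[traj.compound == cpd].sort_values("dose_rank")
            return sub[["umap1", "umap2", "umap3"]].values

        def travel(xyz):
            return np.linalg.norm(xyz[-1] - xyz[0])

        assert travel(path("doseresp_1")) > 3 * travel(path("doseinsens_1"))

        # fingerprint-space dose response: distance from the control-median
        # fingerprint increases with dose for the responsive compound
        feats = res.ledger.final
        ctl_med = res.scaled.loc[res.scaled["kind"] == "control", feats].median()
        sub = (res.scaled[res.scaled["compound"] == "doseresp_1"]
               .sort_values("concentration"))
        dists = np.linalg.norm(sub[feats].values - ctl_med.values, axis=1)
        from scipy.stats import spearmanr
        assert spearmanr(np.arange(len(dists)), dists).statistic > 0.7
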
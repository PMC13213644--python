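"""Differential screen: filters, ANOVA + fold-change rule, PCA/PLS-DA
diagnostics and hierarchical clustering on planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from hsichem import (
    FeatureTable,
    anova_fc_screen,
    filter_features,
    hca_heatmap,
    pca_scores,
    plsda_fit,
    simulate_feature_table,
)


def _table(values, groups, features=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = [f"S{i}" for i in range(values.shape[1])]
    idx = features or [f"F{i}" for i in range(values.shape[0])]
    return FeatureTable(
        intensities=pd.DataFrame(values, index=idx, columns=cols),
        groups=pd.Series(groups, index=cols),
    )


class TestFilter:
    def test_high_everywhere_kept(self):
        t = _table([[6000.0] * 6], ["tuberous"] * 2 + ["taproot"] * 2 + ["old"] * 2)
        assert len(filter_features(t).intensities) == 1

    def test_seventy_percent_occurrence_dropped(self):
        # present in 7 of 10 samples of every group: below the 80 % rule
        block = np.array([[6000.0] * 7 + [0.0] * 3] * 3).reshape(1, 30)
        groups = ["tuberous"] * 10 + ["taproot"] * 10 + ["old"] * 10
        with pytest.raises(ValueError, match="no feature"):
            filter_features(_table(block, groups))

    def test_one_qualifying_group_suffices(self):
        row = [6000.0] * 10 + [10.0] * 10 + [10.0] * 10
        groups = ["tuberous"] * 10 + ["taproot"] * 10 + ["old"] * 10
        assert len(filter_features(_table([row], groups)).intensities) == 1

    def test_matches_brute_force_on_planted_table(self, feature_table):
        kept = filter_features(feature_table, 5000.0, 0.8)
        X = feature_table.intensities
        expected = []
        for fid in X.index:
            ok = False
            for g in ("tuberous", "taproot", "old"):
                cols = feature_table.groups[feature_table.groups == g].index
                hits = sum(X.loc[fid, c] >= 5000.0 for c in cols)
                if hits / len(cols) >= 0.8:
                    ok = True
            expected.append(ok)
        assert list(kept.intensities.index) == list(X.index[expected])


class TestScreen:
    def test_planted_fc4_recovery(self, feature_table):
        filtered = filter_features(feature_table)
        diff = anova_fc_screen(filtered)
        hits = set(diff.feature_ids)
        planted = set(filtered.planted)
        recovered = len(hits & planted) / len(planted)
        assert recovered >= 0.9
        for fid in diff.feature_ids:
            assert diff.table.loc[fid, "fc"] > 2.0
            assert diff.table.loc[fid, "p"] < 0.05

    def test_fc_exactly_two_excluded(self):
        # group means exactly 2:1:1, within-group spread tiny -> p ~ 0, FC == 2.0
        rows = np.array([
            [2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            [8.0, 8.0, 8.0, 8.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        ])
        groups = ["tuberous"] * 4 + ["taproot"] * 4 + ["old"] * 4
        t = _table(rows, groups)
        diff = anova_fc_screen(t, normalize=False)
        assert "F0" not in diff.feature_ids      # FC exactly 2.0: strict rule
        assert "F1" in diff.feature_ids

    def test_identical_group_means_excluded(self, rng):
        base = rng.lognormal(10, 0.2, size=12)
        groups = ["tuberous"] * 4 + ["taproot"] * 4 + ["old"] * 4
        t = _table([base], groups)
        diff = anova_fc_screen(t, normalize=False)
        assert len(diff) == 0

    def test_zero_group_mean_reported_undefined(self):
        rows = [[0.0, 0.0, 0.0, 0.0, 5.0, 6.0, 5.5, 5.2, 7.0, 7.5, 7.2, 7.1]]
        groups = ["tuberous"] * 4 + ["taproot"] * 4 + ["old"] * 4
        diff = anova_fc_screen(_table(rows, groups), normalize=False)
        assert diff.undefined == ["F0"]

    def test_sample_order_invariance(self, feature_table):
        filtered = filter_features(feature_table)
        rng = np.random.default_rng(1)
        perm = rng.permutation(filtered.intensities.shape[1])
        shuffled = FeatureTable(
            intensities=filtered.intensities.iloc[:, perm],
            groups=filtered.groups.iloc[perm],
        )
        a = anova_fc_screen(filtered)
        b = anova_fc_screen(shuffled)
        assert set(a.feature_ids) == set(b.feature_ids)

    def test_uniform_rescaling_invariance(self, feature_table):
        filtered = filter_features(feature_table)
        scaled = FeatureTable(
            intensities=filtered.intensities * 3.25, groups=filtered.groups
        )
        a = anova_fc_screen(filtered)
        b = anova_fc_screen(scaled)
        assert set(a.feature_ids) == set(b.feature_ids)

    def test_hit_count_stable_across_seeds(self):
        # planted count 40; detected totals should stay within +-10 %
        counts = []
        for seed in range(20):
            t = simulate_feature_table(seed=seed, n_features=300,
                                       n_differential=40)
            counts.append(len(anova_fc_screen(filter_features(t))))
        assert all(36 <= c <= 44 for c in counts)


class TestPCA:
    def test_rank_one_data(self):
        u = np.linspace(1, 2, 8)
        v = np.arange(1, 13, dtype=float)
        t = _table(np.outer(u, v) * 1000,
                   ["tuberous"] * 4 + ["taproot"] * 4 + ["old"] * 4)
        _, ev = pca_scores(t, n_components=3)
        assert ev[0] > 0.999

    def test_explained_variance_monotone(self, feature_table):
        _, ev = pca_scores(feature_table, n_components=5)
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-9

    def test_qc_samples_cluster_tightly(self, feature_table):
        scores, _ = pca_scores(feature_table, n_components=2)
        qc = scores[feature_table.groups == "QC"].to_numpy()
        groups = feature_table.groups
        centroids = {
            g: scores[groups == g].to_numpy().mean(axis=0)
            for g in ("tuberous", "taproot", "old")
        }
        qc_spread = np.linalg.norm(qc - qc.mean(axis=0), axis=1).mean()
        between = np.mean([
            np.linalg.norm(centroids[a] - centroids[b])
            for a, b in (("tuberous", "taproot"), ("tuberous", "old"),
                         ("taproot", "old"))
        ])
        assert qc_spread < between


class TestPLSDA:
    def test_separated_groups_high_q2(self, feature_table):
        res = plsda_fit(filter_features(feature_table), seed=0)
        assert res.q2 > 0.5
        assert 0.0 <= res.r2x <= 1.0
        assert 0.0 <= res.r2y <= 1.0

    def test_shuffled_labels_low_q2(self, feature_table):
        filtered = filter_features(feature_table)
        work = filtered.without_qc()
        rng = np.random.default_rng(3)
        q2s = []
        for _ in range(3):
            labels = rng.permutation(work.groups.to_numpy())
            q2s.append(plsda_fit(filtered, labels=labels, seed=0).q2)
        assert np.mean(q2s) <= 0.1

    def test_r2y_nondecreasing_in_components(self, feature_table):
        filtered = filter_features(feature_table)
        r2y = [plsda_fit(filtered, n_components=a, seed=0).r2y
               for a in (1, 2, 3)]
        assert r2y[0] <= r2y[1] + 1e-9 <= r2y[2] + 2e-9


class TestHCA:
    def test_two_planted_clusters_recovered(self, rng):
        # two feature blocks with opposite sample patterns
        n = 12
        pattern = np.concatenate([np.ones(6), np.zeros(6)])
        block1 = 1000 * (1 + pattern) + rng.normal(0, 5, (10, n))
        block2 = 1000 * (2 - pattern) + rng.normal(0, 5, (10, n))
        t = _table(np.vstack([block1, block2]),
                   ["tuberous"] * 4 + ["taproot"] * 4 + ["old"] * 4)
        res = hca_heatmap(t)
        assign = fcluster(res.feature_linkage, 2, criterion="maxclust")
        assert len(set(assign[:10])) == 1
        assert len(set(assign[10:])) == 1
        assert assign[0] != assign[10]

    def test_leaf_count_and_determinism(self, feature_table):
        filtered = filter_features(feature_table)
        a = hca_heatmap(filtered)
        b = hca_heatmap(filtered)
        assert len(a.feature_order) == len(filtered.intensities)
        np.testing.assert_array_equal(a.feature_order, b.feature_order)

    def test_nonfinite_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            hca_heatmap(mat)

    def test_heatmap_file_written(self, tmp_path, feature_table):
        filtered = filter_features(feature_table)
        res = hca_heatmap(filtered, out_png=tmp_path / "heat.png")
        assert (tmp_path / "heat.png").exists()
        assert res.figure_path is not None
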
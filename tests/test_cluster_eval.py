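"""Six validity metrics vs independent oracles, K-Means, Borda, t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from spikeae.cluster_eval import (
    adjusted_mutual_information,
    adjusted_rand_index,
    borda_aggregate,
    calinski_harabasz,
    davies_bouldin,
    kmeans_labels,
    metric_report,
    paired_tests,
    rand_index,
    silhouette,
    v_measure,
)


def _random_label_pairs(rng, n_pairs, n_max=50, k_max=5):
    for _ in range(n_pairs):
        n = int(rng.integers(4, n_max + 1))
        t = rng.integers(0, rng.integers(2, k_max + 1), n)
        p = rng.integers(0, rng.integers(2, k_max + 1), n)
        yield t, p


class TestWorkedExamples:
    """Hand-computable instances with frozen expected values."""

    def test_rand_index_three_point_example(self):
        # pairs: (1,2) split in both = agreement; (1,3),(2,3) mixed -> 1/3
        assert rand_index(["a", "a", "b"], ["x", "y", "y"]) == pytest.approx(1 / 3)

    def test_ari_three_point_example(self):
        # contingency arithmetic: index 0, expected 1/3, max 1 -> -0.5
        assert adjusted_rand_index(["a", "a", "b"], ["x", "y", "y"]) == pytest.approx(
            -0.5
        )

    def test_identical_labelings_score_one(self):
        t = [0, 0, 1, 1, 2]
        assert rand_index(t, t) == 1.0
        assert adjusted_rand_index(t, [5, 5, 9, 9, 7]) == 1.0
        assert adjusted_mutual_information(t, t) == pytest.approx(1.0)
        assert v_measure(t, t) == (1.0, 1.0, 1.0)

    def test_single_cluster_prediction(self):
        t = [0, 0, 1, 1]
        p = [0, 0, 0, 0]
        assert adjusted_mutual_information(t, p) == pytest.approx(0.0, abs=1e-12)
        hom, com, _ = v_measure(t, p)
        assert hom == pytest.approx(0.0)
        assert com == pytest.approx(1.0)

    def test_davies_bouldin_two_cluster_1d(self):
        # s1 = s2 = 1, centroid distance 10 -> (1+1)/10 = 0.2
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert davies_bouldin(X, [0, 0, 1, 1]) == pytest.approx(0.2)

    def test_calinski_harabasz_two_cluster_1d(self):
        # tr(B) = 100, tr(W) = 4, factor (4-2)/(2-1) = 2 -> 50
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == pytest.approx(50.0)

    def test_silhouette_tight_far_clusters(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        assert silhouette(X, [0, 0, 1, 1]) == pytest.approx(0.990, abs=5e-4)

    def test_dbs_scale_invariant(self, rng):
        X = rng.normal(size=(30, 3))
        lab = rng.integers(0, 3, 30)
        assert davies_bouldin(X, lab) == pytest.approx(davies_bouldin(X * 7.3, lab))

    def test_chs_duplication_changes_only_size_factor(self, rng):
        X = rng.normal(size=(20, 2))
        lab = np.repeat([0, 1], 10)
        base = calinski_harabasz(X, lab)
        doubled = calinski_harabasz(np.vstack([X, X]), np.concatenate([lab, lab]))
        # tr ratios identical; only (n-k)/(k-1) changes: 18 -> 38
        assert doubled == pytest.approx(base * 38 / 18)


class TestOracleAgreement:
    """Independent implementations (sklearn + explicit loops) as oracles."""

    def test_external_metrics_match_sklearn_to_1e9(self, rng):
        for t, p in _random_label_pairs(rng, 100):
            assert adjusted_rand_index(t, p) == pytest.approx(
                skm.adjusted_rand_score(t, p), abs=1e-9
            )
            assert adjusted_mutual_information(t, p) == pytest.approx(
                skm.adjusted_mutual_info_score(t, p), abs=1e-9
            )
            assert v_measure(t, p)[2] == pytest.approx(
                skm.v_measure_score(t, p), abs=1e-9
            )

    def test_internal_metrics_match_direct_loops_to_1e9(self, rng):
        from oracles import chs_loop, dbs_loop, silhouette_loop

        for _ in range(50):
            n = int(rng.integers(6, 40))
            X = rng.normal(size=(n, 3))
            lab = rng.integers(0, 3, n)
            if len(np.unique(lab)) < 2:
                continue
            assert silhouette(X, lab) == pytest.approx(silhouette_loop(X, lab), abs=1e-9)
            assert davies_bouldin(X, lab) == pytest.approx(dbs_loop(X, lab), abs=1e-9)
            assert calinski_harabasz(X, lab) == pytest.approx(chs_loop(X, lab), rel=1e-9)

    def test_internal_metrics_agree_with_sklearn(self, rng):
        # independent library cross-check; sklearn computes distances with the
        # quadratic-expansion trick, so agreement is only ~1e-7
        for _ in range(30):
            n = int(rng.integers(6, 40))
            X = rng.normal(size=(n, 3))
            lab = rng.integers(0, 3, n)
            if len(np.unique(lab)) < 2:
                continue
            assert silhouette(X, lab) == pytest.approx(
                skm.silhouette_score(X, lab), abs=1e-7
            )
            assert davies_bouldin(X, lab) == pytest.approx(
                skm.davies_bouldin_score(X, lab), abs=1e-7
            )
            assert calinski_harabasz(X, lab) == pytest.approx(
                skm.calinski_harabasz_score(X, lab), rel=1e-7
            )

    def test_vmeasure_matches_explicit_entropy_sums(self, rng):
        for _ in range(20):
            t = rng.integers(0, 3, 20)
            p = rng.integers(0, 4, 20)

            def H(labels):
                _, c = np.unique(labels, return_counts=True)
                q = c / c.sum()
                return -(q * np.log(q)).sum()

            def H_cond(a, b):  # H(a|b)
                total = 0.0
                for vb in np.unique(b):
                    m = b == vb
                    _, c = np.unique(a[m], return_counts=True)
                    q = c / c.sum()
                    total += m.mean() * -(q * np.log(q)).sum()
                return total

            hom = 1.0 if H(t) == 0 else 1 - H_cond(t, p) / H(t)
            com = 1.0 if H(p) == 0 else 1 - H_cond(p, t) / H(p)
            got_h, got_c, got_v = v_measure(t, p)
            assert got_h == pytest.approx(hom, abs=1e-12)
            assert got_c == pytest.approx(com, abs=1e-12)

    def test_ari_near_zero_under_random_permutations(self, rng):
        labels = np.repeat([0, 1, 2, 3], 25)
        vals = [
            adjusted_rand_index(labels, rng.permutation(labels)) for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.02


class TestMetricProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_ranges_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        t = rng.integers(0, 4, n)
        p = rng.integers(0, 4, n)
        assert -1.0 - 1e-12 <= adjusted_rand_index(t, p) <= 1.0 + 1e-12
        assert 0.0 <= v_measure(t, p)[2] <= 1.0 + 1e-12
        X = rng.normal(size=(n, 2))
        lab = rng.integers(0, 3, n)
        if len(np.unique(lab)) >= 2:
            assert davies_bouldin(X, lab) >= 0.0
            assert calinski_harabasz(X, lab) >= 0.0
            assert -1.0 <= silhouette(X, lab) <= 1.0

    def test_label_permutation_invariance(self, rng):
        t = rng.integers(0, 3, 30)
        p = rng.integers(0, 3, 30)
        remap = {0: 7, 1: 5, 2: 9}
        p2 = np.array([remap[x] for x in p])
        assert adjusted_rand_index(t, p) == pytest.approx(adjusted_rand_index(t, p2))
        assert adjusted_mutual_information(t, p) == pytest.approx(
            adjusted_mutual_information(t, p2)
        )
        X = rng.normal(size=(30, 2))
        assert silhouette(X, p) == pytest.approx(silhouette(X, p2))

    def test_internal_metrics_rotation_invariant(self, rng):
        X = rng.normal(size=(40, 2))
        lab = rng.integers(0, 3, 40)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        XR = X @ R.T
        assert davies_bouldin(X, lab) == pytest.approx(davies_bouldin(XR, lab))
        assert calinski_harabasz(X, lab) == pytest.approx(calinski_harabasz(XR, lab))
        assert silhouette(X, lab) == pytest.approx(silhouette(XR, lab))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rand_index([0, 1], [0, 1, 2])

    def test_degenerate_internal_inputs_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            davies_bouldin(X, [0] * 5)
        with pytest.raises(ZeroDivisionError):
            calinski_harabasz(np.tile([[1.0, 2.0]], (6, 1)), [0, 0, 0, 1, 1, 1])


class TestKMeans:
    def test_k_equals_n_gives_zero_inertia(self, rng):
        X = rng.normal(size=(8, 2))
        res = kmeans_labels(X, k=8, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(res.labels)) == 8

    def test_separated_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 50.0])
        res = kmeans_labels(X, k=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_index(truth, res.labels) == 1.0

    def test_inertia_monotone_in_iterations(self, rng):
        # same seeded init, growing iteration cap: Lloyd never increases inertia
        from sklearn.cluster import KMeans
        import warnings

        X = rng.normal(size=(200, 2))
        inertias = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for it in (1, 2, 3, 5, 10):
                km = KMeans(n_clusters=4, init="k-means++", n_init=1,
                            max_iter=it, random_state=0).fit(X)
                inertias.append(km.inertia_)
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_labels(rng.normal(size=(3, 2)), k=4, seed=0)


class TestBorda:
    def _table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ari": [0.9, 0.5, 0.7],
                "dbs": [0.2, 0.9, 0.5],
            },
            index=["A", "B", "C"],
        )

    def test_toy_table_matches_manual_tally(self):
        # ari ranks: A1 C2 B3 -> points A2 C1 B0; dbs (lower better):
        # A1 C2 B3 -> A2 C1 B0; totals A4 C2 B0
        out = borda_aggregate(self._table())
        assert out.loc["A", "borda_points"] == 4.0
        assert out.loc["C", "borda_points"] == 2.0
        assert out.loc["B", "borda_points"] == 0.0
        assert list(out.index) == ["A", "C", "B"]

    def test_single_metric_equals_that_ranking(self):
        t = self._table()[["ari"]]
        out = borda_aggregate(t)
        assert list(out.index) == ["A", "C", "B"]

    def test_dominating_method_ranked_first(self):
        import pandas as pd

        t = pd.DataFrame(
            {"ari": [0.99, 0.1], "ss": [0.9, 0.2], "dbs": [0.1, 2.0]},
            index=["win", "lose"],
        )
        out = borda_aggregate(t)
        assert out.index[0] == "win"
        assert out.loc["win", "rank"] == 1.0

    def test_missing_cells_rejected(self):
        t = self._table()
        t.loc["A", "ari"] = np.nan
        with pytest.raises(ValueError):
            borda_aggregate(t)


class TestPairedTests:
    def test_t_statistic_matches_closed_form(self):
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.7])
        b = np.array([0.6, 0.7, 0.65, 0.9, 0.5])
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        out = paired_tests(a, b, n_comparisons=1)
        assert out["t"] == pytest.approx(t_manual)

    def test_bonferroni_multiplies_and_caps(self):
        a = np.array([0.9, 0.8, 0.85, 0.95, 0.7])
        b = np.array([0.6, 0.7, 0.65, 0.9, 0.5])
        raw = paired_tests(a, b, 1)
        adj = paired_tests(a, b, 10)
        assert adj["p_adjusted"] == pytest.approx(min(1.0, raw["p_raw"] * 10))
        huge = paired_tests(a, b, 10**9)
        assert huge["p_adjusted"] == 1.0

    def test_zero_variance_flagged(self):
        out = paired_tests([1.0, 2.0, 3.0], [0.5, 1.5, 2.5], 1)
        assert out["degenerate"]
        assert np.isnan(out["p_adjusted"])


class TestMetricReport:
    def test_internal_labels_follow_protocol(self, rng):
        X = rng.normal(size=(30, 2))
        pred = rng.integers(0, 2, 30)
        truth = rng.integers(0, 2, 30)
        with_gt = metric_report(X, pred, true_labels=truth)
        assert with_gt.which_labels_internal == "ground-truth"
        assert with_gt.dbs == pytest.approx(davies_bouldin(X, truth))
        without = metric_report(X, pred)
        assert without.which_labels_internal == "predicted"
        assert np.isnan(without.ari)
        assert without.dbs == pytest.approx(davies_bouldin(X, pred))
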
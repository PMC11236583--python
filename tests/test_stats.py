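"""Cluster-permutation, RSR and interaction-contrast tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats as sp_stats

from deltrain import stats
from deltrain.stats import (
    cluster_permutation,
    interaction_contrast,
    paired_t_map,
    rsr_index,
)


def line_graph(n):
    g = np.zeros((n, n), bool)
    for i in range(n - 1):
        g[i, i + 1] = g[i + 1, i] = True
    return g


def grid_graph(n, k=4):
    from deltrain.simulate import _knn_adjacency, _fibonacci_sphere

    return _knn_adjacency(_fibonacci_sphere(n), k)


def make_responses(values):
    """Long-format ROIResponse rows from {(cond, freq): subject array}."""
    rows = []
    for (cond, f), arr in values.items():
        for s, v in enumerate(np.atleast_1d(arr)):
            rows.append(
                {
                    "subject": s,
                    "condition": cond,
                    "frequency": f,
                    "roi": "EAC",
                    "hemisphere": "right",
                    "R": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestPairedT:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((20, 15))
        b = rng.standard_normal((20, 15))
        t_ours = paired_t_map(a, b)
        t_ref = sp_stats.ttest_rel(a, b, axis=0).statistic
        np.testing.assert_allclose(t_ours, t_ref, atol=1e-12)

    def test_equal_conditions_give_zero(self):
        a = np.random.default_rng(1).standard_normal((5, 4))
        np.testing.assert_array_equal(paired_t_map(a, a), np.zeros(4))

    def test_zero_variance_gives_signed_infinity(self):
        a = np.ones((4, 1))
        b = np.zeros((4, 1))
        with pytest.warns(UserWarning, match="zero-variance"):
            t = paired_t_map(a, b)
        assert t[0] == np.inf


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        a = np.random.default_rng(0).standard_normal((10, 20))
        assert cluster_permutation(a, a, line_graph(20), n_perm=200, seed=0) == []

    def test_planted_patch_detected_with_small_p(self):
        """A d=1.5 effect on a 10-channel connected patch is found reliably."""
        graph = grid_graph(30)
        patch = np.arange(10)
        found = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            a = rng.standard_normal((20, 30))
            b = rng.standard_normal((20, 30))
            a[:, patch] += 1.5
            clusters = cluster_permutation(a, b, graph, n_perm=1000, seed=seed)
            top = [c for c in clusters if c.polarity == "+"]
            if top and top[0].p_mc <= 0.01 and len(
                set(top[0].members) & set(patch)
            ) >= 8:
                found += 1
        assert found >= 9

    def test_invariant_to_channel_reordering(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((12, 25))
        b = rng.standard_normal((12, 25))
        a[:, :6] += 1.2
        graph = line_graph(25)
        perm = rng.permutation(25)
        res1 = cluster_permutation(a, b, graph, n_perm=500, seed=3)
        res2 = cluster_permutation(
            a[:, perm], b[:, perm], graph[np.ix_(perm, perm)], n_perm=500, seed=3
        )
        key = lambda cs: sorted(
            (round(c.mass, 10), c.polarity, c.p_mc) for c in cs
        )
        assert key(res1) == key(res2)
        members1 = sorted(tuple(sorted(c.members)) for c in res1)
        members2 = sorted(tuple(sorted(perm[c.members])) for c in res2)
        assert members1 == members2

    def test_global_sign_flip_swaps_polarity_only(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((12, 25))
        b = rng.standard_normal((12, 25))
        a[:, 5:12] += 1.0
        graph = line_graph(25)
        res_pos = cluster_permutation(a, b, graph, n_perm=400, seed=9)
        res_neg = cluster_permutation(b, a, graph, n_perm=400, seed=9)
        assert sorted(round(abs(c.mass), 9) for c in res_pos) == sorted(
            round(abs(c.mass), 9) for c in res_neg
        )
        flip = {"+": "-", "-": "+"}
        assert sorted(flip[c.polarity] for c in res_pos) == sorted(
            c.polarity for c in res_neg
        )

    def test_type_one_error_on_small_null(self):
        """Under the null the rejection rate stays near the nominal level."""
        graph = grid_graph(102, k=6)
        rng = np.random.default_rng(0)
        hits = 0
        for r in range(150):
            a = rng.standard_normal((14, 102))
            b = rng.standard_normal((14, 102))
            hits += any(
                c.significant
                for c in cluster_permutation(a, b, graph, n_perm=300, seed=r)
            )
        assert hits / 150 <= 0.12

    def test_union_find_components_match_csgraph(self):
        """The fast clustering agrees with scipy connected components."""
        from scipy.sparse.csgraph import connected_components

        rng = np.random.default_rng(11)
        for _ in range(20):
            g = grid_graph(40, k=3)
            mask = rng.random(40) < 0.4
            edges = stats._graph_edges(g)
            ours = sorted(tuple(c) for c in stats._components(mask, edges))
            idx = np.flatnonzero(mask)
            sub = sparse.csr_matrix(g)[idx][:, idx]
            n_comp, lab = connected_components(sub, directed=False)
            ref = sorted(
                tuple(sorted(idx[lab == c])) for c in range(n_comp)
            )
            assert ours == ref

    def test_agrees_with_mne_cluster_test(self):
        """Independent oracle: mne finds the same clusters and masses."""
        mne = pytest.importorskip("mne")
        from deltrain.simulate import build_sensor_model

        model = build_sensor_model(seed=0)
        rng = np.random.default_rng(7)
        n = 12
        diff = rng.standard_normal((n, 102))
        diff[:, model.neighborhood[40]] += 1.2
        diff[:, 40] += 1.2
        thr = float(sp_stats.t.ppf(0.975, n - 1))
        ours = cluster_permutation(
            diff, np.zeros_like(diff), model.neighborhood,
            n_perm=5000, min_channels=1, seed=0,
        )
        t_obs, clusters, pv, _ = mne.stats.permutation_cluster_1samp_test(
            diff, threshold=thr, n_permutations=5000,
            adjacency=sparse.csr_matrix(model.neighborhood),
            tail=0, seed=0, out_type="indices", verbose="error",
        )
        ours_set = {
            tuple(sorted(c.members)): (c.mass, c.p_mc) for c in ours
        }
        mne_set = {
            tuple(sorted(cl[0])): (float(t_obs[cl[0]].sum()), float(p))
            for cl, p in zip(clusters, pv)
        }
        assert set(ours_set) == set(mne_set)
        for k, (mass, p) in ours_set.items():
            assert mne_set[k][0] == pytest.approx(mass, abs=1e-8)
        # the planted cluster is highly significant on both routes
        top = min(ours, key=lambda c: c.p_mc)
        assert top.p_mc < 0.001
        assert min(pv) < 0.001


class TestRSR:
    def test_direct_substitution(self):
        df = make_responses(
            {("SLOW", 0.6): [2.0], ("FAST", 0.6): [1.0],
             ("FAST", 0.9): [2.0], ("SLOW", 0.9): [1.0]}
        )
        assert rsr_index(df)["rsr"].iloc[0] == pytest.approx(2.0)

    def test_equal_responses_give_zero(self):
        df = make_responses(
            {("SLOW", 0.6): [3.0], ("FAST", 0.6): [3.0],
             ("FAST", 0.9): [3.0], ("SLOW", 0.9): [3.0]}
        )
        assert rsr_index(df)["rsr"].iloc[0] == pytest.approx(0.0)

    def test_label_swap_negates_rsr(self, cohort):
        """Swapping SLOW and FAST labels flips the sign of every RSR."""
        df = cohort["roi_ent"]
        swapped = df.assign(
            condition=df["condition"].map({"SLOW": "FAST", "FAST": "SLOW"})
        )
        a = rsr_index(df).set_index(["subject", "roi", "hemisphere"])["rsr"]
        b = rsr_index(swapped).set_index(["subject", "roi", "hemisphere"])["rsr"]
        np.testing.assert_allclose(a.to_numpy(), -b.loc[a.index].to_numpy(), atol=1e-12)

    def test_missing_cell_rejected(self):
        df = make_responses(
            {("SLOW", 0.6): [1.0], ("FAST", 0.6): [1.0], ("FAST", 0.9): [1.0]}
        )
        with pytest.raises(stats.MissingCellError):
            rsr_index(df)


class TestInteractionContrast:
    @staticmethod
    def random_responses(rng, n_sub=10, effect=0.0):
        rows = []
        for s in range(n_sub):
            for cond in ("SLOW", "FAST"):
                for f in (0.6, 0.9):
                    r = rng.standard_normal()
                    if effect and cond == "SLOW" and f == 0.6:
                        r += effect
                    if effect and cond == "FAST" and f == 0.9:
                        r += effect
                    rows.append(
                        {"subject": s, "condition": cond, "frequency": f,
                         "roi": "EAC", "hemisphere": "right", "R": r}
                    )
        return pd.DataFrame(rows)

    def test_null_p_values_not_inflated(self):
        rng = np.random.default_rng(3)
        hits = sum(
            interaction_contrast(self.random_responses(rng), n_perm=400, seed=i)[
                "p_perm"
            ].iloc[0]
            < 0.05
            for i in range(40)
        )
        assert hits / 40 <= 0.15

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(4)
        df = self.random_responses(rng, n_sub=14, effect=1.5)
        out = interaction_contrast(df, n_perm=1000, seed=0)
        assert out["p_perm"].iloc[0] < 0.05
        assert out["contrast_mean"].iloc[0] > 0

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(5)
        df = self.random_responses(rng, n_sub=1)
        with pytest.raises(ValueError):
            interaction_contrast(df, n_perm=100, seed=0)

    def test_entrained_cohort_interaction_in_planted_rois(self, cohort):
        """The condition x frequency interaction is detected where sources live."""
        out = interaction_contrast(cohort["roi_ent"], n_perm=1000, seed=1)
        planted = out[
            (out["hemisphere"] == "right") & out["roi"].isin(["EAC", "STG"])
        ]
        assert (planted["p_perm"] < 0.05).all()
        assert (planted["contrast_mean"] > 0).all()


def test_cluster_json_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    a = rng.standard_normal((10, 20))
    b = rng.standard_normal((10, 20))
    a[:, 4:9] += 1.5
    clusters = cluster_permutation(a, b, line_graph(20), n_perm=300, seed=2)
    assert clusters
    import json

    payload = stats.clusters_to_json(clusters, tmp_path / "cl.json")
    back = json.loads((tmp_path / "cl.json").read_text())
    assert back == json.loads(payload)
    assert back[0]["members"] == sorted(int(m) for m in clusters[0].members)
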
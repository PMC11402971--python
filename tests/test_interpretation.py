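import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condviab.interpretation import (bh_adjust, build_ccs,
                                     cluster_target_profile,
                                     compare_ami_baselines,
                                     connectivity_null,
                                     differential_attribution,
                                     geneset_enrichment,
                                     interaction_enrichment, kmeans_ami,
                                     leiden_clusters, rank_sum_test,
                                     subgraph_connectivity,
                                     target_attribution_test)


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating every assignment of
    the pooled ranks to the first group."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    sums = [sum(c) for c in itertools.combinations(ranks, n)]
    obs_dev = abs(observed - mean) - 1e-9
    return sum(abs(s - mean) >= obs_dev for s in sums) / len(sums)


class TestStatisticalKernels:
    def test_small_group_example(self):
        # in-class {3, 4} vs out-class {1, 2}: 1 of 6 assignments is as
        # extreme in each direction -> two-sided p = 1/3
        assert rank_sum_test([3, 4], [1, 2]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(2, 7)
                                     for m in range(n, 7)])
    def test_matches_exact_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        x = rng.permutation(np.arange(1.0, n + m + 1))[:n]
        y = np.setdiff1d(np.arange(1.0, n + m + 1), x)
        assert rank_sum_test(x, y) == pytest.approx(exact_ranksum_p(x, y))

    def test_bh_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_bh_sorted_q_nondecreasing(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestControlCompoundSet:
    @staticmethod
    def _meta(entries):
        return pd.DataFrame(entries, columns=["cell_line_id", "compound_id"])

    def test_filter_rules(self):
        cells = ["c1", "c2"]
        rows = []
        # classA: two compounds in all cells -> kept
        for comp in ("a1", "a2"):
            rows += [(c, comp) for c in cells]
        # classB: single compound -> dropped
        rows += [(c, "b1") for c in cells]
        # classC: two compounds but c2 missing for one -> dropped
        rows += [(c, "c1c") for c in cells] + [("c1", "c2c")]
        meta = self._meta(rows)
        moa = {"a1": "A", "a2": "A", "b1": "B", "c1c": "C", "c2c": "C"}
        mask, labels = build_ccs(meta, moa)
        assert set(labels) == {"A"}
        assert mask.sum() == 4

    def test_no_survivor_raises(self):
        meta = self._meta([("c1", "x"), ("c2", "x")])
        with pytest.raises(ValueError):
            build_ccs(meta, {"x": "X"})

    def test_synthetic_bookkeeping(self):
        # 5 qualifying classes of 2 compounds each, complete across 3 cells
        cells = [f"c{i}" for i in range(3)]
        rows, moa = [], {}
        for k in range(5):
            for j in range(2):
                comp = f"k{k}_{j}"
                moa[comp] = f"class{k}"
                rows += [(c, comp) for c in cells]
        mask, labels = build_ccs(self._meta(rows), moa)
        assert len(set(labels)) == 5
        assert mask.all()


class TestClusteringAgreement:
    def test_perfect_labels(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], 20)
        X = rng.normal(size=(60, 5)) + labels[:, None] * 50
        amis = kmeans_ami(X, labels, n_trials=3, seed=0)
        assert all(a == pytest.approx(1.0) for a in amis)

    def test_chance_correction_near_zero(self):
        from sklearn.metrics import adjusted_mutual_info_score
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 500)
        b = rng.integers(0, 5, 500)
        assert abs(adjusted_mutual_info_score(a, b)) < 0.05

    def test_relabeling_invariance(self):
        from sklearn.metrics import adjusted_mutual_info_score
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 4, 200)
        remap = {0: 3, 1: 2, 2: 0, 3: 1}
        b2 = np.vectorize(remap.get)(b)
        assert adjusted_mutual_info_score(a, b) == pytest.approx(
            adjusted_mutual_info_score(a, b2))
        assert adjusted_mutual_info_score(a, b) == pytest.approx(
            adjusted_mutual_info_score(b, a))

    def test_compare_ami_baselines_shapes(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 15)
        src = {"a": rng.normal(size=(30, 4)) + labels[:, None] * 3,
               "b": rng.normal(size=(30, 4)),
               "b_again": None}
        src["b_again"] = src["b"].copy()
        amis, tests = compare_ami_baselines(src, labels, n_trials=5, seed=0)
        assert set(amis) == {"a", "b", "b_again"}
        assert all(len(v) == 5 for v in amis.values())
        assert amis["b"] == amis["b_again"]  # identical source, same seeds
        assert len(tests) == 3

    def test_misaligned_rows_rejected(self):
        with pytest.raises(ValueError):
            compare_ami_baselines({"a": np.zeros((5, 2))}, np.zeros(6))


class TestTargetAttribution:
    def test_signal_and_null_genes(self):
        rng = np.random.default_rng(0)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        values = pd.DataFrame({
            "tA": np.r_[rng.normal(3, 0.1, 10), rng.normal(0, 0.1, 10)],
            "flat": np.ones(20),
            "missing_not_used": rng.normal(size=20)})
        out = target_attribution_test(
            values, labels, {"A": ["tA", "flat", "absent"]})
        tA = out[out.target == "tA"].iloc[0]
        flat = out[out.target == "flat"].iloc[0]
        absent = out[out.target == "absent"].iloc[0]
        assert tA.q < 0.05 and tA.effect > 2.5
        assert flat.p == pytest.approx(1.0)
        assert not absent.testable
        ok = out[out.testable]
        assert (ok.q >= ok.p - 1e-12).all()


class TestLeiden:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(20, 8)) + np.r_[5.0, np.zeros(7)]
        b = rng.normal(0, 0.1, size=(20, 8)) + np.r_[np.zeros(7), 5.0]
        X = np.vstack([a, b])
        labels = leiden_clusters(X, resolution=1.0, k_neighbors=10, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        a = leiden_clusters(X, seed=4)
        b = leiden_clusters(X, seed=4)
        assert np.array_equal(a, b)

    def test_low_resolution_single_cluster(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        labels = leiden_clusters(X, resolution=1e-4, k_neighbors=10, seed=0)
        assert len(set(labels.tolist())) == 1


class TestDifferentialAttribution:
    def test_planted_markers_recovered(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 50))
            X[:12, :10] += 2.5  # cluster 0 with 10 elevated genes
            values = pd.DataFrame(X, columns=[f"g{i}" for i in range(50)])
            clusters = np.r_[np.zeros(12, int), np.ones(28, int)]
            res = differential_attribution(values, clusters, 0)
            hits.append(len(set(res.top10) & {f"g{i}" for i in range(10)}))
        assert all(h >= 8 for h in hits)

    def test_flat_gene_never_marker(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 20))
        X[:10, :5] += 3
        values = pd.DataFrame(X, columns=[f"g{i}" for i in range(20)])
        values["identical"] = 1.0
        clusters = np.r_[np.zeros(10, int), np.ones(20, int)]
        res = differential_attribution(values, clusters, 0)
        assert "identical" not in res.top10
        assert (res.table.q >= res.table.p - 1e-12).all()

    def test_merged_clusters_and_errors(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(12, 4)))
        clusters = np.r_[np.zeros(4, int), np.ones(4, int), np.full(4, 2)]
        res = differential_attribution(values, clusters, [0, 1])
        assert len(res.table) == 4
        with pytest.raises(ValueError):
            differential_attribution(values, clusters, [0, 1, 2])


class TestTargetProfiles:
    def test_one_target_per_class(self):
        moa = {"c1": "A", "c2": "B", "c3": "C"}
        targets = {"A": ["EGFR", "ERBB2"], "B": ["TP53"], "C": []}
        with pytest.warns(UserWarning, match="'C'"):
            chosen = cluster_target_profile(["c1", "c2", "c3"], moa, targets,
                                            seed=0)
        assert len(chosen) == 2
        assert chosen & {"EGFR", "ERBB2"}
        assert "TP53" in chosen
        again = cluster_target_profile(["c1", "c2"], moa, targets, seed=0)
        assert again <= {"EGFR", "ERBB2", "TP53"}


class TestNetworkStatistics:
    @staticmethod
    def _background(seed=0, n=40, p=0.08):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        return nx.relabel_nodes(g, {i: f"G{i}" for i in range(n)})

    def test_degenerate_sets(self):
        g = self._background()
        assert subgraph_connectivity(g, []) == 0.0
        assert subgraph_connectivity(g, ["G0"]) == 0.0
        assert subgraph_connectivity(g, ["G0", "not-in-graph"]) == 0.0

    def test_complete_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert subgraph_connectivity(g, {"a", "b", "c"}) == 1.0

    def test_planted_clique_beats_null(self):
        g = self._background()
        clique = [f"G{i}" for i in range(34, 40)]
        g.add_edges_from(itertools.combinations(clique, 2))
        null = connectivity_null(g, clique, [f"G{i}" for i in range(40)],
                                 n_draws=1000, seed=0)
        assert null["observed"] == 1.0
        assert null["p"] == pytest.approx(1 / 1001)
        assert null["observed"] > np.percentile(null["null"], 95)

    def test_null_p_bounds_and_determinism(self):
        g = self._background(1)
        nodes = ["G1", "G2", "G3"]
        pool = [f"G{i}" for i in range(40)]
        a = connectivity_null(g, nodes, pool, n_draws=200, seed=5)
        b = connectivity_null(g, nodes, pool, n_draws=200, seed=5)
        assert a["p"] == b["p"]
        assert 1 / 201 <= a["p"] <= 1.0
        with pytest.raises(ValueError):
            connectivity_null(g, pool, ["G1"], n_draws=10, seed=0)

    def test_interaction_enrichment_toy(self):
        # universe: 4 proteins -> 6 pairs; graph has 3 edges, all inside the
        # 3-node query -> p = C(3,3) C(3,0) / C(6,3) = 1/20
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        p = interaction_enrichment(g, {"a", "b", "c"}, background_size=4)
        assert p == pytest.approx(0.05)

    def test_interaction_enrichment_zero_edges(self):
        g = nx.Graph([("x", "y")])
        p = interaction_enrichment(g, {"a", "b", "c"}, background_size=10)
        assert p == pytest.approx(1.0)

    def test_enrichment_monotone_in_edges(self):
        base = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        p0 = interaction_enrichment(base, {"a", "b", "c"}, 20)
        base.add_edge("b", "c")
        p1 = interaction_enrichment(base, {"a", "b", "c"}, 20)
        assert p1 <= p0


class TestGenesetEnrichment:
    def test_tail_probability(self):
        background = [f"g{i}" for i in range(100)]
        query = background[:10]
        sets = {"hit": set(background[:5]) | set(background[90:95]),
                "disjoint": set(background[50:60])}
        out = geneset_enrichment(query, sets, background)
        hit = out[out.gene_set == "hit"].iloc[0]
        assert hit.overlap == 5
        assert hit.p == pytest.approx(
            float(stats.hypergeom.sf(4, 100, 10, 10)))
        dis = out[out.gene_set == "disjoint"].iloc[0]
        assert dis.overlap == 0 and dis.p == pytest.approx(1.0)

    def test_query_equal_to_set_is_minimal(self):
        background = [f"g{i}" for i in range(20)]
        sets = {"self": set(background[:5]), "other": set(background[10:18])}
        out = geneset_enrichment(background[:5], sets, background)
        assert out.iloc[0].gene_set == "self"
        with pytest.raises(ValueError):
            geneset_enrichment(["nope"], sets, background)

    def test_gmt_roundtrip(self, tmp_path):
        from condviab.interpretation import load_gmt
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = load_gmt(path)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4"}}
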
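"""CV ranking, all-pairs Pearson, thresholded networks and overlays."""

import numpy as np
import pandas as pd
import pytest

import desiccnet as d
from conftest import pearson_brute_force
from desiccnet.config import ModuleSpec


def _tissue_design(n_genes, n_samples, tissue="root", seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"{tissue}_s{i}" for i in range(n_samples)]
    expr = pd.DataFrame(rng.normal(5, 1, (n_genes, n_samples)),
                        index=[f"g{i:03d}" for i in range(n_genes)],
                        columns=cols)
    samples = pd.DataFrame([
        {"sample_id": c, "tissue": tissue, "state": "hydrated", "replicate": i}
        for i, c in enumerate(cols)])
    return expr, samples


class TestRankByCv:
    def test_hand_computed_ordering(self):
        cols = ["root_s0", "root_s1", "root_s2", "root_s3"]
        data = {
            "g_flat": [5.0, 5.0, 5.0, 5.0],       # cv = 0
            "g_low": [10.0, 10.2, 9.8, 10.0],
            "g_mid": [4.0, 6.0, 5.0, 5.0],
            "g_high": [1.0, 3.0, 1.0, 3.0],
            "g_neg": [-2.0, -2.2, -1.8, -2.0],    # |mean| in denominator
        }
        expr = pd.DataFrame(data).T
        expr.columns = cols
        samples = pd.DataFrame([{"sample_id": c, "tissue": "root",
                                 "state": "x", "replicate": i}
                                for i, c in enumerate(cols)])
        ranking = d.rank_by_cv(expr, samples, "root")
        expected = {g: np.std(v, ddof=1) / abs(np.mean(v))
                    for g, v in data.items()}
        by_hand = sorted(expected, key=lambda g: (-expected[g], g))
        assert ranking.gene.tolist() == by_hand
        assert ranking["rank"].tolist() == [1, 2, 3, 4, 5]
        np.testing.assert_allclose(
            ranking.set_index("gene").cv[list(expected)],
            [expected[g] for g in expected])
        assert ranking.gene.iloc[-1] == "g_flat"  # constant gene ranked last

    def test_cv_scale_invariance(self):
        expr, samples = _tissue_design(10, 6, seed=1)
        before = d.rank_by_cv(expr, samples, "root").set_index("gene").cv
        expr.loc["g003"] *= 7.5
        after = d.rank_by_cv(expr, samples, "root").set_index("gene").cv
        assert after["g003"] == pytest.approx(before["g003"])

    def test_near_zero_mean_genes_are_excluded(self):
        expr, samples = _tissue_design(5, 6, seed=2)
        expr.loc["g000"] -= expr.loc["g000"].mean()  # mean ~ 0
        ranking = d.rank_by_cv(expr, samples, "root")
        assert "g000" not in set(ranking.gene)

    def test_too_few_samples_is_design_error(self):
        expr, samples = _tissue_design(5, 2)
        with pytest.raises(ValueError, match="need >= 3"):
            d.rank_by_cv(expr, samples, "root")


class TestSelectTopK:
    def test_k_larger_than_n_returns_all(self):
        expr, samples = _tissue_design(5, 6)
        ranking = d.rank_by_cv(expr, samples, "root")
        assert len(d.select_top_k(ranking, 100)) == 5

    def test_top_two_match_oracle(self):
        expr, samples = _tissue_design(8, 6, seed=3)
        ranking = d.rank_by_cv(expr, samples, "root")
        assert d.select_top_k(ranking, 2) == ranking.gene.head(2).tolist()

    def test_tie_at_boundary_prefers_lexicographic(self):
        cols = ["root_s0", "root_s1", "root_s2"]
        expr = pd.DataFrame({"b_gene": [1.0, 2.0, 3.0],
                             "a_gene": [2.0, 4.0, 6.0],  # same cv as b_gene
                             "c_flat": [5.0, 5.0, 5.0]}).T
        expr.columns = cols
        samples = pd.DataFrame([{"sample_id": c, "tissue": "root",
                                 "state": "x", "replicate": i}
                                for i, c in enumerate(cols)])
        ranking = d.rank_by_cv(expr, samples, "root")
        assert d.select_top_k(ranking, 1) == ["a_gene"]


class TestPearsonAllPairs:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=8)
        expr = pd.DataFrame({"a": v, "a_copy": v.copy(),
                             "a_neg": 2 * v.mean() - v}).T
        corr = d.pearson_all_pairs(expr)
        assert corr.loc["a", "a_copy"] == pytest.approx(1.0)
        assert corr.loc["a", "a_neg"] == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 12))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(20)])
        expr.columns = [f"s{i}" for i in range(12)]
        np.testing.assert_allclose(d.pearson_all_pairs(expr).to_numpy(),
                                   pearson_brute_force(x), atol=1e-12)

    def test_constant_gene_is_named_in_error(self):
        expr = pd.DataFrame({"g_const": [1.0, 1.0, 1.0, 1.0],
                             "g_ok": [1.0, 2.0, 3.0, 4.0]}).T
        with pytest.raises(ValueError, match="g_const"):
            d.pearson_all_pairs(expr)


def _corr_df(mat, genes):
    return pd.DataFrame(mat, index=genes, columns=genes)


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        genes = ["a", "b", "c"]
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.964   # exactly the cutoff: NOT an edge
        m[0, 2] = m[2, 0] = 0.9641
        net = d.build_network(_corr_df(m, genes), threshold=0.964)
        assert set(net.edges) == {("a", "c")}
        assert "b" not in net.nodes  # isolated genes excluded

    def test_perfect_triangle(self):
        genes = ["a", "b", "c"]
        net = d.build_network(_corr_df(np.ones((3, 3)), genes))
        assert net.number_of_edges() == 3

    def test_threshold_monotonicity_nested_edge_sets(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 8))
        corr = d.pearson_all_pairs(
            pd.DataFrame(x, index=[f"g{i}" for i in range(15)]))
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset,
                            d.build_network(corr, threshold=thr).edges))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_module_recovery_with_noise_background(self):
        cfg = d.SimulationConfig(
            n_genes=120, module_size=20, tissues=("root",),
            modules=(ModuleSpec("root", (), "up"),),
            module_corr=0.99, seed=8)
        expr, samples, truth = d.generate_expression(cfg)
        corr = d.pearson_all_pairs(expr)
        net = d.build_network(corr, threshold=0.964, tissue="root")
        members = {g for g, m in truth.module_truth.items() if m == 0}
        within = [e for e in net.edges if set(e) <= members]
        outside = [e for e in net.edges if not (set(e) & members)]
        assert len(within) >= 0.9 * (20 * 19 / 2)
        assert len(outside) == 0

    def test_tissue_separation(self, default_config):
        # permuting the other tissue's samples leaves this tissue's
        # network unchanged
        expr, samples, _ = d.generate_expression(default_config)
        shoot_cols = samples.loc[samples.tissue == "shoot", "sample_id"]
        rng = np.random.default_rng(0)
        permuted = expr.copy()
        permuted[shoot_cols] = permuted[shoot_cols.sample(
            frac=1, random_state=3).to_numpy()].to_numpy()

        def root_net(e):
            ranking = d.rank_by_cv(e, samples, "root")
            top = d.select_top_k(ranking, 150)
            cols = samples.loc[samples.tissue == "root", "sample_id"].tolist()
            return d.build_network(d.pearson_all_pairs(e.loc[top, cols]),
                                   threshold=0.964, tissue="root")

        n1, n2 = root_net(expr), root_net(permuted)
        assert set(n1.nodes) == set(n2.nodes)
        assert set(map(frozenset, n1.edges)) == set(map(frozenset, n2.edges))


def _six_node_network():
    g = pd.DataFrame(np.eye(6), index=list("abcdef"), columns=list("abcdef"))
    for u, v in [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f"), ("a", "f")]:
        g.loc[u, v] = g.loc[v, u] = 0.99
    return d.build_network(g, threshold=0.964, tissue="root")


class TestOverlayAndSummaries:
    def test_empty_deg_table_all_unchanged(self):
        net = _six_node_network()
        table = pd.DataFrame(columns=["gene", "tissue", "state", "log2fc",
                                      "p_raw", "p_adj", "passes", "direction"])
        overlay = d.overlay_deg_states(net, {"RWC40": table})
        assert set(overlay["RWC40"].values()) == {"unchanged"}

    def test_passing_down_gene_gets_down_status(self):
        net = _six_node_network()
        table = pd.DataFrame({"gene": ["a"], "tissue": ["root"],
                              "state": ["RWC40"], "log2fc": [-2.0],
                              "p_raw": [0.001], "p_adj": [0.004],
                              "passes": [True], "direction": ["down"]})
        overlay = d.overlay_deg_states(net, {"RWC40": table})
        assert overlay["RWC40"]["a"] == "down"

    def test_tissue_mismatch_is_design_error(self):
        net = _six_node_network()
        table = pd.DataFrame({"gene": ["a"], "tissue": ["shoot"],
                              "state": ["RWC40"], "log2fc": [-2.0],
                              "p_raw": [0.001], "p_adj": [0.004],
                              "passes": [True], "direction": ["down"]})
        with pytest.raises(ValueError, match="tissue"):
            d.overlay_deg_states(net, {"RWC40": table})

    def test_hand_enumerated_summary(self):
        # a-b-c-f-a cycle-ish: edges ab, bc, de, ef, af
        # status: a,b up; d,e,f down; c unchanged
        net = _six_node_network()
        overlay = {"RWC40": {"a": "up", "b": "up", "c": "unchanged",
                             "d": "down", "e": "down", "f": "down"},
                   "RWC60": {n: "unchanged" for n in "abcdef"}}
        summ = d.summarize_states(net, overlay)
        row = summ["per_state"].set_index("state").loc["RWC40"]
        assert row.n_up == 2 and row.n_down == 3
        # active edges: ab (up-up), de, ef (down-down); af mixed -> not
        assert row.n_active_edges == 3
        # components: {a,b}, {d,e,f} -> 2
        assert row.n_components_active == 2
        quiet = summ["per_state"].set_index("state").loc["RWC60"]
        assert quiet.n_up == quiet.n_down == quiet.n_active_edges == 0
        assert summ["jaccard"].loc["RWC40", "RWC60"] == 0.0
        assert summ["jaccard"].loc["RWC40", "RWC40"] == 1.0

    def test_identical_active_sets_have_unit_jaccard(self):
        net = _six_node_network()
        status = {"a": "up", "b": "up", "c": "unchanged",
                  "d": "unchanged", "e": "unchanged", "f": "unchanged"}
        summ = d.summarize_states(net, {"s1": status, "s2": dict(status)})
        assert summ["jaccard"].loc["s1", "s2"] == 1.0


class TestExportRoundTrip:
    def test_round_trip_preserves_network(self, tmp_path):
        net = _six_node_network()
        overlay = {"RWC40": {n: "up" if n in "ab" else "unchanged"
                             for n in net.nodes}}
        d.export_network(net, overlay, tmp_path / "e.tsv",
                         tmp_path / "n.graphml")
        back = d.read_network(tmp_path / "n.graphml")
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))
        for u, v, data in net.edges(data=True):
            assert back.edges[u, v]["r"] == pytest.approx(data["r"], abs=1e-9)
        assert back.nodes["a"]["status_RWC40"] == "up"
        edge_lines = (tmp_path / "e.tsv").read_text().strip().split("\n")
        assert len(edge_lines) == 1 + net.number_of_edges()

    def test_empty_network_is_valid_graphml(self, tmp_path):
        import networkx as nx
        empty = d.build_network(
            pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]),
            threshold=0.99)
        d.export_network(empty, None, tmp_path / "e.tsv",
                         tmp_path / "n.graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert back.number_of_nodes() == 0
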
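import numpy as np
import networkx as nx
import pandas as pd
import pytest

from pipetarget.crosstalk_detection import (
    CrosstalkResult,
    _graph_csr,
    _solve_at_threshold,
    find_crosstalk,
    merge_pathways,
    permutation_significance,
    read_gmt,
    PathwayNetwork,
)


class TestMergePathways:
    def test_shared_edge_merges_provenance(self):
        gmt = {"p1": ["a", "b"], "p2": ["a", "b"]}
        df = pd.DataFrame({"gene1": ["a", "a"], "gene2": ["b", "b"],
                           "pathway": ["p1", "p2"]})
        net = merge_pathways(gmt, df)
        assert net.graph["a"]["b"]["pathways"] == {"p1", "p2"}

    def test_pathway_without_interactions_contributes_no_edges(self):
        gmt = {"p1": ["a", "b"], "lonely": ["x", "y", "z"]}
        df = pd.DataFrame({"gene1": ["a"], "gene2": ["b"], "pathway": ["p1"]})
        net = merge_pathways(gmt, df)
        assert net.graph.degree("x") == 0

    def test_duplicate_edges_deduplicated(self):
        rows = [("a", "b", "p1"), ("b", "c", "p1"), ("c", "d", "p2"),
                ("d", "e", "p2"), ("e", "f", "p2"), ("f", "g", "p3"),
                ("g", "h", "p3"), ("h", "i", "p3"),
                ("a", "b", "p2"), ("c", "d", "p3")]  # 2 duplicates
        df = pd.DataFrame(rows, columns=["gene1", "gene2", "pathway"])
        net = merge_pathways({"p": []}, df)
        assert net.graph.number_of_edges() == 8

    def test_no_edges_is_hard_error(self):
        with pytest.raises(ValueError, match="no edges"):
            merge_pathways({"p1": ["a"]}, pd.DataFrame(
                columns=["gene1", "gene2", "pathway"]))


def _clique_in_noise(rng, n_noise=200, k=20):
    g = nx.random_regular_graph(3, n_noise, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"bg{i}" for i in range(n_noise)})
    clique = [f"sig{i}" for i in range(k)]
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            g.add_edge(a, b)
    g.add_edge(clique[0], "bg0")  # keep the graph connected
    credits = {v: 0.0 for v in g.nodes}
    credits.update({v: 10.0 - 0.01 * i for i, v in enumerate(clique)})
    return PathwayNetwork(graph=g), credits, set(clique)


class TestFindCrosstalk:
    def test_planted_clique_recovered_exactly(self):
        rng = np.random.default_rng(0)
        net, credits, clique = _clique_in_noise(rng)
        res = find_crosstalk(net, credits, target_size=20)
        assert set(res.nodes) == clique
        assert nx.is_connected(nx.Graph(res.edges))

    def test_negative_bridge_included_for_connectivity(self):
        g = nx.Graph([("hub1", "bridge"), ("bridge", "hub2")])
        credits = np.array([10.0, 4.0, 10.0])  # hub1, bridge, hub2 (sorted order)
        nodes = sorted(g.nodes)
        cvec = np.array([{"bridge": 4.0, "hub1": 10.0, "hub2": 10.0}[v] for v in nodes])
        indptr, indices = _graph_csr(g, nodes)
        sel = _solve_at_threshold(indptr, indices, cvec, t=5.0)
        assert {nodes[i] for i in sel} == {"hub1", "bridge", "hub2"}

    def test_size_within_bound_for_random_credits(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(120, 0.05, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(120)})
        credits = {v: float(rng.uniform(0, 10)) for v in g.nodes}
        res = find_crosstalk(PathwayNetwork(graph=g), credits, target_size=20)
        assert 1 <= res.size <= int(np.ceil(1.1 * 20))

    def test_never_worse_than_best_singleton(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(60, 0.08, seed=2)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(60)})
        credits = {v: float(rng.uniform(0, 10)) for v in g.nodes}
        res = find_crosstalk(PathwayNetwork(graph=g), credits, target_size=10)
        best_single = max(credits.values())
        assert res.total_score >= best_single - res.threshold - 1e-9


class TestPermutationSignificance:
    def test_planted_signal_is_significant(self):
        rng = np.random.default_rng(0)
        net, credits, _ = _clique_in_noise(rng)
        res = find_crosstalk(net, credits, target_size=20)
        res = permutation_significance(net, credits, res, n_perm=200, seed=1)
        assert res.p_normal < 0.01
        assert res.p_empirical <= 1 / (1 + 200) + 1e-12

    def test_observed_below_null_mean_gives_large_p(self):
        rng = np.random.default_rng(0)
        net, credits, _ = _clique_in_noise(rng)
        res = find_crosstalk(net, credits, target_size=20)
        weak = CrosstalkResult(nodes=res.nodes, credits=res.credits,
                               edges=res.edges, threshold=res.threshold,
                               total_score=-1.0)
        weak = permutation_significance(net, credits, weak, n_perm=100, seed=1)
        assert weak.p_normal >= 0.5

    def test_permutation_preserves_credit_multiset_within_degree_bins(self):
        # re-implement the binning step and assert the shuffle invariant
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(80, 0.06, seed=4)
        deg = np.array([d for _, d in sorted(g.degree())])
        credits = rng.uniform(0, 10, 80)
        qs = np.quantile(deg, np.linspace(0, 1, 11)[1:-1])
        bins = np.searchsorted(qs, deg, side="right")
        perm = credits.copy()
        for b in np.unique(bins):
            members = np.nonzero(bins == b)[0]
            perm[members] = perm[rng.permutation(members)]
            assert sorted(perm[members]) == pytest.approx(sorted(credits[members]))

    def test_degree_sequence_untouched(self, pipeline_run):
        manifest = pipeline_run["manifest"]
        net = merge_pathways(manifest["files"]["pathways_gmt"],
                             manifest["files"]["pathway_edges"])
        before = sorted(d for _, d in net.graph.degree())
        cred = pd.read_csv(pipeline_run["run_dir"] / "prioritization.tsv",
                           sep="\t", comment="#", index_col=0)["credit"]
        res = find_crosstalk(net, cred, target_size=10)
        permutation_significance(net, cred, res, n_perm=20, seed=0)
        assert sorted(d for _, d in net.graph.degree()) == before


def test_read_gmt_round_trip(tmp_path):
    p = tmp_path / "x.gmt"
    p.write_text("s1\tdesc\ta\tb\tc\ns2\tdesc\td\n")
    sets = read_gmt(p)
    assert sets == {"s1": ["a", "b", "c"], "s2": ["d"]}
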
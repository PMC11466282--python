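"""Laplacian normalization, RWR, null networks, ego decomposition, enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from dvomics import diffusion as df
from dvomics.ontology import OntologyDAG
from dvomics.simulate import ConfigurationError


def _unit_graph(edges):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=1.0)
    return g


def test_laplacian_triangle_and_star():
    tri = df.laplacian_normalize(_unit_graph([("a", "b"), ("b", "c"), ("a", "c")]))
    assert all(d["weight"] == pytest.approx(0.5) for _, _, d in tri.edges(data=True))
    star = df.laplacian_normalize(
        _unit_graph([("c", "x"), ("c", "y"), ("c", "z")])
    )
    for _, _, d in star.edges(data=True):
        assert d["weight"] == pytest.approx(1 / math.sqrt(3))
    w = nx.to_numpy_array(star, weight="weight")
    assert np.allclose(w, w.T)  # symmetric in, symmetric out


def test_laplacian_removes_isolated_nodes():
    g = _unit_graph([("a", "b")])
    g.add_node("loner")
    with pytest.warns(UserWarning):
        out = df.laplacian_normalize(g)
    assert "loner" not in out


def test_rwr_restart_one_returns_seed_distribution():
    g = df.laplacian_normalize(_unit_graph([("a", "b"), ("b", "c")]))
    p = df.rwr(g, {"a": 2.0, "b": 2.0}, restart=1.0)
    assert p.to_dict() == {"a": 0.5, "b": 0.5, "c": 0.0}


def test_rwr_two_node_closed_form():
    g = df.laplacian_normalize(_unit_graph([("a", "b")]))
    p = df.rwr(g, {"a": 1.0}, restart=0.5, tol=1e-14)
    assert p["a"] == pytest.approx(2 / 3)
    assert p["b"] == pytest.approx(1 / 3)


def test_rwr_matches_direct_solve_on_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.random() + 0.05)
        gn = df.laplacian_normalize(g)
        seeds = {n_: 1.0 for n_ in list(gn.nodes)[:2]}
        p_iter = df.rwr(gn, seeds, 0.5, tol=1e-14)
        p_solve = df.rwr_solve(gn, seeds, 0.5)
        assert np.abs(p_iter - p_solve).max() < 1e-8


def test_rwr_input_validation():
    g = df.laplacian_normalize(_unit_graph([("a", "b")]))
    with pytest.raises(ConfigurationError):
        df.rwr(g, {}, 0.5)
    with pytest.raises(ConfigurationError):
        df.rwr(g, {"a": 1.0}, 0.0)


def test_null_networks_preserve_degrees_and_seed():
    g = nx.barabasi_albert_graph(40, 2, seed=1)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = 1.0
    nulls1 = df.null_networks(g, 3, seed=9)
    nulls2 = df.null_networks(g, 3, seed=9)
    for n1, n2 in zip(nulls1, nulls2):
        assert sorted(n1.edges) == sorted(n2.edges)
        assert dict(n1.degree()) == dict(g.degree())
    assert any(
        sorted(n.edges) != sorted(g.edges) for n in nulls1
    )  # actually rewired


def test_triangle_cannot_rewire_flagged_copy():
    tri = _unit_graph([("a", "b"), ("b", "c"), ("a", "c")])
    (null,) = df.null_networks(tri, 1, seed=0)
    assert sorted(null.edges) == sorted(tri.edges)
    assert null.graph.get("rewire_failed")


def test_empirical_pvalue_extremes_and_retention_rule():
    idx = pd.Index(["n1", "n2", "n3"])
    real = {
        "a": pd.Series([10.0, 0.0, 5.0], index=idx),
        "b": pd.Series([0.0, 0.0, 5.0], index=idx),
    }
    nulls = {
        "a": np.tile([1.0, 1.0, 5.0], (100, 1)),
        "b": np.tile([1.0, 1.0, 4.0], (100, 1)),
    }
    p, retained = df.empirical_pvalues(real, nulls)
    assert p.loc["n1", "a"] == 0.0  # above all nulls
    assert p.loc["n2", "a"] == 1.0  # below all nulls
    assert p.loc["n3", "b"] == 0.0
    assert retained == ["n1", "n3"]  # significant in >= 1 partition


def _ego_fixture():
    """Line a-b-c-d-e plus ring edges; annotations make a,b,c,d similar."""
    terms = ["root", "T1", "T2"]
    dag = OntologyDAG.from_parent_map(terms, {"T1": "root", "T2": "root"}, "root")
    genes = {f"g{i}": {"T1"} for i in range(5)}
    genes |= {f"h{i}": {"T2"} for i in range(20)}
    dag.set_annotations(genes)
    g = nx.Graph()
    for i in range(4):
        g.add_edge(f"g{i}", f"g{i+1}", weight=1.0)
    g.add_edge("g1", "g2", weight=1.0)
    g.add_edge("g0", "g2", weight=1.0)
    g.add_edge("g2", "g4", weight=1.0)  # keeps g4 within 2 steps of g0
    # a distant tail beyond 2 steps
    g.add_edge("g4", "h0", weight=1.0)
    g.add_edge("h0", "h1", weight=1.0)
    return g, dag


def test_ego_membership_two_step_limit_and_min_size():
    g, dag = _ego_fixture()
    stats_table = df.resnik_stats(dag, ["g0"], list(g.nodes) + [f"h{i}" for i in range(2, 20)])
    egos = df.ego_decompose(g, ["g0"], dag, stats_table, min_size=5)
    assert len(egos) == 1
    members = set(egos[0].members)
    assert "h1" not in members  # 3 steps away can never be a member
    assert "h0" not in members  # dissimilar annotation fails the z filter
    assert members == {"g0", "g1", "g2", "g3", "g4"}
    # with a higher minimum size the ego network is discarded
    assert df.ego_decompose(g, ["g0"], dag, stats_table, min_size=6) == []


def test_ego_edge_reweighting_follows_ring_rules():
    g, dag = _ego_fixture()
    stats_table = df.resnik_stats(dag, ["g0"], list(g.nodes) + [f"h{i}" for i in range(2, 20)])
    # reconstruct pre-normalization weights by re-deriving the rule
    (ego,) = df.ego_decompose(g, ["g0"], dag, stats_table)
    ring1 = ego.ring1
    assert "g1" in ring1 and "g2" in ring1
    # within-ring edge (g1, g2): mean of the two Resnik values
    expected = 0.5 * (dag.resnik("g0", "g1") + dag.resnik("g0", "g2"))
    assert expected == pytest.approx(dag.resnik("g0", "g1"))  # symmetric corpus
    # normalized graph is still symmetric with positive weights
    w = nx.to_numpy_array(ego.graph, weight="weight")
    assert np.allclose(w, w.T)
    assert (w[w > 0] > 0).all()


def test_ego_distances_zero_at_ego_and_jsd_hand_value():
    g, dag = _ego_fixture()
    stats_table = df.resnik_stats(dag, ["g0"], list(g.nodes) + [f"h{i}" for i in range(2, 20)])
    (ego,) = df.ego_decompose(g, ["g0"], dag, stats_table)
    dist = df.ego_distances(ego, dag, restart=0.5)
    assert dist.loc["g0", "topological"] == pytest.approx(0.0, abs=1e-6)
    # hand-checked Jensen-Shannon distance for (1,0) vs (.5,.5)
    from scipy.spatial.distance import jensenshannon

    jsd = jensenshannon([1.0, 0.0], [0.5, 0.5], base=2)
    assert jsd == pytest.approx(0.5579, abs=2e-4)
    assert 1000 * np.log2(1 - jsd) == pytest.approx(1000 * np.log2(0.4421), abs=0.5)


def test_kde_filter_mode_kept_outlier_dropped():
    tight = np.concatenate([np.random.default_rng(0).normal(0, 0.05, 30), [50.0]])
    d = pd.DataFrame(
        {"topological": tight, "functional": np.zeros(31)},
        index=[f"n{i}" for i in range(31)],
    )
    kept = df.kde_filter(d)
    assert "n30" not in kept  # the far outlier
    assert len(kept) >= 25  # the tight cluster sits at the mode
    # all-identical members are all retained
    flat = pd.DataFrame(
        {"topological": np.ones(5), "functional": np.ones(5)},
        index=list("abcde"),
    )
    assert df.kde_filter(flat) == list("abcde")


def test_hypergeometric_enrichment_closed_form():
    terms = ["root", "T"]
    dag = OntologyDAG.from_parent_map(terms, {"T": "root"}, "root")
    genes = {f"g{i}": {"T"} for i in range(5)}
    genes |= {f"h{i}": {"root"} for i in range(15)}
    dag.set_annotations(genes)
    background = set(genes)
    members = {f"g{i}" for i in range(5)}
    table = df.term_enrichment(members, dag, background)
    assert table.loc["T", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)
    assert table.loc["root", "p"] == 1.0  # term covering the whole background
    disjoint = df.term_enrichment({"h0", "h1"}, dag, background)
    assert disjoint.loc["T", "p"] == 1.0
    assert df.term_enrichment(set(), dag, background).empty


def test_consensus_term_rules():
    def enr(terms_p):
        return pd.DataFrame(
            {"p": list(terms_p.values()), "p_adj": list(terms_p.values())},
            index=pd.Index(terms_p, name="term"),
        )

    enrichments = {
        "n1": enr({"A": 0.001, "B": 0.2}),
        "n2": enr({"A": 0.01, "B": 0.01}),
        "n3": enr({"B": 0.5}),
        "n4": enr({"C": 0.04}),
    }
    cons = df.consensus_terms(enrichments, min_networks=2)
    assert list(cons.index) == ["A"]  # only A is significant in >= 2
    union = df.consensus_terms(enrichments, min_networks=1)
    assert set(union.index) == {"A", "B", "C"}


def test_build_seed_weights_reciprocal_median_iqr():
    scores = pd.Series({"P1": 0.5, "P2": 0.0})
    w = df.build_seed_weights(scores, mode="ed", max_weight=100.0)
    assert w["P1"] == pytest.approx(2.0)
    assert w["P2"] == 100.0  # zero score capped
    sites = pd.Series({"s1": 0.2, "s2": 0.4, "s3": 0.8})
    mapping = pd.Series({"s1": "P", "s2": "P", "s3": "P"})
    w2 = df.build_seed_weights(sites, mode="ed", site_to_host=mapping)
    assert w2["P"] == pytest.approx(2.5)  # median 0.4 -> 1/0.4
    # deviation mode keeps only the interquartile range
    devs = pd.Series({f"P{i}": v for i, v in enumerate([-3, -1, -0.5, 0.5, 1, 3])})
    w3 = df.build_seed_weights(devs, mode="dev")
    assert set(w3.index) <= set(devs.index) and "P0" not in w3 and "P5" not in w3


def test_partition_seed_sets_normalized():
    weights = pd.Series({"a": 1.0, "b": 3.0, "c": 2.0})
    partition = {"a": "tyrosine-kinase", "b": "tyrosine-kinase", "c": "other"}
    sets = df.partition_seed_sets(weights, partition)
    assert sets["tyrosine-kinase"]["a"] == pytest.approx(0.25)
    assert sum(sets["tyrosine-kinase"].values()) == pytest.approx(1.0)
    assert sets["other"] == {"c": 1.0}
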
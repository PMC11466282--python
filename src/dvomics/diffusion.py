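"""Network propagation over Resnik-weighted interaction networks.

The pipeline scores network nodes by a random walk with restart (RWR) from
seed sets split into three partitions (tyrosine kinases, other kinases, other
proteins), assesses significance against degree-preserving null networks, and
decomposes the significant subnetwork into ego networks filtered by semantic
similarity, topological/functional distance density, and ontology-term
enrichment with cross-network consensus.

Edge weights are first hub-corrected by Laplacian normalization

    w'_ij = w_ij / sqrt(d_i d_j)

with d_i the weighted degree. The normalized matrix is not stochastic, so the
walk column-normalizes it at iteration time, making every RWR score vector a
probability distribution (required for the Jensen-Shannon distance used in
the topological distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

from .ontology import OntologyDAG
from .simulate import ConfigurationError

PARTITIONS = ("tyrosine-kinase", "other-kinase", "other")
#: floor before log2 in the distance transforms (documented clip)
LOG_FLOOR = 2.0**-52


class ConvergenceError(RuntimeError):
    pass


# --- normalization and RWR ---------------------------------------------------


def laplacian_normalize(g: nx.Graph) -> nx.Graph:
    """Hub correction: w'_ij = w_ij / sqrt(d_i d_j) on weighted degrees.

    Isolated (zero-weighted-degree) nodes are removed with a warning before
    normalization.
    """
    degree = dict(g.degree(weight="weight"))
    isolated = [n for n, d in degree.items() if d <= 0]
    if isolated:
        warnings.warn(f"removing {len(isolated)} isolated node(s) before "
                      "Laplacian normalization")
        g = g.copy()
        g.remove_nodes_from(isolated)
        degree = dict(g.degree(weight="weight"))
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=data["weight"] / np.sqrt(degree[u] * degree[v]))
    return out


def _column_stochastic(g: nx.Graph, nodes: list) -> np.ndarray:
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    colsum = w.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return w / colsum


def rwr(
    g: nx.Graph,
    seeds: dict,
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> pd.Series:
    """Random walk with restart on a (normalized) weighted graph.

    ``seeds`` maps node -> weight; weights are normalized to sum 1. The score
    vector is the fixed point of p = restart*s + (1-restart)*W p with W the
    column-stochastic transition matrix, iterated until the L1 change is
    below ``tol``. restart = 1 returns the seed distribution exactly.
    """
    if not seeds:
        raise ConfigurationError("empty seed set")
    if not 0 < restart <= 1:
        raise ConfigurationError("restart must be in (0, 1]")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    s = np.zeros(len(nodes))
    for node, weight in seeds.items():
        s[index[node]] = weight
    if s.sum() <= 0:
        raise ConfigurationError("seed weights must be positive")
    s = s / s.sum()
    if restart == 1.0:
        return pd.Series(s, index=nodes)
    w = _column_stochastic(g, nodes)
    p = s.copy()
    for _ in range(max_iter):
        nxt = restart * s + (1.0 - restart) * (w @ p)
        delta = np.abs(nxt - p).sum()
        p = nxt
        if delta < tol:
            return pd.Series(p, index=nodes)
    raise ConvergenceError(f"RWR did not converge; residual {delta:.3e}")


def rwr_solve(g: nx.Graph, seeds: dict, restart: float = 0.5) -> pd.Series:
    """Direct linear solve of the RWR fixed point (independent oracle):
    p = restart * (I - (1-restart) W)^-1 s."""
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    s = np.zeros(len(nodes))
    for node, weight in seeds.items():
        s[index[node]] = weight
    s = s / s.sum()
    w = _column_stochastic(g, nodes)
    p = restart * np.linalg.solve(np.eye(len(nodes)) - (1 - restart) * w, s)
    return pd.Series(p, index=nodes)


# --- null networks and empirical p-values ------------------------------------


def null_networks(
    g: nx.Graph,
    n: int,
    seed: int,
    weight_fn=None,
    swaps_per_edge: int = 10,
) -> list[nx.Graph]:
    """Degree-preserving randomizations of ``g`` (double edge swaps).

    ``weight_fn(u, v)`` recomputes the weight of each rewired edge (e.g. the
    Resnik similarity of the new endpoints); when None, the original edge
    weights are randomly permuted onto the new edges. Graphs too small to
    rewire come back as flagged copies.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    n_edges = g.number_of_edges()
    for _ in range(n):
        null = g.copy()
        try:
            nx.double_edge_swap(
                null,
                nswap=swaps_per_edge * n_edges,
                max_tries=100 * swaps_per_edge * n_edges,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXError:
            null.graph["rewire_failed"] = True
        if weight_fn is not None:
            for u, v in null.edges:
                null.edges[u, v]["weight"] = weight_fn(u, v)
        else:
            weights = [g.edges[e]["weight"] for e in g.edges]
            perm = rng.permutation(len(weights))
            for k, (u, v) in enumerate(null.edges):
                null.edges[u, v]["weight"] = weights[perm[k]]
        out.append(null)
    return out


def empirical_pvalues(
    real: dict[str, pd.Series],
    nulls: dict[str, np.ndarray],
    alpha: float = 0.05,
    plus_one: bool = False,
) -> tuple[pd.DataFrame, list]:
    """Per-node empirical p-values against null-network scores.

    ``real[partition]`` is the RWR score vector on the real network;
    ``nulls[partition]`` an (n_nulls x n_nodes) array of null scores in the
    same node order. p = #{null > real} / n_nulls (strict exceedance; the
    (r+1)/(n+1) convention is available via ``plus_one``). A node is retained
    when p < alpha in at least one partition.
    """
    parts = list(real)
    index = real[parts[0]].index
    p = pd.DataFrame(index=index, columns=parts, dtype=float)
    for part in parts:
        null = np.asarray(nulls[part], dtype=float)
        exceed = (null > real[part].to_numpy()[None, :]).sum(axis=0)
        if plus_one:
            p[part] = (exceed + 1) / (null.shape[0] + 1)
        else:
            p[part] = exceed / null.shape[0]
    retained = list(index[(p < alpha).any(axis=1)])
    return p, retained


# --- ego decomposition -------------------------------------------------------


@dataclass
class EgoNetwork:
    """A <=2-step neighborhood of a seed node, similarity-filtered."""

    ego: str
    graph: nx.Graph  # Eq.-3 reweighted and Laplacian-renormalized
    members: list  # nodes, ego included
    ring1: set  # nodes at distance 1
    ring2: set  # nodes at distance 2


def resnik_stats(dag: OntologyDAG, egos: list, nodes: list) -> pd.DataFrame:
    """Mean and sd of Resnik similarity of each ego against all nodes."""
    rows = {}
    for ego in egos:
        sims = np.array([dag.resnik(ego, n) for n in nodes if n != ego])
        rows[ego] = {"mean": sims.mean(), "sd": sims.std(ddof=1)}
    return pd.DataFrame(rows).T


def ego_decompose(
    sub: nx.Graph,
    egos: list,
    dag: OntologyDAG,
    stats_table: pd.DataFrame,
    z_threshold: float = 1.28,
    min_size: int = 5,
) -> list[EgoNetwork]:
    """Extract and filter ego networks from the significant subnetwork.

    For each ego: candidate members are nodes within 2 steps; a member j is
    kept when z = (Resnik(ego, j) - mean_ego) / sd_ego > ``z_threshold`` (the
    ego-specific mean/sd come from ``stats_table``, precomputed against the
    whole network). Ego networks with fewer than ``min_size`` nodes are
    discarded. Surviving edges are reweighted: edges touching the ego or
    crossing between rings get Resnik(ego, far node); within-ring edges get
    the mean of the two Resnik values. The result is Laplacian-renormalized.
    """
    out = []
    for ego in egos:
        if ego not in sub:
            continue
        mu, sd = stats_table.at[ego, "mean"], stats_table.at[ego, "sd"]
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"ego {ego!r} has zero Resnik sd; skipped")
            continue
        dist = nx.single_source_shortest_path_length(sub, ego, cutoff=2)
        ring1 = {n for n, d in dist.items() if d == 1}
        ring2 = {n for n, d in dist.items() if d == 2}
        keep = {
            n
            for n in ring1 | ring2
            if (dag.resnik(ego, n) - mu) / sd > z_threshold
        }
        members = [ego] + sorted(keep)
        if len(members) < min_size:
            continue
        ring1 &= keep
        ring2 &= keep
        eg = nx.Graph(sub.subgraph(members).copy())
        for u, v in eg.edges:
            if u == ego or v == ego:
                far = v if u == ego else u
                w = dag.resnik(ego, far)
            elif (u in ring1 and v in ring2) or (u in ring2 and v in ring1):
                far = v if u in ring1 else u  # the non-ring-1 endpoint
                w = dag.resnik(ego, far)
            else:  # within ring 1 or within ring 2
                w = 0.5 * (dag.resnik(ego, u) + dag.resnik(ego, v))
            eg.edges[u, v]["weight"] = w
        eg.remove_edges_from([(u, v) for u, v, d in eg.edges(data=True) if d["weight"] <= 0])
        degree = dict(eg.degree(weight="weight"))
        eg.remove_nodes_from([n for n, d in degree.items() if d <= 0 and n != ego])
        if eg.number_of_nodes() < min_size or ego not in eg:
            continue
        eg = laplacian_normalize(eg)
        out.append(
            EgoNetwork(
                ego=ego,
                graph=eg,
                members=list(eg.nodes),
                ring1=ring1 & set(eg.nodes),
                ring2=ring2 & set(eg.nodes),
            )
        )
    return out


def ego_distances(
    ego_net: EgoNetwork,
    dag: OntologyDAG,
    restart: float = 0.5,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Topological and functional distances of every member to the ego.

    topological = 1000 log2(1 - JSD(RWR_node, RWR_ego)) with single-node
    seeds and the Jensen-Shannon *distance* (base-2); functional =
    1000 log2(Resnik(ego, node)). Arguments of the logs are floored at
    2^-52 so the distances are finite.
    """
    g = ego_net.graph
    p_ego = rwr(g, {ego_net.ego: 1.0}, restart, tol).to_numpy()
    rows = []
    for node in ego_net.members:
        p_node = rwr(g, {node: 1.0}, restart, tol).to_numpy()
        jsd = float(jensenshannon(p_node, p_ego, base=2))
        if not np.isfinite(jsd):
            jsd = 0.0  # identical distributions up to rounding
        topo = 1000.0 * np.log2(max(1.0 - jsd, LOG_FLOOR))
        res = dag.resnik(ego_net.ego, node) if node != ego_net.ego else max(
            (dag.ic.get(t, 0.0) for t in dag.annotations.get(ego_net.ego, ())),
            default=0.0,
        )
        func = 1000.0 * np.log2(max(res, LOG_FLOOR))
        rows.append({"node": node, "topological": topo, "functional": func})
    return pd.DataFrame(rows).set_index("node")


def kde_filter(
    distances: pd.DataFrame, band: tuple[float, float] = (0.7, 1.0)
) -> list:
    """Members whose max-normalized Gaussian-KDE density (Silverman
    bandwidth) lies within ``band`` on both the topological and the
    functional axis. A zero-variance axis places every member at the mode,
    retaining all on that axis."""
    lo, hi = band
    keep = np.ones(len(distances), dtype=bool)
    for col in ("topological", "functional"):
        x = distances[col].to_numpy(dtype=float)
        if len(x) < 2 or np.ptp(x) == 0:
            continue
        kde = stats.gaussian_kde(x, bw_method="silverman")
        dens = kde(x)
        norm = dens / dens.max()
        keep &= (norm >= lo) & (norm <= hi)
    return list(distances.index[keep])


# --- enrichment and consensus -------------------------------------------------


def term_enrichment(
    members: set,
    dag: OntologyDAG,
    background: set,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ontology terms in ``members``.

    ``background`` is the annotation universe (members must be a subset).
    When the DAG carries namespaces, ``namespace`` restricts the tested terms.
    BH-adjusted p-values across terms.
    """
    members = set(members) & set(dag.annotations)
    background = set(background) & set(dag.annotations)
    if not members <= background:
        raise ConfigurationError("members must be a subset of the background")
    if not members:
        return pd.DataFrame(columns=["term", "k", "n", "p", "p_adj"]).set_index("term")
    m_total = len(background)
    n_sel = len(members)
    term_bg: dict[str, int] = {}
    term_hit: dict[str, int] = {}
    for gene in background:
        for t in dag.annotations[gene]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in members:
                term_hit[t] = term_hit.get(t, 0) + 1
    rows = []
    for term, n_bg in sorted(term_bg.items()):
        if namespace and dag.namespace.get(term) != namespace:
            continue
        k = term_hit.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, m_total, n_bg, n_sel))
        rows.append({"term": term, "k": k, "n": n_bg, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")


def consensus_terms(
    enrichments: dict[str, pd.DataFrame],
    min_networks: int = 2,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Terms significant in at least ``min_networks`` of the networks.

    ``enrichments`` maps network label (e.g. ED-Vtl, Dev-Vsp) to a term
    enrichment table. Returns a heatmap-ready matrix of -log10 p per network
    plus the count of supporting networks, sorted by support then best p.
    """
    col = "p_adj" if use_adjusted else "p"
    all_terms = sorted(set().union(*(e.index for e in enrichments.values())))
    mat = pd.DataFrame(index=all_terms, columns=list(enrichments), dtype=float)
    sig = pd.DataFrame(False, index=all_terms, columns=list(enrichments))
    for net, table in enrichments.items():
        mat.loc[table.index, net] = -np.log10(table[col].clip(lower=1e-300))
        sig.loc[table.index, net] = table[col] < alpha
    support = sig.sum(axis=1)
    out = mat[support >= min_networks].copy()
    out["n_networks"] = support[support >= min_networks]
    out["best"] = out[list(enrichments)].max(axis=1)
    out = out.sort_values(["n_networks", "best"], ascending=False)
    return out.drop(columns="best")


# --- seed construction --------------------------------------------------------


def build_seed_weights(
    scores: pd.Series,
    mode: str = "ed",
    site_to_host: pd.Series | None = None,
    max_weight: float = 1e6,
) -> pd.Series:
    """Seed weights = reciprocal of |score| (ED score or linear-model
    deviation).

    Phosphosite scores are collapsed to host proteins by the median before
    the reciprocal. In deviation mode only entities within the interquartile
    range of the score distribution are seeded. Zero scores are capped at
    ``max_weight``.
    """
    s = scores.dropna()
    if mode == "dev":
        q1, q3 = np.percentile(s.to_numpy(), [25, 75])
        s = s[(s >= q1) & (s <= q3)]
    elif mode != "ed":
        raise ConfigurationError(f"unknown seed mode {mode!r}")
    if site_to_host is not None:
        s = s.groupby(site_to_host.reindex(s.index)).median()
    weights = 1.0 / s.abs()
    weights[~np.isfinite(weights)] = max_weight
    return weights.clip(upper=max_weight)


def partition_seed_sets(
    weights: pd.Series, partition: dict
) -> dict[str, dict]:
    """Split seed weights by node partition and normalize within each."""
    out = {}
    for part in PARTITIONS:
        nodes = [n for n in weights.index if partition.get(n) == part]
        if not nodes:
            continue
        w = weights.loc[nodes]
        out[part] = (w / w.sum()).to_dict()
    return out


# --- end-to-end convenience ---------------------------------------------------


def diffusion_pipeline(
    graph: nx.Graph,
    dag: OntologyDAG,
    seed_weights: pd.Series,
    restart: float = 0.5,
    n_nulls: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    weight_fn=None,
    namespace: str | None = None,
    tol: float = 1e-10,
) -> dict:
    """One full network-diffusion run for a single seeded score set.

    Seeds are partitioned by the node ``partition`` attribute; RWR runs per
    partition on the real and on ``n_nulls`` degree-preserving null networks;
    nodes with empirical p < alpha in >= 1 partition form the significant
    subnetwork, which is ego-decomposed, distance-filtered and tested for
    ontology-term enrichment. Returns a dict with the p-value table, retained
    nodes, ego networks, filtered member union, and the enrichment table.
    """
    partition = nx.get_node_attributes(graph, "partition")
    seed_sets = partition_seed_sets(seed_weights, partition)
    if not seed_sets:
        raise ConfigurationError("no seeds map onto the network")
    norm = laplacian_normalize(graph)
    real = {p: rwr(norm, s, restart, tol) for p, s in seed_sets.items()}
    nodes = list(norm.nodes)
    nulls = {p: np.empty((n_nulls, len(nodes))) for p in seed_sets}
    for i, null in enumerate(null_networks(graph, n_nulls, seed, weight_fn)):
        null_norm = laplacian_normalize(null)
        for p, s in seed_sets.items():
            nulls[p][i] = rwr(null_norm, s, restart, tol).reindex(nodes).to_numpy()
    real = {p: v.reindex(nodes) for p, v in real.items()}
    pvals, retained = empirical_pvalues(real, nulls, alpha)
    sub = graph.subgraph(retained).copy()
    egos = [e for e in seed_weights.index if e in sub]
    stats_table = resnik_stats(dag, egos, list(graph.nodes))
    ego_nets = ego_decompose(sub, egos, dag, stats_table)
    selected: set = set()
    for en in ego_nets:
        dists = ego_distances(en, dag, restart, tol)
        selected |= set(kde_filter(dists))
    enrichment = term_enrichment(selected, dag, set(graph.nodes), namespace)
    return {
        "pvalues": pvals,
        "retained": retained,
        "ego_networks": ego_nets,
        "selected": selected,
        "enrichment": enrichment,
    }
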
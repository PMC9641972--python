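"""Spearman co-occurrence networks and their topology.

The meta-community network is built on the most abundant taxa (top 500 by
summed relative abundance by default): Spearman rank correlations with
midranks over all unordered taxon pairs, two-sided p-values from the
t-approximation with n−2 degrees of freedom, Benjamini–Hochberg FDR
adjustment over all tested pairs, and an edge kept when |r| exceeds the
correlation threshold and the adjusted p falls below the FDR threshold
(defaults |r| > 0.7, q < 0.01).  Edge sign is stored as an attribute;
topology is computed on the unsigned simple graph.  Habitat subnetworks
are induced subgraphs on the taxa observed in that habitat's samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_data import OtuTable, to_relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float
    average_path_length: float
    modularity: float
    graph_density: float
    network_diameter: float
    betweenness_centralization: float
    degree_centralization: float
    positive_edge_fraction: float


def select_top_taxa(table: OtuTable, k: int = 500) -> OtuTable:
    """Keep the k taxa with the largest summed relative abundance.

    Ties at the cutoff break lexicographically by taxon id.  Asking for
    more taxa than exist keeps them all with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > table.n_taxa:
        logger.warning(
            "select_top_taxa: k=%d exceeds %d available taxa; keeping all",
            k, table.n_taxa,
        )
        k = table.n_taxa
    totals = to_relative_abundance(table).sum(axis=1)
    order = sorted(range(table.n_taxa), key=lambda i: (-totals[i], table.taxa_ids[i]))
    keep = sorted(order[:k], key=lambda i: table.taxa_ids[i])
    return table.subset(taxa=[table.taxa_ids[i] for i in keep])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def spearman_edges(
    table: OtuTable,
    r_threshold: float = 0.7,
    q_threshold: float = 0.01,
) -> nx.Graph:
    """Build the co-occurrence graph from all pairwise Spearman correlations.

    Needs at least 4 samples for rank correlation to carry information.
    Taxa constant across samples have undefined correlations; their pairs
    are skipped with a warning.  The returned graph holds only nodes with
    at least one retained edge; edges carry ``r``, ``q`` and ``sign``.
    """
    if table.n_samples < 4:
        raise ValueError("Spearman network needs at least 4 samples")
    X = to_relative_abundance(table).T  # samples x taxa
    variable = np.ptp(X, axis=0) > 0
    if not variable.all():
        skipped = [t for t, v in zip(table.taxa_ids, variable) if not v]
        logger.warning(
            "spearman_edges: skipping %d constant taxa (undefined r): %s%s",
            len(skipped), ", ".join(skipped[:5]),
            "..." if len(skipped) > 5 else "",
        )
    ids = [t for t, v in zip(table.taxa_ids, variable) if v]
    rho, pval = stats.spearmanr(X[:, variable])
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    iu = np.triu_indices(len(ids), k=1)
    r_flat = rho[iu]
    q_flat = bh_fdr(pval[iu])
    keep = (np.abs(r_flat) > r_threshold) & (q_flat < q_threshold)
    G = nx.Graph()
    for a, b, r, q in zip(iu[0][keep], iu[1][keep], r_flat[keep], q_flat[keep]):
        G.add_edge(
            ids[a], ids[b], r=float(r), q=float(q),
            sign=1 if r > 0 else -1,
        )
    return G


def positive_edge_fraction(G: nx.Graph) -> float:
    if G.number_of_edges() == 0:
        return np.nan
    signs = [d.get("sign", 1) for _, _, d in G.edges(data=True)]
    return float(np.mean([s > 0 for s in signs]))


def detect_modules(G: nx.Graph, seed: int = 0) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization; modules labelled 1..k by size.

    The greedy agglomeration is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic stages.  An edgeless graph
    places every node in its own module with Q = 0.
    """
    if G.number_of_edges() == 0:
        return {n: i + 1 for i, n in enumerate(sorted(G.nodes()))}, 0.0
    communities = nx.community.greedy_modularity_communities(G)
    q = nx.community.modularity(G, communities)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = {}
    for i, comm in enumerate(ordered, start=1):
        for node in comm:
            labels[node] = i
    return labels, float(q)


def _freeman_centralization(values: np.ndarray, denom: float) -> float:
    if denom <= 0:
        return np.nan
    return float((values.max() - values).sum() / denom)


def network_topology(G: nx.Graph, seed: int = 0) -> NetworkTopology:
    """Network-level topology summary.

    Average path length and diameter are computed on the largest connected
    component; the clustering coefficient is the mean local transitivity
    over nodes of degree >= 2; centralizations follow Freeman (dispersion
    relative to the star-graph maximum, attaining 1 on stars and 0 on
    vertex-transitive graphs).
    """
    n = G.number_of_nodes()
    e = G.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, *([np.nan] * 9))
    degrees = np.array([d for _, d in G.degree()], float)
    avg_degree = 2 * e / n
    density = nx.density(G)
    clust = nx.clustering(G)
    eligible = [c for node, c in clust.items() if G.degree(node) >= 2]
    clustering = float(np.mean(eligible)) if eligible else np.nan
    if n > 1:
        comp = max(nx.connected_components(G), key=len)
        H = G.subgraph(comp)
        if H.number_of_nodes() > 1:
            apl = float(nx.average_shortest_path_length(H))
            diam = float(nx.diameter(H))
        else:
            apl = diam = np.nan
    else:
        apl = diam = np.nan
    _, q = detect_modules(G, seed=seed)
    deg_centralization = _freeman_centralization(degrees, (n - 1) * (n - 2))
    btw = np.array(list(nx.betweenness_centrality(G, normalized=True).values()))
    btw_centralization = _freeman_centralization(btw, n - 1)
    return NetworkTopology(
        n_nodes=n, n_edges=e, average_degree=float(avg_degree),
        clustering_coefficient=clustering, average_path_length=apl,
        modularity=q, graph_density=float(density), network_diameter=diam,
        betweenness_centralization=btw_centralization,
        degree_centralization=deg_centralization,
        positive_edge_fraction=positive_edge_fraction(G),
    )


def node_topology(G: nx.Graph) -> pd.DataFrame:
    """Per-node degree, local transitivity, betweenness, and closeness.

    Transitivity is undefined (NaN) for nodes of degree < 2.  Closeness is
    computed within each node's connected component; isolated nodes get 0.
    """
    if G.number_of_nodes() < 2:
        raise ValueError("node topology needs at least 2 nodes")
    clust = nx.clustering(G)
    btw = nx.betweenness_centrality(G, normalized=True)
    close = nx.closeness_centrality(G, wf_improved=False)
    rows = []
    for node in G.nodes():
        deg = G.degree(node)
        rows.append(
            dict(
                node=node, degree=deg,
                transitivity=clust[node] if deg >= 2 else np.nan,
                betweenness=btw[node],
                closeness=close[node] if deg > 0 else 0.0,
            )
        )
    return pd.DataFrame(rows).set_index("node")


def extract_subnetwork(
    G: nx.Graph, table: OtuTable, group_samples: list[str]
) -> nx.Graph:
    """Induced subgraph on the taxa present in a habitat's samples.

    Edges are inherited from the meta-community network; correlations are
    not recomputed.
    """
    if not group_samples:
        raise ValueError("group has no samples")
    sub = table.subset(samples=list(group_samples))
    present = {
        t for t, total in zip(sub.taxa_ids, sub.counts.sum(axis=1)) if total > 0
    }
    nodes = [n for n in G.nodes() if n in present]
    if not nodes:
        logger.warning("extract_subnetwork: no group taxa present in network")
    return G.subgraph(nodes).copy()
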
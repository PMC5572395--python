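"""Co-expression clusters, key-cluster selection, and the cluster graph.

Communities are found with the random-walk (walktrap) agglomeration of
Pons & Latapy as implemented in igraph, cut at maximum modularity.  Clusters
are summarized by the mean local clustering coefficient of their members on
the intra-cluster subgraph, the top half of clusters by that coefficient are
flagged "key", and a coarse cluster-level graph links cluster pairs whose
observed inter-cluster edge count O_AB is at least twice the
configuration-model expectation E_AB = sum k_a * k_b / (2N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .coexnet import CoexpressionNetwork

__all__ = [
    "CommunityPartition",
    "ClusterGraph",
    "detect_communities",
    "clustering_coefficient",
    "select_key_clusters",
    "build_cluster_graph",
    "hypergeometric_enrichment",
]


@dataclass
class CommunityPartition:
    """Disjoint gene -> cluster assignment covering all network nodes."""

    membership: dict[str, int]
    coefficients: dict[int, float] = field(default_factory=dict)
    key_clusters: set[int] = field(default_factory=set)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.membership.values()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.membership.items() if c == cluster)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.membership.values():
            out[c] = out.get(c, 0) + 1
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (g, c, self.coefficients.get(c, float("nan")), c in self.key_clusters)
            for g, c in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "cluster", "coefficient", "is_key"])


@dataclass
class ClusterGraph:
    """Cluster-pair table with observed/expected inter-cluster edge counts."""

    table: pd.DataFrame  # columns: cluster_a, cluster_b, observed, expected, edge
    within_edges: dict[int, int]
    n_edges: int
    factor: float

    def edge_list(self) -> list[tuple[int, int]]:
        sub = self.table[self.table["edge"]]
        return list(zip(sub["cluster_a"], sub["cluster_b"]))


def _to_igraph(network: CoexpressionNetwork) -> tuple[ig.Graph, list[str]]:
    nodes = network.nodes  # sorted, deterministic
    index = {g: i for i, g in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in network.edge_pairs()]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.simplify()
    return g, nodes


def detect_communities(network: CoexpressionNetwork, steps: int = 4) -> CommunityPartition:
    """Random-walk community detection, cut at maximum modularity.

    ``steps`` is the random-walk length of the agglomeration criterion.
    Isolated nodes become singleton clusters.  Cluster ids are relabelled
    0..K-1 in order of each cluster's lexicographically smallest member so the
    labelling does not depend on igraph internals.
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    g, nodes = _to_igraph(network)
    dendro = g.community_walktrap(steps=steps)
    clustering = dendro.as_clustering()
    raw = clustering.membership
    # deterministic relabelling by smallest member gene id
    first_member: dict[int, str] = {}
    for gene, c in zip(nodes, raw):
        if c not in first_member or gene < first_member[c]:
            first_member[c] = gene
    relabel = {
        c: new for new, c in enumerate(sorted(first_member, key=first_member.get))
    }
    membership = {gene: relabel[c] for gene, c in zip(nodes, raw)}
    return CommunityPartition(membership=membership)


def clustering_coefficient(
    network: CoexpressionNetwork,
    partition: CommunityPartition,
    induced: bool = True,
) -> dict[int, float]:
    """Mean local clustering coefficient of each cluster's members.

    By default each coefficient is computed on the subgraph induced by the
    cluster's own members; with ``induced=False`` the local coefficients come
    from the full network.  Nodes with degree < 2 contribute 0.  The result is
    stored on the partition and returned.
    """
    import networkx as nx

    nxg = network.to_networkx()
    missing = [g for g in nxg.nodes if g not in partition.membership]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    coefs: dict[int, float] = {}
    if not induced:
        local = nx.clustering(nxg)
    for c in partition.cluster_ids:
        members = partition.members(c)
        present = [m for m in members if m in nxg]
        if not present:
            coefs[c] = 0.0
            continue
        if induced:
            sub = nxg.subgraph(present)
            local_c = nx.clustering(sub)
            vals = [local_c[m] for m in present]
        else:
            vals = [local[m] for m in present]
        coefs[c] = float(np.mean(vals)) if vals else 0.0
    partition.coefficients = coefs
    return coefs


def select_key_clusters(partition: CommunityPartition) -> CommunityPartition:
    """Flag the top ``ceil(K/2)`` clusters by clustering coefficient as key.

    Ties are broken by size (descending) then cluster id.  Requires the
    coefficients to have been computed first.
    """
    if partition.n_clusters < 1:
        raise ValueError("no clusters")
    if not partition.coefficients:
        raise ValueError("compute clustering coefficients before key selection")
    sizes = partition.sizes()
    order = sorted(
        partition.cluster_ids,
        key=lambda c: (-partition.coefficients[c], -sizes[c], c),
    )
    n_key = math.ceil(partition.n_clusters / 2)
    partition.key_clusters = set(order[:n_key])
    return partition


def build_cluster_graph(
    network: CoexpressionNetwork,
    partition: CommunityPartition,
    factor: float = 2.0,
) -> ClusterGraph:
    """Link cluster pairs whose observed inter-cluster edges beat expectation.

    E_AB = (sum of full-network degrees in A) * (sum in B) / (2N), N = total
    edge count; the pair is linked iff O_AB >= factor * E_AB and O_AB > 0.
    """
    n_edges = network.n_edges
    if n_edges == 0:
        raise ValueError("network has no edges")
    membership = partition.membership
    missing = [g for g in network.nodes if g not in membership]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")

    degree: dict[str, int] = {}
    observed: dict[tuple[int, int], int] = {}
    within: dict[int, int] = {c: 0 for c in partition.cluster_ids}
    for a, b in network.edge_pairs():
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
        ca, cb = membership[a], membership[b]
        if ca == cb:
            within[ca] += 1
        else:
            key = (min(ca, cb), max(ca, cb))
            observed[key] = observed.get(key, 0) + 1

    deg_sum: dict[int, float] = {c: 0.0 for c in partition.cluster_ids}
    for g, d in degree.items():
        deg_sum[membership[g]] += d

    ids = partition.cluster_ids
    rows = []
    for i, ca in enumerate(ids):
        for cb in ids[i + 1 :]:
            o = observed.get((ca, cb), 0)
            e = deg_sum[ca] * deg_sum[cb] / (2.0 * n_edges)
            rows.append((ca, cb, o, e, o > 0 and o >= factor * e))
    table = pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "observed", "expected", "edge"]
    )
    return ClusterGraph(table=table, within_edges=within, n_edges=n_edges, factor=factor)


def hypergeometric_enrichment(
    query,
    term_sets: dict[str, set],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set in each term.

    For overlap k between the query (size n) and a term (size K) inside a
    universe of size N_u, p = P[X >= k] with X ~ Hypergeometric(N_u, K, n).
    Terms are intersected with the universe first; results are sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    n_u = len(universe)
    n_q = len(query)
    for term, genes in term_sets.items():
        term_genes = set(genes) & universe
        k_term = len(term_genes)
        k_overlap = len(term_genes & query)
        p = float(hypergeom.sf(k_overlap - 1, n_u, k_term, n_q))
        rows.append((term, n_u, k_term, n_q, k_overlap, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "universe", "term_size", "query_size", "overlap", "p"]
    )
    out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
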
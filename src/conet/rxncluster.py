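"""Metabolic reaction co-expression clusters and their differential scoring.

Gene co-expression is projected onto metabolic reactions through the
reaction->enzyme map: the co-expression of two reactions is the maximum
Pearson r over their enzyme gene pairs.  Reactions are clustered by average-
linkage hierarchical clustering on 1 - r_max; per-cluster mean co-expression
is compared between conditions after Fisher's variance-stabilizing Z
transform, and the clusters whose co-expression drops most (top 1% of the
Fisher-Z difference) are called condition-specific (reference vs another
tissue) or disease-deregulated (reference vs tumor).  Clusters are further
annotated with TF-binding enrichment, enriched-TF importance (one-sided KS
against all TF scores), and metabolic subsystem enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .coexnet import CorrelationTable
from .commdetect import hypergeometric_enrichment
from .coreg import PhysicalNetwork

__all__ = [
    "ReactionEnzymeMap",
    "ReactionCoexpressionMatrix",
    "ReactionClustering",
    "reaction_coexpression_matrix",
    "cluster_reactions",
    "fisher_z",
    "differential_cluster_scores",
    "combine_deregulation_flags",
    "cluster_tf_enrichment",
    "select_highly_regulated_clusters",
    "subsystem_enrichment",
]


@dataclass
class ReactionEnzymeMap:
    """reaction id -> enzyme gene set, plus a subsystem label per reaction."""

    enzymes: dict[str, tuple[str, ...]]
    subsystem: dict[str, str]

    def __post_init__(self) -> None:
        for rxn, enz in self.enzymes.items():
            if not enz:
                raise ValueError(f"reaction {rxn} has no enzymes")
        for rxn in self.enzymes:
            if not self.subsystem.get(rxn):
                raise ValueError(f"reaction {rxn} has no subsystem label")

    @property
    def reactions(self) -> list[str]:
        return sorted(self.enzymes)

    @property
    def genes(self) -> list[str]:
        out = set()
        for enz in self.enzymes.values():
            out.update(enz)
        return sorted(out)


@dataclass
class ReactionCoexpressionMatrix:
    """Symmetric reaction-pair r_max matrix for one condition.

    ``r_max`` of a reaction pair is the maximum Pearson r over their enzyme
    gene pairs; reactions with no enzyme present in the correlation table are
    excluded and listed.
    """

    reactions: list[str]  # sorted, canonical order
    matrix: np.ndarray
    condition: str
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r: i for i, r in enumerate(self.reactions)}

    def r_max(self, rxn_a: str, rxn_b: str) -> float:
        return float(self.matrix[self._index[rxn_a], self._index[rxn_b]])


@dataclass
class ReactionClustering:
    """reaction -> cluster id (1..k) from the reference condition."""

    assignment: dict[str, int]
    k: int
    condition: str = ""
    linkage_method: str = "average"

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return sorted(r for r, c in self.assignment.items() if c == cluster)


def reaction_coexpression_matrix(
    rmap: ReactionEnzymeMap, table: CorrelationTable
) -> ReactionCoexpressionMatrix:
    """Project gene correlations onto reaction pairs by the max over enzymes.

    Reactions are processed in sorted-id order so the output is independent of
    the map's insertion order.  A reaction with an expressed enzyme has
    r_max(R, R) = 1 by the identity correlation.
    """
    usable = []
    excluded = []
    enzyme_idx: list[np.ndarray] = []
    for rxn in rmap.reactions:
        present = [g for g in rmap.enzymes[rxn] if g in table]
        if present:
            usable.append(rxn)
            enzyme_idx.append(
                np.array([table._index[g] for g in present], dtype=np.intp)
            )
        else:
            excluded.append(rxn)
    if len(usable) < 2:
        raise ValueError("fewer than 2 reactions with an expressed enzyme")
    n = len(usable)
    out = np.empty((n, n))
    corr = table.matrix
    for i in range(n):
        rows = corr[enzyme_idx[i]]  # (n_enz_i, n_genes)
        for j in range(i, n):
            out[i, j] = out[j, i] = rows[:, enzyme_idx[j]].max()
        out[i, i] = 1.0
    return ReactionCoexpressionMatrix(
        reactions=usable, matrix=out, condition=table.condition, excluded=excluded
    )


def cluster_reactions(
    matrix: ReactionCoexpressionMatrix,
    k: int = 100,
    method: str = "average",
) -> ReactionClustering:
    """Agglomerative clustering on distance 1 - r_max, cut to exactly k clusters.

    Average linkage by default (single/complete via ``method``).  The
    canonical sorted reaction order of the input matrix makes the result
    independent of how the reaction map was ordered.  Cluster ids are
    relabelled 1..k by each cluster's lexicographically smallest member.
    """
    n = len(matrix.reactions)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    dist = 1.0 - matrix.matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    first: dict[int, str] = {}
    for rxn, c in zip(matrix.reactions, raw):
        if c not in first or rxn < first[c]:
            first[c] = rxn
    relabel = {c: i + 1 for i, c in enumerate(sorted(first, key=first.get))}
    assignment = {rxn: relabel[c] for rxn, c in zip(matrix.reactions, raw)}
    return ReactionClustering(
        assignment=assignment,
        k=len(set(raw)),
        condition=matrix.condition,
        linkage_method=method,
    )


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r).

    r is clamped to +/-(1 - 1e-7) before the transform so perfectly
    correlated pairs map to a large finite z instead of infinity.  Accepts
    scalars or arrays; rejects |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1):
        raise ValueError("|r| must be <= 1")
    clamped = np.clip(arr, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(clamped)
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _cluster_mean_z(
    clustering: ReactionClustering, matrix: ReactionCoexpressionMatrix
) -> dict[int, float]:
    """Mean Fisher-Z over within-cluster reaction pairs, per cluster."""
    out: dict[int, float] = {}
    for c in clustering.cluster_ids:
        members = [r for r in clustering.members(c) if r in matrix._index]
        if len(members) < 2:
            continue
        idx = np.array([matrix._index[r] for r in members], dtype=np.intp)
        sub = matrix.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[c] = float(np.mean(fisher_z(sub[iu])))
    return out


def differential_cluster_scores(
    clustering: ReactionClustering,
    matrix_ref: ReactionCoexpressionMatrix,
    matrix_other: ReactionCoexpressionMatrix,
    q: float = 0.01,
) -> pd.DataFrame:
    """Per-cluster Fisher-Z co-expression difference, reference minus other.

    A positive delta means the cluster is more co-expressed in the reference
    condition — "specific" when the other condition is a tissue, "deregulated"
    when the other condition is the disease (loss of reference co-expression).
    The top ``ceil(q * k)`` clusters by delta are flagged; clusters with fewer
    than 2 mappable reactions in either condition have an undefined delta and
    are reported unflagged with NaN.
    """
    z_ref = _cluster_mean_z(clustering, matrix_ref)
    z_other = _cluster_mean_z(clustering, matrix_other)
    k = len(clustering.cluster_ids)
    rows = []
    for c in clustering.cluster_ids:
        zr = z_ref.get(c, np.nan)
        zo = z_other.get(c, np.nan)
        rows.append((c, zr, zo, zr - zo))
    out = pd.DataFrame(rows, columns=["cluster", "z_ref", "z_other", "delta"])
    n_flag = math.ceil(q * k)
    order = out.sort_values(
        ["delta", "cluster"], ascending=[False, True], kind="mergesort", na_position="last"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = ranks
    head = order.head(n_flag)
    flagged = set(head.loc[head["delta"].notna(), "cluster"])
    out["flagged"] = out["cluster"].isin(flagged)
    return out.sort_values("cluster").reset_index(drop=True)


def combine_deregulation_flags(
    tissue_tables: dict[str, pd.DataFrame],
    disease_table: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-reference condition-specific and disease-deregulated flags.

    A cluster flagged in the disease comparison that is also flagged in at
    least one tissue comparison is both condition-specific and deregulated in
    disease — the prime candidates for disease-driven loss of a
    tissue-specific program.
    """
    specific: set[int] = set()
    for tbl in tissue_tables.values():
        specific |= set(tbl.loc[tbl["flagged"], "cluster"])
    deregulated = set(disease_table.loc[disease_table["flagged"], "cluster"])
    clusters = sorted(
        set(disease_table["cluster"]).union(*[set(t["cluster"]) for t in tissue_tables.values()])
        if tissue_tables
        else set(disease_table["cluster"])
    )
    rows = [
        (
            c,
            c in specific,
            c in deregulated,
            c in specific and c in deregulated,
        )
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster", "condition_specific", "disease_deregulated", "both"],
    )


def cluster_tf_enrichment(
    clustering: ReactionClustering,
    rmap: ReactionEnzymeMap,
    phys: PhysicalNetwork,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each TF's binding in each cluster.

    The universe is the enzyme genes of all clustered reactions; each TF's
    term is its targets within that universe, and each cluster's query is its
    reactions' enzyme genes.
    """
    if phys.kind != "regulatory":
        raise ValueError("TF enrichment requires a regulatory network")
    universe: set[str] = set()
    cluster_genes: dict[int, set[str]] = {}
    for c in clustering.cluster_ids:
        genes: set[str] = set()
        for rxn in clustering.members(c):
            genes.update(rmap.enzymes.get(rxn, ()))
        cluster_genes[c] = genes
        universe |= genes
    if not universe:
        raise ValueError("no enzyme genes in the clustered reactions")
    term_sets = {
        tf: set(targets) & universe for tf, targets in phys.target_map().items()
    }
    term_sets = {tf: t for tf, t in term_sets.items() if t}
    frames = []
    for c in clustering.cluster_ids:
        res = hypergeometric_enrichment(
            cluster_genes[c], term_sets, universe, alpha=alpha
        )
        res.insert(0, "cluster", c)
        res = res.rename(columns={"term": "tf"})
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "tf", "universe", "term_size", "query_size", "overlap", "p", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def select_highly_regulated_clusters(
    enrichment: pd.DataFrame,
    importance: pd.DataFrame,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Clusters whose enriched TFs carry unusually high importance scores.

    For each cluster, the importance scores of its significantly enriched TFs
    are compared with the full TF score distribution by a one-sided
    two-sample KS test (alternative: enriched scores stochastically greater).
    A cluster is selected iff p < alpha and at least 2 enriched TFs have
    scores; enriched TFs missing from the importance table are skipped.
    """
    score_by_tf = dict(zip(importance["tf"], importance["score"]))
    all_scores = importance["score"].to_numpy(dtype=float)
    rows = []
    for c, sub in enrichment.groupby("cluster"):
        enriched = sorted(sub.loc[sub["significant"], "tf"])
        scored = [score_by_tf[tf] for tf in enriched if tf in score_by_tf]
        if len(scored) < 2:
            rows.append((c, len(enriched), len(scored), np.nan, False))
            continue
        # alternative="less": the enriched-score ECDF lies below the overall
        # ECDF, i.e. enriched scores are stochastically greater
        stat = ks_2samp(np.asarray(scored), all_scores, alternative="less")
        rows.append((c, len(enriched), len(scored), float(stat.pvalue), stat.pvalue < alpha))
    return pd.DataFrame(
        rows, columns=["cluster", "n_enriched", "n_scored", "ks_p", "selected"]
    )


def subsystem_enrichment(
    clustering: ReactionClustering,
    rmap: ReactionEnzymeMap,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric enrichment of metabolic subsystems within each cluster.

    The universe is the clustered reactions; each subsystem's term is its
    reactions, each cluster's query is its member reactions.
    """
    universe = [r for r in clustering.assignment]
    term_sets: dict[str, set[str]] = {}
    for rxn in universe:
        term_sets.setdefault(rmap.subsystem[rxn], set()).add(rxn)
    frames = []
    for c in clustering.cluster_ids:
        res = hypergeometric_enrichment(
            clustering.members(c), term_sets, universe, alpha=alpha
        )
        res.insert(0, "cluster", c)
        res = res.rename(columns={"term": "subsystem"})
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
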
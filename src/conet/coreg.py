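"""Overlay of physical networks (regulatory, protein-protein) on co-expression.

Physical edges — TF->target regulation or undirected protein interaction —
are scored by the mean Pearson r of their gene pairs and compared with
permutation nulls that redraw edge endpoints uniformly from the actual
network's node set.  Pairs of genes sharing regulators ("co-regulated" pairs)
are counted and stratified, mean co-expression is traced as a function of the
co-regulator count, and individual regulators whose linked pairs are
unusually co-expressed are selected with a two-sample KS test plus a mean-r
floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .coexnet import CorrelationTable

__all__ = [
    "PhysicalNetwork",
    "CoregulationProfile",
    "PermutationNullSummary",
    "mean_edge_coexpression",
    "permutation_null",
    "coregulation_counts",
    "coexpression_by_coregulator_count",
    "select_coexpressed_regulators",
]


@dataclass
class PhysicalNetwork:
    """Edge list of a regulatory (directed TF->target) or PPI network."""

    kind: str  # "regulatory" | "ppi"
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("regulatory", "ppi"):
            raise ValueError("kind must be 'regulatory' or 'ppi'")
        seen = set()
        dedup = []
        for a, b in self.edges:
            if a == b:
                continue
            key = (a, b) if self.kind == "regulatory" else (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                dedup.append(key)
        self.edges = dedup

    @property
    def nodes(self) -> list[str]:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    @property
    def regulators(self) -> list[str]:
        """Sources of a regulatory network, or all proteins of a PPIN."""
        if self.kind == "regulatory":
            return sorted({a for a, _ in self.edges})
        return self.nodes

    def targets_of(self, regulator: str) -> set[str]:
        if self.kind == "regulatory":
            return {b for a, b in self.edges if a == regulator}
        out = set()
        for a, b in self.edges:
            if a == regulator:
                out.add(b)
            elif b == regulator:
                out.add(a)
        return out

    def target_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        if self.kind == "regulatory":
            for a, b in self.edges:
                out.setdefault(a, set()).add(b)
        else:
            for a, b in self.edges:
                out.setdefault(a, set()).add(b)
                out.setdefault(b, set()).add(a)
        return out


@dataclass
class CoregulationProfile:
    """Shared-regulator counts for unordered gene pairs.

    ``counts`` holds only pairs with at least one shared regulator; the zero
    stratum is every other unordered pair over ``universe``.
    """

    kind: str
    counts: dict[tuple[str, str], int]
    universe: list[str]

    @property
    def n_universe_pairs(self) -> int:
        n = len(self.universe)
        return n * (n - 1) // 2

    def top_stratum(self, q: float = 0.001) -> list[tuple[str, str]]:
        """Top ``ceil(q * n_coregulated_pairs)`` pairs by shared-regulator count."""
        if not self.counts:
            return []
        n_top = math.ceil(q * len(self.counts))
        order = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [pair for pair, _ in order[:n_top]]

    def zero_pairs(self) -> list[tuple[str, str]]:
        """Unordered universe pairs with no shared regulator."""
        nonzero = set(self.counts)
        return [
            (a, b)
            for a, b in combinations(sorted(self.universe), 2)
            if (a, b) not in nonzero
        ]


@dataclass
class PermutationNullSummary:
    """Observed mean edge r against an endpoint-resampling null."""

    observed: float
    null: np.ndarray
    seed: int | None = None
    collision_rate: float = 0.0
    coverage: float = 1.0

    @property
    def n_perm(self) -> int:
        return len(self.null)

    @property
    def p_value(self) -> float:
        """Add-one empirical upper-tail p: (1 + #{null >= obs}) / (1 + n_perm)."""
        return (1 + int(np.sum(self.null >= self.observed))) / (1 + self.n_perm)


def _mappable(edges, table: CorrelationTable):
    pairs = [(a, b) for a, b in edges if a in table and b in table and a != b]
    return pairs


def mean_edge_coexpression(edges, table: CorrelationTable) -> tuple[float, float]:
    """Mean Pearson r over edges mappable into the correlation table.

    Returns ``(mean_r, coverage)`` where coverage is the mappable fraction.
    """
    edges = list(edges)
    pairs = _mappable(edges, table)
    if not pairs:
        raise ValueError("no edge maps into the correlation table")
    mean_r = float(np.mean(table.lookup(pairs)))
    return mean_r, len(pairs) / len(edges)


def permutation_null(
    edges,
    table: CorrelationTable,
    n_perm: int = 1000,
    seed: int | None = None,
    nodes=None,
) -> PermutationNullSummary:
    """Endpoint-resampling null for the mean edge co-expression.

    Each permutation redraws both endpoints of every edge uniformly from the
    actual network's node set (restricted to genes present in the table),
    rejecting self-loops and duplicate pairs so the permuted edge count equals
    the observed one.  Collisions with original edges are allowed (pure
    resampling) and their rate is reported.
    """
    edges = list(edges)
    if nodes is None:
        nodes = sorted({g for e in edges for g in e})
    pool = [g for g in nodes if g in table]
    if len(pool) < 3:
        raise ValueError("node set too small to permute (need >= 3 genes in table)")
    n_edges = len(_mappable(edges, table))
    if n_edges == 0:
        raise ValueError("no edge maps into the correlation table")
    max_pairs = len(pool) * (len(pool) - 1) // 2
    if n_edges > max_pairs:
        raise ValueError("node set too small to place the edges without duplicates")

    observed, coverage = mean_edge_coexpression(edges, table)
    n_g = table.n_genes
    original_keys = set()
    for a, b in edges:
        if a in table and b in table:
            i, j = table._index[a], table._index[b]
            original_keys.add(min(i, j) * n_g + max(i, j))
    idx_pool = np.array([table._index[g] for g in pool], dtype=np.intp)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    m = table.matrix
    collision_hits = 0
    for t in range(n_perm):
        chosen_i = np.empty(n_edges, dtype=np.intp)
        chosen_j = np.empty(n_edges, dtype=np.intp)
        seen: set[tuple[int, int]] = set()
        filled = 0
        while filled < n_edges:
            need = n_edges - filled
            draw = rng.integers(0, len(pool), size=(int(need * 1.3) + 4, 2))
            for u, v in draw:
                if u == v:
                    continue
                key = (min(u, v), max(u, v))
                if key in seen:
                    continue
                seen.add(key)
                chosen_i[filled] = idx_pool[key[0]]
                chosen_j[filled] = idx_pool[key[1]]
                filled += 1
                if filled == n_edges:
                    break
        null[t] = m[chosen_i, chosen_j].mean()
        keys = np.minimum(chosen_i, chosen_j) * n_g + np.maximum(chosen_i, chosen_j)
        collision_hits += sum(1 for k in keys if int(k) in original_keys)
    collision_rate = collision_hits / (n_perm * n_edges)
    return PermutationNullSummary(
        observed=observed,
        null=null,
        seed=seed,
        collision_rate=collision_rate,
        coverage=coverage,
    )


def coregulation_counts(phys: PhysicalNetwork) -> CoregulationProfile:
    """Count shared regulators for every unordered gene pair.

    Regulatory network: the count for (g1, g2) is the number of TFs binding
    both.  PPIN: the number of shared interaction partners, excluding the two
    genes themselves.  Only pairs with a positive count are stored.
    """
    counts: dict[tuple[str, str], int] = {}
    if phys.kind == "regulatory":
        universe = sorted({b for _, b in phys.edges})
        for tf, targets in phys.target_map().items():
            for a, b in combinations(sorted(targets), 2):
                counts[(a, b)] = counts.get((a, b), 0) + 1
    else:
        universe = phys.nodes
        neighbors = phys.target_map()
        for p, nbrs in neighbors.items():
            for a, b in combinations(sorted(nbrs), 2):
                if p in (a, b):
                    continue
                counts[(a, b)] = counts.get((a, b), 0) + 1
    return CoregulationProfile(kind=phys.kind, counts=counts, universe=universe)


def coexpression_by_coregulator_count(
    profile: CoregulationProfile,
    table: CorrelationTable,
    thresholds,
) -> pd.DataFrame:
    """Mean pair co-expression as a function of the co-regulator count floor.

    For each threshold t the mean r is taken over mappable universe pairs
    whose shared-regulator count is >= t (t = 0 therefore covers every
    universe pair).  Thresholds with no qualifying mappable pair emit no row.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    rows = []
    for t in thresholds:
        if t <= 0:
            pairs = list(combinations(sorted(profile.universe), 2))
        else:
            pairs = [p for p, c in profile.counts.items() if c >= t]
        pairs = _mappable(pairs, table)
        if not pairs:
            continue
        rows.append((t, float(np.mean(table.lookup(pairs))), len(pairs)))
    return pd.DataFrame(rows, columns=["threshold", "mean_r", "n_pairs"])


def select_coexpressed_regulators(
    phys: PhysicalNetwork,
    table: CorrelationTable,
    alpha: float = 0.05,
    min_abs_mean: float = 0.1,
) -> pd.DataFrame:
    """Select regulators whose linked pairs are unusually co-expressed.

    For each TF (or protein) the r values of its regulator-target (or
    interaction) pairs are compared against all evaluated pair r values in the
    table with a two-sided two-sample KS test; the regulator is selected iff
    KS p < alpha and |mean r| > min_abs_mean.  Regulators with fewer than 3
    mappable pairs are skipped (reported with selected = NA semantics via the
    ``skipped`` column).
    """
    background = table.condensed()
    rows = []
    for reg in phys.regulators:
        linked = [(reg, t) for t in sorted(phys.targets_of(reg))]
        pairs = _mappable(linked, table)
        if len(pairs) < 3:
            rows.append((reg, len(pairs), np.nan, np.nan, False, True))
            continue
        r_vals = table.lookup(pairs)
        stat = ks_2samp(r_vals, background, alternative="two-sided")
        mean_r = float(np.mean(r_vals))
        selected = stat.pvalue < alpha and abs(mean_r) > min_abs_mean
        rows.append((reg, len(pairs), mean_r, float(stat.pvalue), selected, False))
    return pd.DataFrame(
        rows, columns=["regulator", "n_pairs", "mean_r", "ks_p", "selected", "skipped"]
    )
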
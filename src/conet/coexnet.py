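"""Per-condition co-expression networks.

The substrate of every downstream analysis is a genes x samples expression
matrix for one condition (a tissue or a tumor cohort).  This module converts
RPKM to TPM, drops the weakly expressed tail, computes all-pairs Pearson
correlations, and thresholds the pair list at a signed upper quantile to form
the co-expression network (CN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CorrelationTable",
    "CoexpressionNetwork",
    "rpkm_to_tpm",
    "filter_low_expression",
    "correlation_table",
    "build_network",
]


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (genes x samples) for one condition.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    condition : str
        Condition label (tissue or cohort name).
    unit : {"TPM", "RPKM"}
        Unit tag; correlations should be computed on TPM.
    """

    values: pd.DataFrame
    condition: str
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "RPKM"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationTable:
    """Symmetric all-pairs Pearson r for one condition.

    ``matrix[i, j]`` is the correlation between ``genes[i]`` and ``genes[j]``.
    Genes with zero variance across samples are excluded up front (a NaN row
    would poison the quantile cutoff) and recorded in ``dropped``.
    """

    genes: list[str]
    matrix: np.ndarray
    condition: str
    dropped: list[str] = field(default_factory=list)
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        """Number of evaluated unordered gene pairs."""
        g = self.n_genes
        return g * (g - 1) // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def r(self, gene_a: str, gene_b: str) -> float:
        return float(self.matrix[self._index[gene_a], self._index[gene_b]])

    def lookup(self, pairs) -> np.ndarray:
        """Vectorized r lookup for an iterable of (gene_a, gene_b) pairs."""
        idx = self._index
        ii = np.array([idx[a] for a, b in pairs], dtype=np.intp)
        jj = np.array([idx[b] for a, b in pairs], dtype=np.intp)
        return self.matrix[ii, jj]

    def condensed(self) -> np.ndarray:
        """Upper-triangle r values in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.matrix[iu]


@dataclass
class CoexpressionNetwork:
    """Thresholded co-expression network: the top ``q`` fraction of pairs.

    ``edges`` has columns (gene_a, gene_b, r), sorted by descending r with a
    deterministic lexicographic tie-break; ``cutoff`` is the smallest retained
    r value.
    """

    edges: pd.DataFrame
    cutoff: float
    quantile: float
    condition: str = ""
    absolute: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["gene_a"]) | set(self.edges["gene_b"]))

    def edge_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for a, b, r in self.edges.itertuples(index=False):
            g.add_edge(a, b, r=float(r))
        return g


def rpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale RPKM columns to TPM: TPM_gs = RPKM_gs / sum_g RPKM_gs * 1e6.

    Every output column sums to 1e6.  Rejects all-zero samples, naming the
    offending sample id.
    """
    if matrix.unit != "RPKM":
        raise ValueError("input unit tag must be RPKM")
    colsums = matrix.values.sum(axis=0)
    bad = colsums[colsums <= 0]
    if len(bad):
        raise ValueError(f"all-zero sample(s): {list(bad.index)}")
    tpm = matrix.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, condition=matrix.condition, unit="TPM")


def filter_low_expression(
    matrix: ExpressionMatrix, fraction: float = 1.0 / 3.0
) -> ExpressionMatrix:
    """Drop the ``floor(fraction * G)`` genes with the lowest mean expression.

    Ties on the mean are broken by gene id (lexicographically earlier genes
    are dropped first); the retained genes keep their original order.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_drop = math.floor(fraction * matrix.values.shape[0])
    if n_drop == 0:
        return matrix
    means = matrix.values.mean(axis=1)
    order = sorted(matrix.values.index, key=lambda g: (means[g], g))
    drop = set(order[:n_drop])
    keep = [g for g in matrix.values.index if g not in drop]
    if not keep:
        raise ValueError("filter would remove all genes")
    return ExpressionMatrix(
        values=matrix.values.loc[keep], condition=matrix.condition, unit=matrix.unit
    )


def correlation_table(
    matrix: ExpressionMatrix,
    log_transform: bool = False,
    pseudocount: float = 1.0,
) -> CorrelationTable:
    """Pearson r between all unordered pairs of genes.

    With ``log_transform`` the values are mapped by log2(x + pseudocount)
    first (used for the robustness re-ranking of tumor data).  Genes whose
    expression has zero variance are excluded and recorded.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = matrix.values.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + pseudocount)
    sd = values.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(matrix.values.index, keep) if not k]
    genes = [g for g, k in zip(matrix.values.index, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(values[keep])
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationTable(
        genes=genes,
        matrix=corr,
        condition=matrix.condition,
        dropped=dropped,
        log_transformed=log_transform,
    )


def build_network(
    table: CorrelationTable, q: float = 0.01, absolute: bool = False
) -> CoexpressionNetwork:
    """Retain the top ``ceil(q * P)`` pairs by signed r (descending).

    P is the number of evaluated pairs.  The boundary tie-break is
    deterministic: r descending, then the (gene_a, gene_b) id pair
    lexicographically.  With ``absolute`` the ranking uses |r| instead of the
    signed value.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if table.n_pairs == 0:
        raise ValueError("empty correlation table")
    n_keep = math.ceil(q * table.n_pairs)

    iu, ju = np.triu_indices(table.n_genes, k=1)
    r = table.matrix[iu, ju]
    score = np.abs(r) if absolute else r
    gene_arr = np.asarray(table.genes, dtype=str)
    a_names = gene_arr[iu]
    b_names = gene_arr[ju]
    # canonical orientation: gene_a < gene_b regardless of input order
    swap = a_names > b_names
    a_names, b_names = (
        np.where(swap, b_names, a_names),
        np.where(swap, a_names, b_names),
    )
    # lexsort: last key is primary
    order = np.lexsort((b_names, a_names, -score))
    sel = order[:n_keep]
    edges = pd.DataFrame(
        {"gene_a": a_names[sel], "gene_b": b_names[sel], "r": r[sel]}
    ).reset_index(drop=True)
    cutoff = float(score[sel].min())
    return CoexpressionNetwork(
        edges=edges,
        cutoff=cutoff,
        quantile=q,
        condition=table.condition,
        absolute=absolute,
    )
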
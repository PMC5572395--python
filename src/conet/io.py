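"""Readers and writers for the plain-text formats the pipeline consumes.

Expression comes in as TSV (first column gene id, header sample ids) or
GCT 1.2; physical networks and reaction maps as TSV edge/row lists; gene
sets as GMT.  Networks go out as 3-column TSV or GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .coexnet import CoexpressionNetwork, CorrelationTable, ExpressionMatrix
from .coreg import PhysicalNetwork
from .rxncluster import ReactionEnzymeMap
from .synthgen import GroundTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gct",
    "write_gct",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_reaction_map",
    "write_reaction_map",
    "write_network",
    "read_network",
    "write_network_graphml",
    "write_correlation_matrix",
    "read_correlation_matrix",
    "write_ground_truth",
    "read_counts_tsv",
    "write_counts_tsv",
]


def read_expression_tsv(
    path, condition: str = "", unit: str = "TPM"
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, condition=condition or Path(path).stem, unit=unit)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gct(path, condition: str = "", unit: str = "TPM") -> ExpressionMatrix:
    """Read a GCT 1.2 file (version line, dims line, Name/Description header)."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line {version!r}")
        n_rows, n_cols = (int(x) for x in fh.readline().split())
        frame = pd.read_csv(fh, sep="\t")
    if frame.shape[0] != n_rows or frame.shape[1] - 2 != n_cols:
        raise ValueError("GCT dimension line does not match the table")
    values = frame.set_index(frame.columns[0]).drop(columns=[frame.columns[1]])
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, condition=condition or Path(path).stem, unit=unit)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.values.shape[0]}\t{matrix.values.shape[1]}\n")
        out = matrix.values.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="Name")


def read_edge_list(path, kind: str) -> PhysicalNetwork:
    frame = pd.read_csv(path, sep="\t")
    cols = list(frame.columns[:2])
    edges = list(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str)))
    return PhysicalNetwork(kind=kind, edges=edges)


def write_edge_list(phys: PhysicalNetwork, path) -> None:
    cols = ("tf", "target") if phys.kind == "regulatory" else ("protein_a", "protein_b")
    pd.DataFrame(phys.edges, columns=cols).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name <tab> description <tab> gene1 <tab> ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_reaction_map(path) -> ReactionEnzymeMap:
    """TSV with columns reaction_id, gene_id, subsystem (one enzyme per row)."""
    frame = pd.read_csv(path, sep="\t")
    enzymes: dict[str, list[str]] = {}
    subsystem: dict[str, str] = {}
    for rxn, gene, sub in frame.itertuples(index=False):
        enzymes.setdefault(str(rxn), []).append(str(gene))
        subsystem[str(rxn)] = str(sub)
    return ReactionEnzymeMap(
        enzymes={r: tuple(sorted(set(g))) for r, g in enzymes.items()},
        subsystem=subsystem,
    )


def write_reaction_map(rmap: ReactionEnzymeMap, path) -> None:
    rows = [
        (rxn, gene, rmap.subsystem[rxn])
        for rxn in rmap.reactions
        for gene in rmap.enzymes[rxn]
    ]
    pd.DataFrame(rows, columns=["reaction_id", "gene_id", "subsystem"]).to_csv(
        path, sep="\t", index=False
    )


def write_network(network: CoexpressionNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_network(path, q: float = 0.01, condition: str = "") -> CoexpressionNetwork:
    edges = pd.read_csv(path, sep="\t")
    cutoff = float(edges["r"].min()) if len(edges) else float("nan")
    return CoexpressionNetwork(
        edges=edges, cutoff=cutoff, quantile=q, condition=condition
    )


def write_network_graphml(network: CoexpressionNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(network.to_networkx(), path)


def write_correlation_matrix(table: CorrelationTable, path) -> None:
    frame = pd.DataFrame(table.matrix, index=table.genes, columns=table.genes)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_correlation_matrix(path, condition: str = "") -> CorrelationTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationTable(
        genes=list(frame.index),
        matrix=frame.to_numpy(dtype=float),
        condition=condition or Path(path).stem,
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
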
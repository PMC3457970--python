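"""Flat-file readers/writers for every pipeline artifact.

All intermediates are plain TSV (or SIF for networks, one-symbol-per-line
text for gene lists) so each stage is independently inspectable.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import GeneSet, KineticExpressionMatrix, PatientCohort, PPINetwork


def write_expression(matrix: KineticExpressionMatrix, expr_path, meta_path) -> None:
    matrix.values.to_csv(expr_path, sep="\t", index_label="gene")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_expression(expr_path, meta_path) -> KineticExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return KineticExpressionMatrix(values, meta)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes, key=str)))


def read_gene_list(path, name: str | None = None) -> GeneSet:
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneSet(name or Path(path).stem, set(genes), provenance=str(path))


def write_ppi(ppi: PPINetwork, tsv_path, sif_path=None) -> None:
    rows = [(u, v, d["confidence"]) for u, v, d in ppi.graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    df.sort_values(["node_a", "node_b"]).to_csv(tsv_path, sep="\t", index=False)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v, _ in rows:
                fh.write(f"{u}\tpp\t{v}\n")


def read_ppi(tsv_path, directed_overrides=(), removed_nodes=()) -> PPINetwork:
    df = pd.read_csv(tsv_path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["node_a"], row["node_b"], confidence=float(row["confidence"]))
    return PPINetwork(g, set(map(tuple, directed_overrides)), set(removed_nodes))


def write_cohort(cohort: PatientCohort, expr_path, clinical_path) -> None:
    cohort.expression.to_csv(expr_path, sep="\t", index_label="gene")
    cohort.clinical.to_csv(clinical_path, sep="\t", index_label="patient_id")


def read_cohort(expr_path, clinical_path, name: str = "cohort") -> PatientCohort:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clinical = pd.read_csv(clinical_path, sep="\t", index_col=0)
    return PatientCohort(expr, clinical, name=name)


def write_subnetwork_sif(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\tpp\t{v}\n")


def read_annotation(path) -> dict:
    """Annotation TSV (term_id, gene_id) -> dict term -> gene set."""
    df = pd.read_csv(path, sep="\t")
    return {term: set(sub["gene_id"]) for term, sub in df.groupby("term_id")}
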
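"""Reading and writing the pipeline's plain-text formats.

Counts and metadata are tab-separated with headers; gene lists are one id
per line; networks are exported as edge/node attribute TSVs plus SIF
(``geneA<TAB>co<TAB>geneB``) for import into Cytoscape-style viewers.  All
exports use a deterministic row order (sorted endpoints) so reruns diff
cleanly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gene_list",
    "write_gene_list",
    "export_network",
    "read_sif",
]

REQUIRED_METADATA = ("tissue", "condition", "sex")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column = gene id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed counts file {path}: {err}") from err
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups[:5]}")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))].tolist()
    if bad:
        raise ValueError(f"non-numeric count column(s) in {path}: {bad[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    df.index.name = "gene"
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with sample/tissue/condition/sex columns."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    return df.set_index("sample")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis("sample").to_csv(path, sep="\t")


def read_gene_list(path: str | Path, known: set[str] | None = None) -> list[str]:
    """One gene id per line; unknown ids are dropped with a warning."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(genes)) != len(genes):
        genes = list(dict.fromkeys(genes))
    if known is not None:
        unknown = [g for g in genes if g not in known]
        if unknown:
            import warnings

            warnings.warn(f"{path}: dropping {len(unknown)} gene(s) absent "
                          f"from the count matrix, e.g. {unknown[:3]}")
            genes = [g for g in genes if g in known]
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def _sorted_edges(net: nx.Graph):
    return sorted((min(a, b), max(a, b), d) for a, b, d in net.edges(data=True))


def export_network(net: nx.Graph, prefix: str | Path) -> dict[str, Path]:
    """Write <prefix>.sif, <prefix>_edges.tsv and <prefix>_nodes.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"sif": prefix.with_suffix(".sif"),
             "edges": Path(f"{prefix}_edges.tsv"),
             "nodes": Path(f"{prefix}_nodes.tsv")}
    edges = _sorted_edges(net)
    with open(paths["sif"], "w") as fh:
        for a, b, _ in edges:
            fh.write(f"{a}\tco\t{b}\n")
    edge_rows = [{"geneA": a, "geneB": b, **d} for a, b, d in edges]
    edge_cols = ["geneA", "geneB"] + sorted(
        {k for _, _, d in edges for k in d})
    pd.DataFrame(edge_rows, columns=edge_cols).to_csv(paths["edges"], sep="\t",
                                                      index=False)
    node_rows = [{"gene": n, **net.nodes[n]} for n in sorted(net.nodes)]
    node_cols = ["gene"] + sorted({k for n in net.nodes for k in net.nodes[n]})
    pd.DataFrame(node_rows, columns=node_cols).to_csv(paths["nodes"], sep="\t",
                                                      index=False)
    return paths


def read_sif(path: str | Path) -> nx.Graph:
    """Reconstruct the edge set of a SIF export (attributes not preserved)."""
    g = nx.Graph()
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed SIF line {ln!r}")
        a, _, b = parts
        g.add_edge(a, b)
    return g
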
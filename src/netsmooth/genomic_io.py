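"""Readers, writers and encoders for the tool's tabular input formats.

Formats handled here:

* weighted edge lists (``node<TAB>node<TAB>weight``, HIPPIE-like; extra
  columns ignored, whitespace-delimited lines accepted),
* sample x gene TSV matrices with a header row of gene symbols,
* GMT gene-set files,
* CSV clinical tables and their one-hot indicator encoding,
* TSV per-drug signature vectors (gene, value per drug column).

Gene symbols are uppercased at read time on both the matrix and network side
so that joins between data sources are case-insensitive.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    BINARY,
    CONTINUOUS,
    ClinicalTable,
    FeatureTable,
    GeneMatrix,
    GeneSet,
    WeightedNetwork,
)
from .errors import ParseError, ValidationError


# ---------------------------------------------------------------------------
# network

def read_network(path, min_weight: float = 0.0) -> WeightedNetwork:
    """Read a weighted undirected edge list.

    Self-loops are dropped, duplicate edges (in either node order) are
    collapsed keeping the maximum weight, and edges with weight below
    ``min_weight`` are removed. Raises :class:`ParseError` naming the line
    for malformed input and :class:`ValidationError` if nothing survives
    filtering.
    """
    if min_weight < 0:
        raise ValidationError("min_weight must be >= 0")
    path = Path(path)
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"expected at least 3 columns (node, node, weight), got {len(parts)}",
                    path=path, line=lineno,
                )
            u, v = parts[0].upper(), parts[1].upper()
            try:
                w = float(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # tolerate a header row
                raise ParseError(f"non-numeric weight {parts[2]!r}", path=path, line=lineno)
            if not np.isfinite(w) or w <= 0:
                raise ParseError(f"weight must be positive and finite, got {w}", path=path, line=lineno)
            if u == v:
                continue
            if w < min_weight:
                continue
            if graph.has_edge(u, v):
                graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
            else:
                graph.add_edge(u, v, weight=w)
    if graph.number_of_edges() == 0:
        raise ValidationError(f"network is empty after filtering ({path})")
    return WeightedNetwork(graph)


def write_network(net: WeightedNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\t{net.graph[u][v]['weight']!r}\n")


# ---------------------------------------------------------------------------
# gene matrices

def read_gene_matrix(path, dtype_flag: str = CONTINUOUS, on_duplicate: str = "error") -> GeneMatrix:
    """Read a sample x gene TSV matrix (first column = sample IDs).

    ``on_duplicate`` is ``"error"`` (strict, default) or ``"first"`` to keep
    the first occurrence of a duplicated sample or gene label. NaN entries
    and, for binary matrices, values outside {0,1} are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.upper()
    df.columns = df.columns.astype(str).str.upper()
    if on_duplicate == "first":
        df = df.loc[~df.index.duplicated(), ~df.columns.duplicated()]
    elif on_duplicate != "error":
        raise ValidationError(f"on_duplicate must be 'error' or 'first', got {on_duplicate!r}")
    if df.isna().any().any():
        raise ValidationError(f"matrix {path} contains missing values")
    return GeneMatrix(df.astype(float), dtype_flag=dtype_flag)


def write_gene_matrix(matrix: GeneMatrix, path) -> None:
    # repr round-trips float64 exactly, so write->read is the identity
    matrix.data.to_csv(path, sep="\t", index_label="sample", float_format=lambda v: repr(float(v)))


def binarize_expression(expression: GeneMatrix, sigma: float = 2.0) -> GeneMatrix:
    """Flag per-sample outlier expression: ``D[i,j] = 1`` iff
    ``|E[i,j] - mean_i| > sigma * sd_i`` with the population (ddof=0)
    standard deviation of row ``i``. Rows with zero dispersion binarize to
    all zeros.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if expression.dtype_flag != CONTINUOUS:
        raise ValidationError("binarize_expression expects a continuous matrix")
    values = expression.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        flags = np.abs(values - mean) > sigma * sd
    flags[np.broadcast_to(sd == 0, flags.shape)] = False
    data = pd.DataFrame(
        flags.astype(float), index=expression.data.index, columns=expression.data.columns
    )
    return GeneMatrix(data, dtype_flag=BINARY)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file (name, description, genes...); order of sets preserved,
    duplicate genes within a set collapsed."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"GMT line needs name, description and >=1 gene, got {len(parts)} fields",
                    path=path, line=lineno,
                )
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not genes:
                raise ParseError("gene set has no non-empty genes", path=path, line=lineno)
            sets.append(GeneSet(name=parts[0], genes=genes))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# LINCS-style drug signatures

def read_signatures(path) -> dict[str, pd.Series]:
    """Read per-drug gene signature vectors from a TSV (first column gene
    symbol, one column per drug). Returns drug -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate gene symbols in signature file {path}")
    if df.isna().any().any():
        raise ValidationError(f"signature file {path} contains missing values")
    return {str(drug): df[drug].astype(float) for drug in df.columns}


def write_signatures(signatures: dict[str, pd.Series], path) -> None:
    pd.DataFrame(signatures).to_csv(
        path, sep="\t", index_label="gene", float_format=lambda v: repr(float(v))
    )


# ---------------------------------------------------------------------------
# clinical table

def read_clinical(path) -> ClinicalTable:
    """Read a CSV clinical table (first column sample IDs); empty cells are
    missing values."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.upper()
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="sample")


def encode_clinical(table: ClinicalTable) -> FeatureTable:
    """Expand each categorical variable into 0/1 indicator columns named
    ``variable_category``. A missing value contributes all-zero indicators
    for that variable (no explicit "missing" column)."""
    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for var in table.variables:
        col = table.data[var]
        observed = sorted(c for c in col.dropna().unique())
        for cat in observed:
            name = f"{var}_{cat}"
            columns[name] = (col == cat).to_numpy(dtype=float)
            provenance[name] = f"clinical:{var}"
    data = pd.DataFrame(columns, index=table.data.index)
    return FeatureTable(data, provenance=provenance)
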
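"""Readers and writers for the pipeline's on-disk formats.

All tables are plain tab-separated UTF-8 text without quoting, matching
the HTSeq-style count exports the pipeline consumes.  Every writer sorts
its rows deterministically so that identical inputs produce byte-identical
files; edges are always stored with the lexicographically smaller gene
first.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .types import (
    CountMatrix,
    GeneSetCollection,
    RunConfig,
    SampleMetadata,
    ValidationError,
)

_LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "devcoexpr") -> logging.Logger:
    """Logger writing level-prefixed lines to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger()


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else df.index[0]
            raise ValidationError(
                f"non-integer count at gene {gene!r}, sample {col!r}"
            )
    return CountMatrix(df)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_metadata(path: str | Path, stage_order: list[str]) -> SampleMetadata:
    """Read a two-column TSV (sample_id, stage) with an explicit stage order."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(
            f"sample metadata must have exactly 2 columns, found {df.shape[1]}"
        )
    sample_col, stage_col = df.columns
    stage_of = dict(zip(df[sample_col], df[stage_col]))
    if len(stage_of) != len(df):
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    return SampleMetadata(stage_of, tuple(stage_order))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tstage\n")
        for sample, stage in meta.stage_of.items():
            fh.write(f"{sample}\t{stage}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member TAB member ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"found {len(parts)}"
                )
            name, description = parts[0], parts[1]
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValidationError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = (description, members)
    return GeneSetCollection(sets)


def _canonical_edges(network: nx.Graph) -> list[tuple[str, str, dict]]:
    edges = []
    for u, v, data in network.edges(data=True):
        a, b = (u, v) if str(u) < str(v) else (v, u)
        edges.append((str(a), str(b), data))
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def write_network(network: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a co-expression network as an edge-list TSV or GraphML.

    Edge attributes ``r`` (Pearson correlation) and ``q`` (BH-adjusted
    p-value) are carried in both formats.  Output is deterministic: edges
    are sorted with the lexicographically smaller gene first.
    """
    if format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tpcc\tq\n")
            for a, b, data in _canonical_edges(network):
                r = data.get("r", float("nan"))
                q = data.get("q", float("nan"))
                fh.write(f"{a}\t{b}\t{r:.10g}\t{q:.6g}\n")
    elif format == "graphml":
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(network.nodes, key=str))
        for a, b, data in _canonical_edges(network):
            ordered.add_edge(a, b, **data)
        nx.write_graphml(ordered, path)
    else:
        raise ValidationError(f"unknown network format: {format!r}")


def read_network_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, r=float(row.pcc), q=float(row.q))
    return g


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
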
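"""Topology-weighted pathway activation scoring.

A pathway is a directed acyclic graph whose nodes each hold one or more
genes, with designated sources (in-degree 0) and sinks (out-degree 0).
The activation score of a pathway, given a differential-expression result,
is a linear combination of member-gene log2 fold-changes weighted by

* a statistical weight ``min(-log10 p, 10) / 10`` in [0, 1], and
* a topological weight: the fraction of distinct source-to-sink paths that
  pass through the gene's node (computed exactly with two dynamic-
  programming passes over the DAG).

Positive scores indicate coordinated up-regulation of the pathway, negative
scores down-regulation.  Per-node mean LFCs are emitted as a coloring table
for diagram annotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import DEResult, bh_adjust  # noqa: F401  (re-export convenience)

__all__ = [
    "PathwayGraph",
    "PathwayScore",
    "topological_weight",
    "statistical_weight",
    "ipanda_score",
    "rank_pathways",
    "node_coloring",
    "read_gmt",
    "write_gmt",
]


@dataclass
class PathwayGraph:
    """Directed acyclic pathway graph; each node holds >= 1 gene id."""

    name: str
    graph: nx.DiGraph
    genes_by_node: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"pathway {self.name!r} is not a DAG")
        for n in self.graph.nodes:
            if not self.genes_by_node.get(n):
                raise ValueError(f"node {n!r} holds no genes")

    @property
    def sources(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    @property
    def sinks(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for n in self.graph.nodes:
            out.extend(self.genes_by_node[n])
        return out

    def node_of_gene(self) -> dict[str, str]:
        m: dict[str, str] = {}
        for n, gs in self.genes_by_node.items():
            for g in gs:
                m.setdefault(g, n)
        return m


@dataclass
class PathwayScore:
    """Signed activation score with per-gene contributions."""

    pathway: str
    score: float
    contributions: pd.Series
    coverage: float
    n_scored: int
    rank: int | None = None
    top_flag: bool = False


def _path_counts(P: PathwayGraph) -> tuple[dict[str, float], dict[str, float], float]:
    """paths-from-any-source and paths-to-any-sink per node, plus total."""
    G = P.graph
    order = list(nx.topological_sort(G))
    from_src = {n: (1.0 if G.in_degree(n) == 0 else 0.0) for n in G.nodes}
    for n in order:
        for m in G.successors(n):
            from_src[m] += from_src[n]
    to_sink = {n: (1.0 if G.out_degree(n) == 0 else 0.0) for n in G.nodes}
    for n in reversed(order):
        for m in G.predecessors(n):
            to_sink[m] += to_sink[n]
    total = sum(from_src[s] for s in P.sinks)
    return from_src, to_sink, total


def topological_weight(P: PathwayGraph, node: str) -> float:
    """Fraction of source-to-sink paths passing through ``node``, in [0, 1]."""
    if node not in P.graph:
        raise KeyError(f"node {node!r} not in pathway {P.name!r}")
    from_src, to_sink, total = _path_counts(P)
    if total == 0:
        return 0.0
    return from_src[node] * to_sink[node] / total


def statistical_weight(p_g: float, floor: float = 1e-10) -> float:
    """Evidence weight min(-log10 p, 10) / 10 in [0, 1]; p floored at 1e-10."""
    if not 0.0 <= p_g <= 1.0:
        raise ValueError(f"p-value {p_g} outside [0, 1]")
    p = max(p_g, floor)
    return min(-math.log10(p), 10.0) / 10.0


def ipanda_score(
    P: PathwayGraph, de: DEResult, normalize: str = "mean"
) -> PathwayScore:
    """Signed pathway activation from a DE result.

    score = sum over measured pathway genes of
    LFC_g * w_stat(p_g) * w_topo(node(g)), divided by the number of scored
    genes (``normalize='mean'``, default) or left as the raw sum
    (``normalize='sum'``).  Genes absent from ``de`` contribute nothing.
    """
    if normalize not in ("mean", "sum"):
        raise ValueError(f"unknown normalize {normalize!r}")
    # membership-only pathway (no topology): every gene weighted 1
    flat = P.graph.number_of_edges() == 0
    from_src, to_sink, total = _path_counts(P)
    node_of = P.node_of_gene()
    measured = [g for g in P.genes if g in de.table.index]
    coverage = len(measured) / len(P.genes)
    if not measured:
        warnings.warn(f"pathway {P.name!r}: no genes measured; score is NA")
        return PathwayScore(
            pathway=P.name,
            score=float("nan"),
            contributions=pd.Series(dtype=float),
            coverage=0.0,
            n_scored=0,
        )
    contrib = {}
    for g in measured:
        n = node_of[g]
        if flat:
            w_topo = 1.0
        else:
            w_topo = from_src[n] * to_sink[n] / total if total else 0.0
        lfc = float(de.table.loc[g, "lfc"])
        p = float(de.table.loc[g, "p"])
        contrib[g] = lfc * statistical_weight(p) * w_topo
    contributions = pd.Series(contrib)
    score = float(contributions.sum())
    if normalize == "mean":
        score /= len(measured)
    return PathwayScore(
        pathway=P.name,
        score=score,
        contributions=contributions,
        coverage=coverage,
        n_scored=len(measured),
    )


def rank_pathways(
    scores: list[PathwayScore], top_fraction: float = 0.05
) -> list[PathwayScore]:
    """Sort by score descending; flag the top ceil(fraction * N) as most
    up-regulated.  NA scores sort last and are never flagged; ties break by
    pathway id."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    valid = [s for s in scores if not math.isnan(s.score)]
    if not valid:
        raise ValueError("no non-NA pathway scores")
    ordered = sorted(valid, key=lambda s: (-s.score, s.pathway))
    n_flag = math.ceil(top_fraction * len(ordered))
    for i, s in enumerate(ordered):
        s.rank = i + 1
        s.top_flag = i < n_flag
    na = sorted((s for s in scores if math.isnan(s.score)), key=lambda s: s.pathway)
    for s in na:
        s.rank = None
        s.top_flag = False
    return ordered + na


def node_coloring(P: PathwayGraph, de: DEResult) -> pd.DataFrame:
    """Per-node mean LFC over measured member genes (NA if none measured).

    Positive values = up-regulated node (case above control)."""
    rows = []
    for n in P.graph.nodes:
        gs = [g for g in P.genes_by_node[n] if g in de.table.index]
        mean_lfc = float(de.table.loc[gs, "lfc"].mean()) if gs else float("nan")
        rows.append((n, len(P.genes_by_node[n]), len(gs), mean_lfc))
    return pd.DataFrame(
        rows, columns=["node", "n_genes", "n_measured", "mean_lfc"]
    ).set_index("node")


# ---------------------------------------------------------------------------
# i/o: GMT memberships + per-pathway edge lists


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one pathway per line — name, description, then gene ids."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


def write_gmt(path, memberships: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in memberships.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def load_pathway(name: str, gmt_genes: list[str], edges_path=None) -> PathwayGraph:
    """Build a PathwayGraph from GMT membership and an optional edge list.

    Without topology every gene becomes an isolated single-gene node (each
    is then both source and sink, so all topological weights are 1)."""
    G = nx.DiGraph()
    if edges_path is not None:
        edf = pd.read_csv(edges_path, sep="\t")
        for _, row in edf.iterrows():
            G.add_edge(str(row["src"]), str(row["dst"]))
        genes_by_node = {n: [n] for n in G.nodes}
        for g in gmt_genes:
            if g not in G:
                G.add_node(g)
                genes_by_node[g] = [g]
    else:
        G.add_nodes_from(gmt_genes)
        genes_by_node = {g: [g] for g in gmt_genes}
    return PathwayGraph(name=name, graph=G, genes_by_node=genes_by_node)
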
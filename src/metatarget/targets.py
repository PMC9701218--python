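"""Graph- and expression-based therapeutic target ranking.

Candidate targets for a disease are scored three ways and the scores are
combined by mean rank:

* **Expression score** — |minmax-normalized LFC| x an evidence weight from
  the FDR q-value x the gene's basal-expression percentile; all three
  factors are in [0, 1] so the product is too.
* **Network-neighbors score** — the fraction of a gene's gene-type
  neighbors in the knowledge graph that are either directly linked to the
  disease or significantly perturbed (q < 0.05).
* **HeroWalk score** — cosine similarity between the gene's and the
  disease's node embeddings, learned by skip-gram over metapath-guided
  random walks on the heterogeneous graph (transition probability
  proportional to the candidate neighbor's degree).

Genes lacking druggability annotation, not druggable by small molecules, or
carrying a safety red flag are excluded from the final table (scores are
retained and the exclusion reason logged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._sgns import train_sgns
from .expression import DEResult

__all__ = [
    "DisconnectedQueryError",
    "KnowledgeGraph",
    "NodeEmbeddings",
    "WalkCorpus",
    "TargetScoreTable",
    "HeroWalk",
    "expression_score",
    "network_neighbors_score",
    "herowalk_walks",
    "herowalk_embed",
    "herowalk_rank",
    "aggregate_and_filter",
    "OMICS_MODELS",
]

NODE_TYPES = ("gene", "disease", "pathway")

#: the omics models the platform concept names; only three have public
#: enough descriptions to implement here.
OMICS_MODELS = {
    "Expression": True,
    "Network Neighbors": True,
    "Heterogeneous Graph Walk": True,
    "Matrix Factorization": False,
    "Interactome Community": False,
    "Causal inference": False,
    "Overexpression/Knockout": False,
    "Mutated/Disease Sub-modules": False,
    "Mutations": False,
    "Pathway": False,
    "Relevance": False,
}


class DisconnectedQueryError(KeyError):
    """The query disease node has no embedding (disconnected in the graph)."""


class KnowledgeGraph:
    """Heterogeneous undirected graph with typed nodes (gene/disease/pathway).

    No self-loops; duplicate edge insertions are idempotent."""

    def __init__(self) -> None:
        self.g = nx.Graph()

    def add_node(self, node: str, ntype: str) -> None:
        if ntype not in NODE_TYPES:
            raise ValueError(f"unknown node type {ntype!r}")
        if node in self.g and self.g.nodes[node]["ntype"] != ntype:
            raise ValueError(f"node {node!r} already has a different type")
        self.g.add_node(node, ntype=ntype)

    def add_edge(self, u: str, v: str, etype: str = "assoc") -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        for n in (u, v):
            if n not in self.g:
                raise KeyError(f"node {n!r} must be added (with a type) first")
        self.g.add_edge(u, v, etype=etype)

    def node_type(self, node: str) -> str:
        return self.g.nodes[node]["ntype"]

    def nodes_of_type(self, ntype: str) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["ntype"] == ntype]

    def neighbors_of_type(self, node: str, ntype: str) -> list[str]:
        return [m for m in self.g.neighbors(node) if self.g.nodes[m]["ntype"] == ntype]

    def degree(self, node: str) -> int:
        return int(self.g.degree(node))

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [
            (u, self.node_type(u), v, self.node_type(v), d["etype"])
            for u, v, d in sorted(self.g.edges(data=True))
        ]
        df = pd.DataFrame(rows, columns=["src", "src_type", "dst", "dst_type", "edge_type"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KnowledgeGraph":
        df = pd.read_csv(path, sep="\t")
        kg = cls()
        for _, r in df.iterrows():
            kg.add_node(str(r["src"]), str(r["src_type"]))
            kg.add_node(str(r["dst"]), str(r["dst_type"]))
            kg.add_edge(str(r["src"]), str(r["dst"]), str(r["edge_type"]))
        return kg


@dataclass
class NodeEmbeddings:
    """Node id -> d-vector, with provenance (graph fingerprint, seed)."""

    vectors: dict[str, np.ndarray]
    d: int
    seed: int
    fingerprint: str = ""
    missing: list[str] = field(default_factory=list)

    def __contains__(self, node: str) -> bool:
        return node in self.vectors

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vectors[a], self.vectors[b]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            {k: v for k, v in self.vectors.items()}, orient="index"
        )


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    metapath: tuple[str, ...]
    n_truncated: int = 0


# ---------------------------------------------------------------------------
# component scores


def expression_score(de: DEResult, basal: pd.Series) -> pd.Series:
    """score_g = |nLFC_g| * min(-log10 q, 10)/10 * basal percentile rank.

    nLFC is the study-level minmax LFC (LFC / max |LFC|).  Genes with
    missing basal expression get a zero basal weight (with a warning)."""
    lfc = de.table["lfc"]
    m = lfc.abs().max()
    if m == 0:
        raise ValueError("all-zero LFC; expression score undefined")
    nlfc = lfc / m
    q = np.clip(de.table["q"].to_numpy(), 1e-10, 1.0)
    w_sig = np.minimum(-np.log10(q), 10.0) / 10.0
    basal = basal.reindex(de.table.index)
    if basal.isna().any():
        warnings.warn(
            f"{int(basal.isna().sum())} genes lack basal expression; "
            "their basal weight is 0"
        )
    ok = basal.notna()
    w_basal = pd.Series(0.0, index=de.table.index)
    if ok.any():
        w_basal[ok] = stats.rankdata(basal[ok]) / ok.sum()
    return (nlfc.abs() * w_sig * w_basal).rename("expression_score")


def network_neighbors_score(
    G: KnowledgeGraph, disease: str, de: DEResult, q_threshold: float = 0.05
) -> pd.Series:
    """Fraction of each gene's gene-type neighbors that are disease-linked
    or significantly perturbed (q < threshold); isolated genes score 0."""
    if disease not in G.g:
        raise KeyError(f"disease node {disease!r} not in graph")
    linked = set(G.neighbors_of_type(disease, "gene"))
    sig = set(de.table.index[de.table["q"] < q_threshold])
    out = {}
    for g in G.nodes_of_type("gene"):
        nbrs = G.neighbors_of_type(g, "gene")
        if not nbrs:
            out[g] = 0.0
        else:
            hits = sum(1 for n in nbrs if n in linked or n in sig)
            out[g] = hits / len(nbrs)
    return pd.Series(out, name="neighbors_score")


# ---------------------------------------------------------------------------
# HeroWalk: metapath-guided walks + skip-gram


def herowalk_walks(
    G: KnowledgeGraph,
    metapath: tuple[str, ...] = ("gene", "disease", "gene"),
    walks_per_node: int = 20,
    walk_length: int = 21,
    seed: int = 0,
    degree_mode: str = "total",
) -> WalkCorpus:
    """Sample metapath-guided random walks.

    ``metapath`` is cyclic (first type == last type); node types along a
    walk follow the pattern with period len(metapath) - 1.  The next node
    is drawn among the current node's neighbors of the required type with
    probability proportional to that neighbor's degree (total degree by
    default; ``degree_mode='typed'`` restricts to same-type-edge degree).
    Walks that reach a node with no compatible neighbor are truncated and
    counted."""
    if len(metapath) < 2:
        raise ValueError("metapath needs >= 2 node types")
    if metapath[0] != metapath[-1]:
        raise ValueError("metapath must be cyclic (first type == last type)")
    for t in metapath:
        if t not in NODE_TYPES:
            raise ValueError(f"unknown node type {t!r} in metapath")
    period = len(metapath) - 1
    rng = np.random.default_rng(seed)
    starts = sorted(G.nodes_of_type(metapath[0]))
    walks: list[list[str]] = []
    n_trunc = 0
    for start in starts:
        for _ in range(walks_per_node):
            walk = [start]
            cur = start
            for step in range(1, walk_length):
                want = metapath[(step - 1) % period + 1]
                nbrs = G.neighbors_of_type(cur, want)
                if not nbrs:
                    n_trunc += 1
                    break
                nbrs = sorted(nbrs)
                if degree_mode == "total":
                    w = np.array([G.degree(n) for n in nbrs], dtype=float)
                else:
                    w = np.array(
                        [len(G.neighbors_of_type(n, G.node_type(n))) or 1 for n in nbrs],
                        dtype=float,
                    )
                cur = nbrs[rng.choice(len(nbrs), p=w / w.sum())]
                walk.append(cur)
            walks.append(walk)
    return WalkCorpus(walks=walks, metapath=tuple(metapath), n_truncated=n_trunc)


def herowalk_embed(
    corpus: WalkCorpus,
    d: int = 64,
    window: int = 3,
    negatives: int = 5,
    epochs: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> NodeEmbeddings:
    """Train skip-gram-with-negative-sampling embeddings on the walk corpus."""
    vectors = train_sgns(
        corpus.walks, d=d, window=window, negatives=negatives,
        epochs=epochs, lr=lr, seed=seed,
    )
    return NodeEmbeddings(vectors=vectors, d=d, seed=seed)


def herowalk_rank(
    E: NodeEmbeddings, disease: str, genes: list[str]
) -> pd.DataFrame:
    """Rank candidate genes by cosine similarity to the disease embedding.

    Genes without an embedding rank last with a null score."""
    if disease not in E:
        raise DisconnectedQueryError(
            f"disease {disease!r} has no embedding (disconnected from the walks)"
        )
    rows = []
    for g in genes:
        score = E.cosine(g, disease) if g in E else np.nan
        rows.append((g, score))
    df = pd.DataFrame(rows, columns=["gene", "herowalk_score"]).set_index("gene")
    embedded = df[df["herowalk_score"].notna()].sort_values(
        "herowalk_score", ascending=False, kind="stable"
    )
    missing = df[df["herowalk_score"].isna()]
    return pd.concat([embedded, missing])


class HeroWalk:
    """Metapath walk + skip-gram embedder with a fit/rank surface.

    Parameters mirror ``herowalk_walks`` and ``herowalk_embed``; ``fit``
    samples the walk corpus from a KnowledgeGraph and trains embeddings
    (exposed as ``embeddings_``), ``rank`` scores candidate genes against a
    disease node."""

    def __init__(
        self,
        metapath: tuple[str, ...] = ("gene", "disease", "gene"),
        walks_per_node: int = 20,
        walk_length: int = 21,
        d: int = 64,
        window: int = 3,
        negatives: int = 5,
        epochs: int = 5,
        lr: float = 0.025,
        seed: int = 0,
    ) -> None:
        self.metapath = tuple(metapath)
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.d = d
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def fit(self, G: KnowledgeGraph) -> "HeroWalk":
        corpus = herowalk_walks(
            G, self.metapath, self.walks_per_node, self.walk_length, self.seed
        )
        self.corpus_ = corpus
        self.embeddings_ = herowalk_embed(
            corpus, d=self.d, window=self.window, negatives=self.negatives,
            epochs=self.epochs, lr=self.lr, seed=self.seed,
        )
        all_nodes = set(G.g.nodes)
        self.embeddings_.missing = sorted(all_nodes - set(self.embeddings_.vectors))
        return self

    def rank(self, disease: str, genes: list[str]) -> pd.DataFrame:
        return herowalk_rank(self.embeddings_, disease, genes)


# ---------------------------------------------------------------------------
# aggregation and filtering


@dataclass
class TargetScoreTable:
    """All candidate genes with component scores, ranks and filter status."""

    table: pd.DataFrame
    top: pd.DataFrame
    exclusions: pd.DataFrame


def aggregate_and_filter(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    top_n: int = 20,
) -> TargetScoreTable:
    """Combine component scores by mean rank and apply target filters.

    ``scores``: genes x score columns (higher = better); ``annotations``:
    genes x {druggable, safety_red_flag} (0/1).  Per-column ranks (1 =
    best, ties share the mean rank) are averaged into ``aggregate_rank``.
    Genes that are unannotated, not druggable, or safety-red-flagged are
    excluded (scores retained, reason logged); the ``top_n`` surviving
    genes are returned sorted by aggregate rank."""
    t = scores.copy()
    for col in scores.columns:
        vals = t[col].to_numpy(dtype=float)
        filled = np.where(np.isnan(vals), -np.inf, vals)
        t[f"rank_{col}"] = stats.rankdata(-filled, method="average")
    rank_cols = [f"rank_{c}" for c in scores.columns]
    t["aggregate_rank"] = t[rank_cols].mean(axis=1)

    ann = annotations.reindex(t.index)
    reason = pd.Series(None, index=t.index, dtype=object)
    reason[ann["druggable"].isna() | ann["safety_red_flag"].isna()] = "unannotated"
    mask = reason.isna()
    reason[mask & (ann["druggable"] == 0)] = "not_druggable"
    mask = reason.isna()
    reason[mask & (ann["safety_red_flag"] == 1)] = "safety_red_flag"
    t["druggable"] = ann["druggable"]
    t["safety_red_flag"] = ann["safety_red_flag"]
    t["filtered_out_reason"] = reason

    surviving = t[t["filtered_out_reason"].isna()]
    order = surviving.assign(_g=surviving.index.astype(str)).sort_values(
        ["aggregate_rank", "_g"], kind="stable"
    ).index
    top = surviving.loc[order].head(top_n)
    exclusions = t[t["filtered_out_reason"].notna()][
        list(scores.columns) + ["filtered_out_reason"]
    ]
    return TargetScoreTable(table=t, top=top, exclusions=exclusions)


def require_model(name: str) -> None:
    """Guard for the omics-model registry: unknown or undescribed models
    raise instead of silently returning nothing."""
    if name not in OMICS_MODELS:
        raise ValueError(f"unknown omics model {name!r}")
    if not OMICS_MODELS[name]:
        raise NotImplementedError(
            f"omics model {name!r} is recognized but its algorithm is not "
            "publicly described; only Expression, Network Neighbors and "
            "Heterogeneous Graph Walk are implemented"
        )
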
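"""Synthetic data with planted ground truth for the whole pipeline.

Every input the pipeline consumes can be generated here: small case/control
log-expression studies sharing a planted set of perturbed genes, survival
cohorts whose hazard depends on a planted biomarker, a heterogeneous
disease-gene knowledge graph with planted true associations, directed
acyclic pathway graphs with planted coordinated regulation, and a
phenotype-prevalence matrix with planted disease clusters.

Generation is fully deterministic: every generator derives its random
stream from the ``SimulationSpec`` seed through fixed
``numpy.random.SeedSequence`` spawn keys, so identical specs reproduce
byte-identical files.

Model choices (documented in the methods note):

* per-gene basal log2 expression ~ Uniform(3, 12), shared by all studies
  and cohorts, giving the basal-expression spread the Expression score
  needs;
* log2 expression ~ Normal(basal_g, noise_sd); case samples of planted
  genes are shifted by the planted log2 effect; raw-scale matrices are
  ``2 ** log2`` so upper-quartile normalization is actually exercised;
* survival: exponential event times with rate ``lambda0 * HR`` for
  patients at or above the biomarker's cohort median expression and
  ``lambda0`` below it; independent exponential censoring calibrated so
  each patient is censored with the requested probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .pathways import PathwayGraph
from .phenotype import PhenotypePrevalenceMatrix
from .survival import SurvivalCohort
from .targets import KnowledgeGraph

__all__ = [
    "StudySpec",
    "CohortSpec",
    "GraphSpec",
    "PathwaySpec",
    "SimulationSpec",
    "gen_phenotype_matrix",
    "gen_expression_study",
    "gen_survival_cohort",
    "gen_knowledge_graph",
    "gen_pathways",
    "gen_annotations",
    "baseline_log2",
    "default_scenario",
    "write_scenario",
    "gene_id",
    "disease_id",
]


def gene_id(i: int) -> str:
    return f"G{i:04d}"


def disease_id(j: int) -> str:
    return f"D{j:02d}"


@dataclass(frozen=True)
class StudySpec:
    n_case: int
    n_control: int
    label: str


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    biomarker_gene: int
    hazard_ratio: float
    censor_rate: float
    label: str = ""


@dataclass(frozen=True)
class GraphSpec:
    n_diseases: int
    edges_per_gene: int
    planted_assoc: tuple[tuple[int, int], ...]  # (gene index, disease index)
    n_genes: int = 500
    noise_edges_per_disease: int = 3
    community_p: float = 0.2


@dataclass(frozen=True)
class PathwaySpec:
    size: int
    topology: str  # chain | fork | diamond
    planted_direction: str  # up | down | null


@dataclass
class SimulationSpec:
    """Full description of a synthetic scenario (see module docstring)."""

    seed: int
    n_genes: int
    studies: list[StudySpec] = field(default_factory=list)
    planted_lfc: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    cohorts: list[CohortSpec] = field(default_factory=list)
    graph: GraphSpec | None = None
    pathways: list[PathwaySpec] = field(default_factory=list)
    #: force specific genes' basal log2 expression (e.g. a biomarker that
    #: must be well expressed to be measurable after normalization)
    baseline_override: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for g in self.planted_lfc:
            if not 1 <= g <= self.n_genes:
                raise ValueError(f"planted gene {g} outside 1..{self.n_genes}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for s in self.studies:
            if s.n_case < 1 or s.n_control < 1:
                raise ValueError("study sample counts must be >= 1")
        for c in self.cohorts:
            if c.n_patients < 1:
                raise ValueError("cohort size must be >= 1")
            if c.hazard_ratio <= 0:
                raise ValueError("hazard_ratio must be > 0")
            if not 0 <= c.censor_rate < 1:
                raise ValueError("censor_rate must be in [0, 1)")
            if not 1 <= c.biomarker_gene <= self.n_genes:
                raise ValueError("biomarker gene outside the gene universe")
        if self.graph is not None:
            for g, d in self.graph.planted_assoc:
                if not 1 <= g <= self.graph.n_genes:
                    raise ValueError(f"planted gene {g} outside graph genes")
                if not 0 <= d < self.graph.n_diseases:
                    raise ValueError(f"planted disease {d} out of range")
        for g, b in self.baseline_override.items():
            if not 1 <= g <= self.n_genes:
                raise ValueError(f"baseline override gene {g} outside universe")
            if b <= 0:
                raise ValueError("baseline override must be positive log2 units")
        for p in self.pathways:
            if p.size < 3:
                raise ValueError("pathway size must be >= 3")
            if p.topology not in ("chain", "fork", "diamond"):
                raise ValueError(
                    f"topology {p.topology!r} not supported (must be an "
                    "acyclic one of chain/fork/diamond)"
                )
            if p.planted_direction not in ("up", "down", "null"):
                raise ValueError(f"unknown direction {p.planted_direction!r}")

    @property
    def planted_genes(self) -> set[int]:
        return set(self.planted_lfc)

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    # -- (de)serialization --------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        d["planted_lfc"] = {str(k): v for k, v in d["planted_lfc"].items()}
        d["baseline_override"] = {
            str(k): v for k, v in d["baseline_override"].items()
        }
        if d["graph"] is not None:
            d["graph"]["planted_assoc"] = [list(x) for x in d["graph"]["planted_assoc"]]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        d["studies"] = [StudySpec(**s) for s in d.get("studies", [])]
        d["planted_lfc"] = {int(k): float(v) for k, v in d.get("planted_lfc", {}).items()}
        d["cohorts"] = [CohortSpec(**c) for c in d.get("cohorts", [])]
        if d.get("graph"):
            d["graph"]["planted_assoc"] = tuple(
                (int(g), int(dd)) for g, dd in d["graph"]["planted_assoc"]
            )
            d["graph"] = GraphSpec(**d["graph"])
        else:
            d["graph"] = None
        d["pathways"] = [PathwaySpec(**p) for p in d.get("pathways", [])]
        d["baseline_override"] = {
            int(k): float(v) for k, v in d.get("baseline_override", {}).items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# phenotype matrix


@dataclass
class PlantedPhenotypes:
    matrix: PhenotypePrevalenceMatrix
    labels: np.ndarray  # planted cluster assignment per disease


def gen_phenotype_matrix(
    n_diseases: int,
    n_features: int,
    n_clusters: int,
    within_noise: float,
    seed: int,
) -> PlantedPhenotypes:
    """Diseases drawn from ``n_clusters`` archetype prevalence vectors.

    Each disease's vector is its archetype plus independent uniform
    perturbation of magnitude <= ``within_noise``, clipped to [0, 1]."""
    if n_diseases < 1 or n_features < 1 or n_clusters < 1:
        raise ValueError("counts must be >= 1")
    if n_clusters > n_diseases:
        raise ValueError("n_clusters cannot exceed n_diseases")
    if not 0 <= within_noise < 0.5:
        raise ValueError("within_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    archetypes = rng.uniform(0.0, 1.0, size=(n_clusters, n_features))
    labels = np.arange(n_diseases) % n_clusters
    P = archetypes[labels]
    if within_noise > 0:
        P = P + rng.uniform(-within_noise, within_noise, size=P.shape)
    P = np.clip(P, 0.0, 1.0)
    M = PhenotypePrevalenceMatrix(
        diseases=[f"disease_{i:02d}" for i in range(n_diseases)],
        features=[f"feature_{j:02d}" for j in range(n_features)],
        P=P,
    )
    return PlantedPhenotypes(matrix=M, labels=labels)


# ---------------------------------------------------------------------------
# expression studies


def baseline_log2(spec: SimulationSpec) -> np.ndarray:
    """Per-gene basal log2 expression, Uniform(3, 12), fixed by the seed.

    ``spec.baseline_override`` pins chosen genes to fixed basal levels."""
    base = spec._rng(0, 0).uniform(3.0, 12.0, size=spec.n_genes)
    for g, b in spec.baseline_override.items():
        base[g - 1] = b
    return base


def _log2_matrix(
    spec: SimulationSpec, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    base = baseline_log2(spec)
    return base[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))


def gen_expression_study(spec: SimulationSpec, study_index: int) -> ExpressionStudy:
    """Raw-scale case/control study with planted log2 shifts in cases."""
    if not 0 <= study_index < len(spec.studies):
        raise ValueError(f"study_index {study_index} out of range")
    s = spec.studies[study_index]
    rng = spec._rng(1, study_index)
    n = s.n_case + s.n_control
    log2 = _log2_matrix(spec, rng, n)
    for g, lfc in sorted(spec.planted_lfc.items()):
        log2[g - 1, : s.n_case] += lfc
    raw = np.power(2.0, log2)
    samples = [f"{s.label}_case_{i+1}" for i in range(s.n_case)] + [
        f"{s.label}_ctrl_{i+1}" for i in range(s.n_control)
    ]
    X = pd.DataFrame(raw, index=[gene_id(i + 1) for i in range(spec.n_genes)], columns=samples)
    group = pd.Series(
        ["case"] * s.n_case + ["control"] * s.n_control, index=samples
    )
    return ExpressionStudy(X=X, group=group, scale_flag="raw", label=s.label)


# ---------------------------------------------------------------------------
# survival cohorts

LAMBDA0 = 0.1  # baseline event rate (arbitrary time units)


def gen_survival_cohort(spec: SimulationSpec, cohort_index: int) -> SurvivalCohort:
    """Cohort with exponential survival linked to the planted biomarker.

    Patients at or above the biomarker's cohort-median expression have
    event rate ``LAMBDA0 * hazard_ratio``; censoring is independent
    exponential with per-patient rate ``c * r_i / (1 - c)`` so each patient
    is censored with probability exactly ``censor_rate``."""
    if not 0 <= cohort_index < len(spec.cohorts):
        raise ValueError(f"cohort_index {cohort_index} out of range")
    c = spec.cohorts[cohort_index]
    rng = spec._rng(2, cohort_index)
    log2 = _log2_matrix(spec, rng, c.n_patients)
    expr_b = log2[c.biomarker_gene - 1]
    high = expr_b >= np.median(expr_b)
    rate = LAMBDA0 * np.where(high, c.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if c.censor_rate > 0:
        c_rate = c.censor_rate * rate / (1.0 - c.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(c.n_patients, dtype=int)
    time = np.maximum(time, 1e-9)
    patients = [f"{c.label or f'cohort{cohort_index}'}_p{i+1:03d}" for i in range(c.n_patients)]
    expr = pd.DataFrame(
        log2, index=[gene_id(i + 1) for i in range(spec.n_genes)], columns=patients
    )
    return SurvivalCohort(
        patients=patients, time=time, event=event, expr=expr,
        label=c.label or f"cohort{cohort_index}",
    )


# ---------------------------------------------------------------------------
# knowledge graph


def gen_knowledge_graph(spec: SimulationSpec) -> KnowledgeGraph:
    """Heterogeneous gene/disease graph with planted associations.

    Background gene-gene edges follow preferential attachment (a few hub
    genes of high degree), so node degree alone is a poor predictor of
    disease association and the embedding benchmark is meaningful.  Each
    disease's planted genes additionally form a moderate-density community
    (pairwise edges with probability ``community_p``) and are all linked to
    the disease; noise gene-disease edges attach degree-proportionally."""
    if spec.graph is None:
        raise ValueError("spec has no graph section")
    gs = spec.graph
    rng = spec._rng(3, 0)
    kg = KnowledgeGraph()
    genes = [gene_id(i + 1) for i in range(gs.n_genes)]
    for g in genes:
        kg.add_node(g, "gene")
    for j in range(gs.n_diseases):
        kg.add_node(disease_id(j), "disease")
    # background gene-gene: preferential attachment (hubs)
    ba_seed = int(rng.integers(2**31))
    ba = nx.barabasi_albert_graph(gs.n_genes, max(gs.edges_per_gene, 1), seed=ba_seed)
    # random BA-index -> gene mapping: preferential attachment makes the
    # earliest indices the hubs, which must not coincide with planted genes
    perm = rng.permutation(gs.n_genes)
    for u, v in sorted(ba.edges()):
        kg.add_edge(genes[perm[u]], genes[perm[v]], "gene_gene")
    # planted communities + gene-disease edges
    by_disease: dict[int, list[int]] = {}
    for g, d in gs.planted_assoc:
        by_disease.setdefault(d, []).append(g)
    for d in sorted(by_disease):
        members = sorted(by_disease[d])
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if rng.random() < gs.community_p:
                    kg.add_edge(gene_id(members[a_i]), gene_id(members[b_i]), "gene_gene")
        for g in members:
            kg.add_edge(gene_id(g), disease_id(d), "gene_disease")
    # noise gene-disease edges, degree-proportional
    if gs.noise_edges_per_disease > 0:
        deg = np.array([kg.degree(g) for g in genes], dtype=float)
        for d in range(gs.n_diseases):
            planted = {gene_id(g) for g in by_disease.get(d, [])}
            w = deg.copy()
            for i, g in enumerate(genes):
                if g in planted:
                    w[i] = 0.0
            if w.sum() == 0:
                continue
            picks = rng.choice(
                gs.n_genes, size=min(gs.noise_edges_per_disease, int((w > 0).sum())),
                replace=False, p=w / w.sum(),
            )
            for i in sorted(picks):
                kg.add_edge(genes[i], disease_id(d), "gene_disease")
    return kg


# ---------------------------------------------------------------------------
# pathways


def _topology(size: int, topology: str) -> nx.DiGraph:
    G = nx.DiGraph()
    nodes = [f"n{i}" for i in range(size)]
    G.add_nodes_from(nodes)
    if topology == "chain":
        for a, b in zip(nodes, nodes[1:]):
            G.add_edge(a, b)
    elif topology == "fork":
        for b in nodes[1:]:
            G.add_edge(nodes[0], b)
    elif topology == "diamond":
        for m in nodes[1:-1]:
            G.add_edge(nodes[0], m)
            G.add_edge(m, nodes[-1])
    else:
        raise ValueError(f"topology {topology!r} is not an acyclic template")
    return G


def gen_pathways(spec: SimulationSpec) -> list[tuple[PathwayGraph, str]]:
    """Build pathway DAGs; returns (pathway, planted_direction) pairs.

    'up' pathways draw their genes from the positively planted genes,
    'down' from the negatively planted ones, 'null' from unplanted genes;
    a pathway spec that needs more genes of a sign than are planted is an
    error."""
    pos = sorted(g for g, l in spec.planted_lfc.items() if l > 0)
    neg = sorted(g for g, l in spec.planted_lfc.items() if l < 0)
    unplanted = sorted(set(range(1, spec.n_genes + 1)) - spec.planted_genes)
    cursors = {"up": 0, "down": 0, "null": 0}
    pools = {"up": pos, "down": neg, "null": unplanted}
    out: list[tuple[PathwayGraph, str]] = []
    for idx, p in enumerate(spec.pathways):
        pool = pools[p.planted_direction]
        cur = cursors[p.planted_direction]
        if cur + p.size > len(pool):
            raise ValueError(
                f"not enough {p.planted_direction!r} genes for pathway {idx} "
                f"(need {p.size}, have {len(pool) - cur})"
            )
        members = pool[cur : cur + p.size]
        cursors[p.planted_direction] = cur + p.size
        G = _topology(p.size, p.topology)
        nodes = [f"n{i}" for i in range(p.size)]
        genes_by_node = {n: [gene_id(g)] for n, g in zip(nodes, members)}
        out.append(
            (
                PathwayGraph(
                    name=f"pw{idx:02d}_{p.topology}_{p.planted_direction}",
                    graph=G,
                    genes_by_node=genes_by_node,
                ),
                p.planted_direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(spec: SimulationSpec) -> pd.DataFrame:
    """Druggability/safety annotations for the graph's gene universe.

    Planted-association genes are druggable and safe (the scenario's
    drivers must be rankable); background genes are druggable with
    probability 0.7 and red-flagged with probability 0.1."""
    if spec.graph is None:
        raise ValueError("spec has no graph section")
    rng = spec._rng(4, 0)
    planted = {g for g, _ in spec.graph.planted_assoc}
    rows = []
    for i in range(1, spec.graph.n_genes + 1):
        if i in planted:
            rows.append((gene_id(i), 1, 0))
        else:
            rows.append(
                (gene_id(i), int(rng.random() < 0.7), int(rng.random() < 0.1))
            )
    return pd.DataFrame(
        rows, columns=["gene", "druggable", "safety_red_flag"]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# bundled scenario + writers


def default_scenario(seed: int = 0) -> SimulationSpec:
    """The bundled end-to-end scenario.

    Four case/control studies sized like small fibroblast/iPSC cohorts
    (10v10, 7v4, 6v3, 5v5); 2000 genes with 20 planted (one biomarker at
    +2.5 log2, nine at +1.5, ten at -1.5) and log2 noise SD 0.5; ten
    survival cohorts of 250 patients (censoring 0.3) of which three are
    hazard-linked to the biomarker at HR 2.5; a 500-gene/20-disease
    knowledge graph whose first disease is associated with 25 planted
    genes; six pathways (two up, two down, two null)."""
    planted = {1: 2.5}
    planted.update({g: 1.5 for g in range(2, 11)})
    planted.update({g: -1.5 for g in range(11, 21)})
    # the biomarker is planted as a well-expressed gene: its effect must
    # survive upper-quartile normalization + log2(x+1), which suppresses
    # genes expressed far below the upper quartile
    override = {1: 11.0}
    cohorts = []
    for i in range(10):
        hr = 2.5 if i < 3 else 1.0
        cohorts.append(
            CohortSpec(
                n_patients=250, biomarker_gene=1, hazard_ratio=hr,
                censor_rate=0.3, label=f"cohort{i:02d}",
            )
        )
    assoc = tuple((g, 0) for g in range(1, 26))
    return SimulationSpec(
        seed=seed,
        n_genes=2000,
        studies=[
            StudySpec(10, 10, "s10v10"),
            StudySpec(7, 4, "s7v4"),
            StudySpec(6, 3, "s6v3"),
            StudySpec(5, 5, "s5v5"),
        ],
        planted_lfc=planted,
        noise_sd=0.5,
        cohorts=cohorts,
        graph=GraphSpec(
            n_diseases=20, edges_per_gene=4, planted_assoc=assoc, n_genes=500
        ),
        pathways=[
            PathwaySpec(5, "chain", "up"),
            PathwaySpec(4, "diamond", "up"),
            PathwaySpec(5, "chain", "down"),
            PathwaySpec(4, "diamond", "down"),
            PathwaySpec(5, "chain", "null"),
            PathwaySpec(4, "diamond", "null"),
        ],
        baseline_override=override,
    )


def write_scenario(spec: SimulationSpec, outdir) -> None:
    """Write every generated input plus a machine-readable ground-truth
    sidecar (JSON) to ``outdir``; byte-identical for identical specs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {
        "planted_lfc": {gene_id(g): l for g, l in sorted(spec.planted_lfc.items())},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    for i, s in enumerate(spec.studies):
        study = gen_expression_study(spec, i)
        study.X.round(6).to_csv(out / f"study_{s.label}.tsv", sep="\t")
        study.group.rename("group").to_csv(out / f"study_{s.label}_labels.tsv", sep="\t")
    truth["cohorts"] = []
    for i, c in enumerate(spec.cohorts):
        cohort = gen_survival_cohort(spec, i)
        df = pd.DataFrame(
            {"time": cohort.time.round(6), "event": cohort.event},
            index=pd.Index(cohort.patients, name="patient_id"),
        )
        df = pd.concat([df, cohort.expr.T.round(6)], axis=1)
        df.to_csv(out / f"survival_{cohort.label}.tsv", sep="\t")
        truth["cohorts"].append(
            {
                "label": cohort.label,
                "biomarker": gene_id(c.biomarker_gene),
                "hazard_ratio": c.hazard_ratio,
                "censor_rate": c.censor_rate,
            }
        )
    if spec.graph is not None:
        kg = gen_knowledge_graph(spec)
        kg.to_tsv(out / "graph.tsv")
        gen_annotations(spec).to_csv(out / "annotations.tsv", sep="\t")
        truth["planted_assoc"] = [
            [gene_id(g), disease_id(d)] for g, d in spec.graph.planted_assoc
        ]
    if spec.pathways:
        memberships = {}
        truth["pathways"] = {}
        for pw, direction in gen_pathways(spec):
            memberships[pw.name] = pw.genes
            edges = pd.DataFrame(sorted(pw.graph.edges()), columns=["src", "dst"])
            edges["src"] = edges["src"].map(lambda n: pw.genes_by_node[n][0])
            edges["dst"] = edges["dst"].map(lambda n: pw.genes_by_node[n][0])
            edges.to_csv(out / f"pathway_{pw.name}_edges.tsv", sep="\t", index=False)
            truth["pathways"][pw.name] = direction
        from .pathways import write_gmt

        write_gmt(out / "pathways.gmt", memberships)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    (out / "spec.json").write_text(spec.to_json())
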
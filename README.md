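# metatarget

From disease phenotypes to therapeutic target hypotheses: a tested,
simulation-backed pipeline for cross-disease transcriptomics.

Rare monogenic diseases that share molecular machinery (for example,
DNA-repair syndromes that are all prone to cancer) can be mined jointly:
cluster the diseases by their clinical phenotypes, find genes perturbed in
*all* of them, ask whether those genes stratify cancer patients by
survival, and rank candidate therapeutic targets for the poor-prognosis
stratum.  `metatarget` implements each stage of that workflow as a small,
well-tested library with a planted-signal simulator, so every statistical
step can be validated end to end without any external download.

## The pipeline

1. **Phenotype clustering** (`metatarget.phenotype`). Diseases are vectors
   of clinical-feature prevalences in [0, 1]. Agglomerative clustering with
   *uncentered correlation* similarity `s(x, y) = Σxᵢyᵢ / (‖x‖‖y‖)` and
   average linkage (UPGMA) on `d = 1 − s`.

2. **Differential expression and meta-analysis** (`metatarget.expression`).
   Raw matrices are upper-quartile normalized (each sample divided by its
   75th percentile) and log2-transformed. Per study, a two-group test:
   plain pooled t or an empirical-Bayes moderated t with the posterior
   variance `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, hyperparameters
   estimated by moment-matching of `log s²_g`. Studies are combined per
   gene: minmax-normalized LFCs `nLFC = LFC / max|LFC|` averaged into a
   combined LFC, and signed Stouffer
   `Z_g = Σ_k sign(LFC_gk)·Φ⁻¹(1 − p_gk/2) / √K`, then BH FDR.

3. **Survival stratification** (`metatarget.survival`). For each gene and
   cancer cohort, patients split at the median expression (ties → "high"),
   Kaplan–Meier curves compared with the two-group log-rank test; results
   form a genes × cohorts grid of p-values, significance flags (p < α) and
   directions (which group fares worse).

4. **Target ranking** (`metatarget.targets`). Three per-gene scores:
   *Expression* (|nLFC| × capped −log10 q × basal-expression percentile),
   *Network Neighbors* (fraction of gene neighbors that are disease-linked
   or perturbed), and *HeroWalk* — skip-gram embeddings of metapath-guided
   random walks (gene–disease–gene, transition probability ∝ neighbor
   degree) on a heterogeneous knowledge graph, scored by cosine similarity
   to the disease node. Scores are combined by mean rank; genes that are
   not druggable or carry a safety red flag are filtered out.

5. **Pathway activation** (`metatarget.pathways`). Signed pathway score
   `Σ_g LFC_g · w_stat(p_g) · w_topo(g) / n`, with the statistical weight
   `min(−log10 p, 10)/10` and the topological weight the exact fraction of
   source→sink paths through the gene's node in the pathway DAG. The top
   5% of pathways by score are flagged as most up-regulated, and per-node
   mean LFCs are emitted for diagram coloring.

6. **Simulation** (`metatarget.simulate`). Deterministic generators for
   every input with planted ground truth: shared perturbed genes across
   small case/control studies, exponential survival linked to a biomarker,
   a knowledge graph with planted gene–disease associations, and pathway
   DAGs with planted coordinated regulation.

## Worked example

```python
from metatarget import simulate as sim, expression as ex, survival as sv

spec = sim.default_scenario(seed=1)          # 4 studies, 2000 genes, 20 planted
des = [
    ex.differential_expression(
        ex.normalize_expression(sim.gen_expression_study(spec, i), "uq_log2"), "eb"
    )
    for i in range(4)
]
meta = ex.meta_combine(des)
top = ex.top_k_genes(meta, 5)
print(top[["clfc", "z", "q"]])

cohorts = [sim.gen_survival_cohort(spec, i) for i in range(3)]
grid = sv.stratification_screen(cohorts, list(top.index), alpha=0.05)
print(grid.flag.loc[top.index[0]].tolist())
```

prints (seed 1):

```
           clfc         z             q
G0001  1.000000  9.299671  2.817630e-17
G0008  0.626226  7.985157  1.403436e-12
G0011 -0.113728 -7.856479  2.633881e-12
G0013 -0.317147 -7.701801  6.708092e-12
G0012 -0.484738 -7.544467  1.816564e-11
[True, True, True]
```

`G0001` is the scenario's planted biomarker (+2.5 log2 in cases): it tops
the combined ranking (`clfc` = 1 means it carries the study-maximal LFC;
`q` is the combined FDR), and it significantly stratifies survival in all
three hazard-linked cohorts.

The same stages are scriptable from a shell:

```bash
metatarget simulate --spec spec.json --out data/
metatarget dge --study data/study_s10v10.tsv --labels data/study_s10v10_labels.tsv \
    --norm uq_log2 --mode eb --label s10v10 --out de/
metatarget meta --de de/de_s10v10.tsv --de de/de_s7v4.tsv --k 10 --out meta/
metatarget survive --cohorts data/ --genes genes.txt --out surv/
metatarget targetid --graph data/graph.tsv --de de/de_s10v10.tsv \
    --basal basal.tsv --annot data/annotations.tsv --disease D00 --out tid/
metatarget pathways --gmt data/pathways.gmt --topo data/ --de de/de_s10v10.tsv --out pw/
```

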
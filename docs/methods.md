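# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `metatarget`, stage by stage.

## Phenotype clustering

Diseases are clustered on vectors of clinical-feature prevalences with
uncentered correlation (cosine) similarity and average linkage (UPGMA) on
the distance `d = 1 − s`, so all dendrogram heights lie in [0, 2].  Three
conventions are deliberate:

* **Distance transform** `1 − s` (not `√(1 − s)` or angular distance) —
  the convention of classic clustering tools built around "uncentered
  correlation".
* **Tie-break**: among equally distant cluster pairs, the pair with the
  lexicographically smallest (id_a, id_b) merges first, making trees
  platform-deterministic.  The agglomeration is O(n³), irrelevant at
  tens of diseases.
* **Missing prevalences** are an error by default; `impute='feature_mean'`
  is opt-in, because silent imputation hides data problems.

The number of flat clusters `k` is an explicit parameter (default 3 in the
CLI); no automatic cut criterion is guessed.

## Normalization and differential expression

`uq_log2` divides each sample by its own 75th percentile and applies
`log2(x + 1)`.  With no further rescaling the transform is *exactly*
invariant to per-sample scale factors; an optional rescale by the
geometric mean of the per-sample upper quartiles restores raw-like
magnitudes but breaks exact invariance, so it is off by default.  A
consequence worth knowing: genes expressed far below the upper quartile
land in the `x ≪ 1` regime of `log2(x + 1)`, which compresses their
fold-changes (their t-statistics survive roughly intact because noise is
compressed alongside signal).

Per-study testing is a two-group comparison on the log2 scale.  Plain
mode is the pooled-variance t.  `eb` mode moderates per-gene variances:
the prior `(d₀, s₀²)` is estimated by moment-matching the log sample
variances (closed-form prior mean; prior df from a trigamma inversion by
damped Newton), and the posterior variance
`s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g)` feeds a t with `d₀ + d_g` df.
Forcing `d₀ = 0` recovers plain mode exactly; `d₀ = ∞` pools variances
entirely (both asserted in tests).  Benjamini–Hochberg is implemented
directly from the step-up definition and cross-checked against both an
exhaustive oracle and statsmodels.

## Meta-analysis

Per study, LFCs are minmax-normalized as `nLFC = LFC / max|LFC|` over the
shared gene universe — a sign-preserving variant chosen because the
classical `(x − min)/(max − min)` destroys the sign structure a volcano
plot needs.  The combined LFC is the unweighted mean of nLFCs.  P-values
combine by *signed* Stouffer, `z = sign(LFC)·Φ⁻¹(1 − p/2)`, summed over
studies and divided by √K, so opposite-direction effects cancel rather
than reinforce; study weights are configurable but default to equal.
`p = 0` is floored at a configurable ε = 1e−300 before the quantile.
Genes absent from any study are dropped and reported, never imputed.
Ranking is by combined FDR, with ties broken by |combined LFC| then gene
id, so output order is total and reproducible.

## Survival stratification

Patients are dichotomized at the cohort median expression; ties at the
median go to "high" (configurable `tie=high|low|drop`).  Survival curves
use the product-limit estimator and groups are compared with the standard
two-group log-rank test (hypergeometric variance, χ² reference with 1 df);
both are vectorized over distinct event times and verified to match
lifelines to 1e-8.  Two properties deserve explicit statement:

* The χ² reference is mildly liberal at moderate samples: at n = 100 with
  exponential times and 20% censoring the measured type-I error is
  ≈ 0.053–0.054 rather than 0.050 (identical numbers are obtained from
  lifelines).  The calibration checks use enough replicates that this
  real, small liberality is measured accurately instead of being washed
  out or exaggerated by Monte-Carlo noise.
* A censored observation beyond the last event adds no event time and no
  deaths, but *does* enter every earlier risk set, so the survival curve
  itself is legitimately reweighted.

The genes × cohorts screen records raw p-values, flags cells at raw
p < α (α default 0.05), and reports direction as the sign of (median
survival of low − high), falling back to the sign of O − E for the high
group when a median is undefined.  A BH-corrected view of the grid is
emitted alongside but does not drive the headline flags — fidelity to the
raw-p convention first, rigor available.  Degenerate cells (constant
expression, no events, zero variance) become NA and never abort a screen.
No correction is applied across the grid for the headline flags, no Cox
models, no competing risks.

## Target ranking

Three omics scores are implemented; ten further model names are
recognized in configuration but raise `NotImplementedError` because no
public description of their algorithms exists.

* **Expression score** = `|nLFC| · min(−log10 q, 10)/10 · basal
  percentile`, a product of three factors in [0, 1].  The functional form
  is this package's own construction around the verbal definition
  (fold-change × significance × basal expression); the −log10 cap at 10
  keeps vanishing q-values from dominating.
* **Network Neighbors score** = fraction of a gene's gene-type neighbors
  that are disease-linked or significantly perturbed (q < 0.05); isolated
  genes score 0.  This is a minimal, defensible neighborhood-enrichment
  definition.
* **HeroWalk**: metapath-guided random walks (default gene–disease–gene,
  cyclic pattern; walks truncate, with a count, at nodes lacking a
  compatible neighbor) with transition probability proportional to the
  candidate neighbor's *total* degree (type-restricted degree is a
  config option).  Walk corpora train skip-gram with negative sampling:
  d = 64, window 3, 5 negatives, 5 epochs, 20 walks per start node, walk
  length 21, lr 0.025 with linear decay — defaults chosen as standard
  small-graph node2vec/metapath2vec-scale settings, all exposed.  The
  trainer is a single-threaded numba loop with an internal xorshift
  generator, so embeddings are bit-reproducible for a fixed seed.
  Candidate genes are ranked by cosine similarity to the disease node;
  genes without embeddings rank last with a null score, and a
  disconnected query disease raises.

Scores combine by mean per-score rank (ties share the mean rank) — rank
aggregation is scale-free, which matters because the three scores have
incommensurate scales.  Druggability/safety filtering removes rows
(reason logged: `unannotated`, `not_druggable`, `safety_red_flag`)
without ever reordering survivors.

## Pathway activation

A pathway is a DAG of nodes each holding ≥ 1 gene.  The activation score
is `Σ_g LFC_g · w_stat(p_g) · w_topo(node(g))`, divided by the number of
scored genes (`normalize='mean'`; `'sum'` available).  The statistical
weight is `min(−log10 p, 10)/10` computed from the per-study p (not q):
the weight is a soft evidence factor, FDR is reserved for selection.  The
topological weight is the exact fraction of distinct source→sink paths
through the node, computed by two DP passes (paths-from-sources ×
paths-to-sinks / total); an isolated node is its own trivial path.
Pathways supplied as bare gene sets (no topology) weight every gene 1.
Ranked pathways flag the top ⌈fraction · N⌉ (default 5%) as most
up-regulated; per-node mean LFCs are emitted as a coloring table.  This
is deliberately the *linear-combination core* of topology-weighted
pathway scoring; gene-module aggregation and group-level statistics of
the full published algorithm are out of scope and not claimed.

## The simulator

Every generator derives its stream from the scenario seed through fixed
`SeedSequence` spawn keys: identical specs give byte-identical files.

* **Expression**: per-gene basal log2 expression ~ Uniform(3, 12), shared
  across studies and cohorts (the Expression score needs a basal spread);
  log2 values ~ Normal(basal, noise_sd = 0.5); planted genes shift case
  samples by their planted log2 effect; raw matrices are `2^log2` so
  normalization is genuinely exercised.  Default study sizes 10v10, 7v4,
  6v3, 5v5 mirror small fibroblast/iPSC case/control cohorts.
* **Survival**: exponential event times (baseline rate 0.1 per time unit,
  memoryless — the simplest model with known log-rank power behavior),
  rate multiplied by the hazard ratio for patients at or above the
  biomarker's cohort-median expression.  Censoring is independent
  exponential with per-patient rate `c·r/(1 − c)`, so each patient is
  censored with probability exactly `censor_rate`.
* **Knowledge graph**: background gene–gene edges by preferential
  attachment with a randomized index-to-gene mapping (hubs exist but are
  unrelated to the planted signal — otherwise a degree ranking would
  trivially match the embedding and the degree-baseline comparison would
  be meaningless); each disease's planted genes form a community
  (pairwise edges, p = 0.2) and all link to the disease; noise
  gene–disease edges attach degree-proportionally.
* **Pathways**: chain / fork / diamond DAG templates; "up" pathways draw
  genes from the positively planted pool, "down" from the negative,
  "null" from unplanted genes.
* **Bundled scenario** (`default_scenario`): 2000 genes, 20 planted (one
  biomarker at +2.5, nine at +1.5, ten at −1.5), ten cohorts of 250
  patients (censoring 0.3) with three hazard-linked to the biomarker at
  HR 2.5, a 500-gene/20-disease graph with 25 genes planted for the first
  disease, six pathways.  The biomarker's basal expression is pinned high
  (log2 = 11) because a biomarker is by definition robustly measurable;
  with a random low basal the normalization's low-expression compression
  can mute exactly the gene the scenario is built around.
  Planted-association genes are annotated druggable and safe so the
  scenario's drivers are rankable; background genes are druggable with
  probability 0.7 and red-flagged with probability 0.1.

What the simulator does *not* emulate: batch effects, confounders,
library-size artifacts, real pathway curation, correlated gene modules in
the background, or non-exponential hazards.  Passing tests therefore
demonstrate correctness of the statistics and recoverability of planted
signals under clean conditions, not robustness to real-data pathologies.

## Problem sizes in checks

The oracle and calibration checks run at: 1000 random vectors (BH), 200
random instances (UPGMA ≤ 6 leaves; DAGs ≤ 12 nodes), 50 genes (plain t),
one 10,000-permutation log-rank reference at n = 20, 2000 genes (null
uniformity), 2000 cohorts of n = 100 (log-rank type-I), 2000 replicates
of a 10 × 10 null screen, 100 replicates of the three-study meta-analysis
recovery, 500 survival-power replicates, 10 embedding seeds, and 200
pathway replicates — sizes chosen so each estimate's Monte-Carlo error is
small relative to the property being checked.

## Known limitations

* The moderated-t prior fit assumes a common residual df across genes
  (true here by design of the two-group layout).
* Mann–Whitney switches from exact enumeration to the tie-corrected
  normal approximation at total n > 16 or in the presence of ties.
* The log-rank χ² reference inherits the usual small-sample liberality
  (~0.003–0.004 above nominal at n = 100); no permutation or exact
  version is wired into the screen.
* HeroWalk determinism is guaranteed only single-threaded (the default);
  the trainer never multithreads.
* Pathway scores are comparable across pathways only under the same DE
  input and normalization mode.
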
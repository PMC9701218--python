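"""Differential expression and cross-study meta-analysis.

The workflow mirrors a multi-cohort case/control transcriptomics comparison:

1. ``normalize_expression`` — upper-quartile normalization of raw expression
   (each sample divided by its 75th percentile) followed by ``log2(x + 1)``.
2. ``differential_expression`` — per-study two-group test on the log2 scale:
   either a plain pooled-variance t-test or an empirical-Bayes moderated t
   in which per-gene variances are shrunk toward a common prior whose
   hyperparameters (d0, s0^2) are estimated by moment-matching the
   log sample variances (digamma/trigamma inversion).
3. ``meta_combine`` — combine K studies per gene: minmax-normalized LFCs
   (LFC divided by the study's max |LFC|, preserving sign) are averaged into
   a combined LFC, and p-values are combined with a *signed* Stouffer sum
   z_gk = sign(LFC_gk) * Phi^-1(1 - p_gk / 2),  Z_g = sum_k z_gk / sqrt(K),
   so that discordant directions cancel; combined p-values are then
   FDR-adjusted with Benjamini-Hochberg.
4. ``top_k_genes`` — rank by adjusted Q (ties: |combined LFC|, then gene id).

``group_difference_test`` is the two-sided Mann-Whitney U used for
per-dataset case/control comparisons of a single gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionStudy",
    "DEResult",
    "MetaResult",
    "normalize_expression",
    "differential_expression",
    "bh_adjust",
    "meta_combine",
    "top_k_genes",
    "group_difference_test",
    "read_study_tsv",
]

CASE, CONTROL = "case", "control"


@dataclass
class ExpressionStudy:
    """One case/control gene x sample expression matrix.

    ``X`` is genes x samples; ``group`` maps each sample to 'case' or
    'control'; ``scale_flag`` is one of 'raw', 'normalized', 'log2'.
    """

    X: pd.DataFrame
    group: pd.Series
    scale_flag: str = "raw"
    label: str = "study"

    def __post_init__(self) -> None:
        if self.scale_flag not in ("raw", "normalized", "log2"):
            raise ValueError(f"unknown scale_flag {self.scale_flag!r}")
        self.group = self.group.reindex(self.X.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels {bad}; use 'case'/'control'")
        if self.scale_flag == "raw" and (self.X.to_numpy() <= 0).any():
            raise ValueError("raw-scale expression must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.X.index)

    @property
    def samples(self) -> list[str]:
        return list(self.X.columns)

    def case_control_counts(self) -> tuple[int, int]:
        return int((self.group == CASE).sum()), int((self.group == CONTROL).sum())


@dataclass
class DEResult:
    """Per-gene two-group differential expression statistics.

    ``table`` columns: lfc (log2 case minus control), s2 (residual
    variance), df (residual degrees of freedom), t, p, q (BH-adjusted).
    """

    table: pd.DataFrame
    label: str = "study"
    moderation: str = "plain"
    d0: float = 0.0
    s0_sq: float = float("nan")

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MetaResult:
    """Combined meta-analysis over K studies (shared gene universe).

    ``table`` columns: nlfc_<label> per study, clfc, z, p, q.
    """

    table: pd.DataFrame
    K: int
    study_labels: list[str]
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# normalization


def normalize_expression(
    study: ExpressionStudy,
    method: str = "uq_log2",
    rescale: str = "none",
) -> ExpressionStudy:
    """Normalize an expression study.

    ``uq_log2``: divide each sample by its own 75th percentile (computed over
    positive values), optionally rescale all samples by the geometric mean of
    the per-sample upper quartiles (``rescale='geomean'``), then log2(x + 1).
    The default ``rescale='none'`` makes the transform exactly invariant to
    per-sample scale factors.  ``log2_only``: log2(x + 1) on already
    normalized data.  ``none``: pass through.
    """
    if method == "none":
        return study
    X = study.X.to_numpy(dtype=float)
    if method == "uq_log2":
        if study.scale_flag != "raw":
            raise ValueError(
                f"uq_log2 requires raw-scale data, got {study.scale_flag!r}"
            )
        if (X <= 0).any():
            raise ValueError("uq_log2 requires strictly positive expression")
        uq = np.quantile(X, 0.75, axis=0)
        if (uq <= 0).any():
            raise ValueError("zero upper quartile in some sample")
        Xn = X / uq
        if rescale == "geomean":
            Xn = Xn * np.exp(np.mean(np.log(uq)))
        elif rescale != "none":
            raise ValueError(f"unknown rescale {rescale!r}")
        out = np.log2(Xn + 1.0)
    elif method == "log2_only":
        if study.scale_flag == "log2":
            raise ValueError("log2_only requires non-log-scale data")
        out = np.log2(X + 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionStudy(
        X=pd.DataFrame(out, index=study.X.index, columns=study.X.columns),
        group=study.group.copy(),
        scale_flag="log2",
        label=study.label,
    )


# ---------------------------------------------------------------------------
# per-study differential expression


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = (tri - x) / special.polygamma(2, y)
        y_new = y - step
        if y_new <= 0:  # Newton overshoot; bisect toward zero instead
            y_new = y / 2.0
        if abs(y_new - y) < 1e-10 * y_new:
            y = y_new
            break
        y = y_new
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log sample variances.

    Uses the scaled-F model for sample variances: E[log s^2] and
    Var[log s^2] are matched through digamma/trigamma identities, giving a
    closed-form prior mean and a trigamma inversion for the prior df.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / max(n - 1, 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = float("inf")
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def differential_expression(
    study: ExpressionStudy,
    moderation: str = "eb",
    prior: tuple[float, float] | None = None,
) -> DEResult:
    """Two-group differential expression on a log2-scale study.

    ``plain``: ordinary pooled-variance two-sample t with n1 + n2 - 2 df.
    ``eb``: empirical-Bayes moderated t — the posterior variance
    ``(d0 s0^2 + d_g s_g^2) / (d0 + d_g)`` replaces the pooled variance and
    the t reference gains d0 degrees of freedom.  ``prior`` forces (d0, s0^2)
    instead of estimating them (d0 = 0 recovers plain mode exactly).
    """
    if moderation not in ("eb", "plain"):
        raise ValueError(f"unknown moderation {moderation!r}")
    if study.scale_flag != "log2":
        raise ValueError("differential expression requires log2-scale data")
    n1, n2 = study.case_control_counts()
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} case / {n2} control")
    X = study.X.to_numpy(dtype=float)
    case = X[:, (study.group == CASE).to_numpy()]
    ctrl = X[:, (study.group == CONTROL).to_numpy()]
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    df_resid = float(n1 + n2 - 2)
    s2 = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    if not (s2 > 0).any():
        raise FloatingPointError("all genes have zero residual variance")

    d0, s0_sq = 0.0, float("nan")
    if moderation == "eb":
        d0, s0_sq = prior if prior is not None else _fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": s2,
            "df": df_resid,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        },
        index=study.X.index,
    )
    return DEResult(table=table, label=study.label, moderation=moderation, d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, clipped at 1, in input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# meta-analysis


def meta_combine(
    results: list[DEResult],
    eps: float = 1e-300,
    weights: list[float] | None = None,
) -> MetaResult:
    """Combine per-study DE results over the shared gene universe.

    Genes absent from any study are dropped (and reported per study).
    ``weights`` optionally weights the Stouffer sum (default: equal weights,
    Z = sum z_k / sqrt(K)).
    """
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 studies")
    labels = []
    for i, r in enumerate(results):
        lab = r.label if r.label not in labels else f"{r.label}_{i}"
        labels.append(lab)
    universe = set(results[0].genes)
    for r in results[1:]:
        universe &= set(r.genes)
    if not universe:
        raise ValueError("empty shared gene universe")
    genes = sorted(universe)
    dropped = {
        lab: sorted(set(r.genes) - universe) for lab, r in zip(labels, results)
    }

    K = len(results)
    w = np.ones(K) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (K,) or (w <= 0).any():
        raise ValueError("weights must be K positive numbers")

    nlfc_cols = {}
    zsum = np.zeros(len(genes))
    for lab, wk, r in zip(labels, w, results):
        sub = r.table.loc[genes]
        lfc = sub["lfc"].to_numpy()
        m = np.max(np.abs(lfc))
        if m == 0:
            raise ValueError(f"study {lab!r} has all-zero LFC; minmax undefined")
        nlfc_cols[f"nlfc_{lab}"] = lfc / m
        p = np.clip(sub["p"].to_numpy(), eps, 1.0)
        zsum += wk * np.sign(lfc) * stats.norm.isf(p / 2.0)
    Z = zsum / np.sqrt(np.sum(w**2))
    P = np.clip(2.0 * stats.norm.sf(np.abs(Z)), eps, 1.0)
    table = pd.DataFrame(nlfc_cols, index=genes)
    table["clfc"] = table[[f"nlfc_{lab}" for lab in labels]].mean(axis=1)
    table["z"] = Z
    table["p"] = P
    table["q"] = bh_adjust(P)
    return MetaResult(table=table, K=K, study_labels=labels, dropped_genes=dropped)


def top_k_genes(meta: MetaResult, k: int) -> pd.DataFrame:
    """Top-k genes by combined Q (ties: |combined LFC| desc, then gene id)."""
    if k > len(meta.genes):
        raise ValueError(f"k={k} exceeds {len(meta.genes)} genes")
    key = pd.DataFrame(
        {
            "q": meta.table["q"],
            "nabs": -meta.table["clfc"].abs(),
            "gene": meta.table.index.astype(str),
        },
        index=meta.table.index,
    )
    order = key.sort_values(["q", "nabs", "gene"], kind="stable").index
    return meta.table.loc[order].head(k)


# ---------------------------------------------------------------------------
# per-gene group comparison


def group_difference_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for two value vectors.

    Exact enumeration when n_a + n_b <= 16 and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction.
    Returns (U for group a, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 16 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    U = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mU = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return U, 1.0
    num = max(abs(U - mU) - 0.5, 0.0)  # continuity correction
    p = min(2.0 * stats.norm.sf(num / np.sqrt(var)), 1.0)
    return U, p


# ---------------------------------------------------------------------------
# i/o


def read_study_tsv(
    expr_path, labels_path, scale_flag: str = "raw", label: str = "study"
) -> ExpressionStudy:
    """Read an expression TSV (genes as rows) and a two-column label TSV."""
    X = pd.read_csv(expr_path, sep="\t", index_col=0)
    lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    lab.index = lab.index.astype(str)
    X.columns = X.columns.astype(str)
    return ExpressionStudy(X=X, group=lab, scale_flag=scale_flag, label=label)


def volcano_table(meta: MetaResult) -> pd.DataFrame:
    """Combined LFC vs -log10 Q, ready for a volcano plot."""
    with np.errstate(divide="ignore"):
        neg = -np.log10(meta.table["q"].to_numpy())
    return pd.DataFrame(
        {"clfc": meta.table["clfc"], "neg_log10_q": neg}, index=meta.table.index
    )


def heatmap_table(meta: MetaResult, k: int) -> pd.DataFrame:
    """nLFC matrix (genes x studies) for the top-k genes."""
    top = top_k_genes(meta, k)
    cols = [f"nlfc_{lab}" for lab in meta.study_labels]
    return top[cols]
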
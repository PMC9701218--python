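"""Median-split biomarker survival stratification.

For each candidate biomarker gene and each patient cohort, patients are
dichotomized at the cohort median expression (ties at the median go to
"high" by default), the two groups' survival is compared with the two-group
log-rank test, and results are collected in a genes x cohorts grid of
p-values with significance flags and a direction (which group fares worse).
Kaplan-Meier curves are estimated with the product-limit estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateSplitError",
    "DegenerateTestError",
    "SurvivalCohort",
    "KMCurve",
    "StratificationGrid",
    "median_split",
    "km_estimate",
    "logrank_test",
    "stratification_screen",
    "read_survival_tsv",
]


class DegenerateSplitError(ValueError):
    """Median split impossible (constant expression vector)."""


class DegenerateTestError(ValueError):
    """Log-rank variance is zero; the test statistic is undefined."""


@dataclass
class SurvivalCohort:
    """One cancer cohort: follow-up, event flags, and expression.

    ``time`` strictly positive; ``event`` 1 = death observed, 0 = censored;
    ``expr`` is genes x patients normalized expression.
    """

    patients: list[str]
    time: np.ndarray
    event: np.ndarray
    expr: pd.DataFrame
    label: str = "cohort"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patients)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match patients")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        if list(self.expr.columns) != list(self.patients):
            self.expr = self.expr[self.patients]


@dataclass
class KMCurve:
    """Product-limit survival estimate over distinct event times."""

    event_times: np.ndarray
    S: np.ndarray
    at_risk: np.ndarray
    d: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.S[idx])

    def median_survival_time(self) -> float:
        """First event time where S drops to <= 0.5; NaN if never reached."""
        below = np.nonzero(self.S <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")


@dataclass
class StratificationGrid:
    """genes x cohorts log-rank screen results.

    ``p``/``flag``/``direction`` are genes x cohorts DataFrames; direction
    +1 means the high-expression group fares worse, -1 the low group,
    NaN a degenerate cell.  ``q`` is a BH-corrected view of the p grid
    (correction across all non-NA cells), emitted alongside but not used
    for the headline flags.
    """

    p: pd.DataFrame
    flag: pd.DataFrame
    direction: pd.DataFrame
    q: pd.DataFrame
    alpha: float

    def significant_counts(self) -> pd.Series:
        """Per-gene number of cohorts flagged significant."""
        return self.flag.sum(axis=1, skipna=True).astype(int)


def median_split(expr_g, tie: str = "high") -> np.ndarray:
    """Label patients 'high' (expr >= median) or 'low' (expr < median).

    ``tie`` controls patients exactly at the median: 'high' (default),
    'low', or 'drop' (labelled '' and excluded downstream).
    """
    x = np.asarray(expr_g, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 patients to split")
    if np.all(x == x[0]):
        raise DegenerateSplitError("constant expression; median split degenerate")
    med = np.median(x)
    if tie == "high":
        lab = np.where(x >= med, "high", "low")
    elif tie == "low":
        lab = np.where(x > med, "high", "low")
    elif tie == "drop":
        lab = np.where(x > med, "high", np.where(x < med, "low", ""))
    else:
        raise ValueError(f"unknown tie rule {tie!r}")
    present = set(lab) - {""}
    if present != {"high", "low"}:
        raise DegenerateSplitError("median split produced a single group")
    return lab


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event lengths differ")
    if event.sum() == 0:
        warnings.warn("no events observed; survival curve is flat at 1.0")
        return KMCurve(
            event_times=np.array([]), S=np.array([]),
            at_risk=np.array([], dtype=int), d=np.array([], dtype=int),
        )
    et = np.unique(time[event == 1])
    order = np.sort(time)
    # at risk at t = number with time >= t; deaths at t by searchsorted bins
    n_at = time.size - np.searchsorted(order, et, side="left")
    ev_times_sorted = np.sort(time[event == 1])
    d_at = np.searchsorted(ev_times_sorted, et, side="right") - np.searchsorted(
        ev_times_sorted, et, side="left"
    )
    S = np.cumprod(1.0 - d_at / n_at)
    return KMCurve(
        event_times=et,
        S=S,
        at_risk=n_at.astype(int),
        d=d_at.astype(int),
    )


def logrank_test(labels, time, event) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed-minus-expected events for group 1 ("high") over distinct
    event times with the hypergeometric variance; chi2 = (O1 - E1)^2 / V,
    p from chi-square with 1 df.  Returns (chi2, p).
    """
    labels = np.asarray(labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    keep = labels != ""
    labels, time, event = labels[keep], time[keep], event[keep]
    groups = set(labels.tolist())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {sorted(groups)}")
    if event.sum() == 0:
        raise ValueError("no events observed")
    g1 = labels == sorted(groups)[0]  # deterministic group-1 choice ("high")
    if "high" in groups:
        g1 = labels == "high"
    o_minus_e, V = _logrank_oe(g1, time, event)
    if V <= 0:
        raise DegenerateTestError("log-rank variance is zero")
    chi2 = o_minus_e**2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _logrank_oe(g1: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    et = np.unique(time[event == 1])
    all_sorted = np.sort(time)
    g1_sorted = np.sort(time[g1])
    n = time.size - np.searchsorted(all_sorted, et, side="left")
    n1 = np.count_nonzero(g1) - np.searchsorted(g1_sorted, et, side="left")
    ev_sorted = np.sort(time[event == 1])
    ev1_sorted = np.sort(time[g1 & (event == 1)])
    d = np.searchsorted(ev_sorted, et, side="right") - np.searchsorted(
        ev_sorted, et, side="left"
    )
    d1 = np.searchsorted(ev1_sorted, et, side="right") - np.searchsorted(
        ev1_sorted, et, side="left"
    )
    frac = n1 / n
    o_minus_e = float(np.sum(d1 - d * frac))
    ok = n > 1
    V = float(np.sum(d[ok] * frac[ok] * (1 - frac[ok]) * (n[ok] - d[ok]) / (n[ok] - 1)))
    return o_minus_e, V


def stratification_screen(
    cohorts: list[SurvivalCohort],
    genes: list[str],
    alpha: float = 0.05,
    tie: str = "high",
) -> StratificationGrid:
    """Median-split + log-rank over a genes x cohorts grid.

    Degenerate cells (missing gene, constant expression, no events, zero
    variance) are recorded as NA and never abort the screen.  Direction is
    the sign of (median survival of low group - high group); when either
    median is undefined it falls back to the sign of (O_high - E_high).
    """
    labels = [c.label for c in cohorts]
    p = pd.DataFrame(np.nan, index=genes, columns=labels)
    direction = pd.DataFrame(np.nan, index=genes, columns=labels)
    for c in cohorts:
        for g in genes:
            if g not in c.expr.index:
                continue
            try:
                lab = median_split(c.expr.loc[g].to_numpy(), tie=tie)
                chi2, pval = logrank_test(lab, c.time, c.event)
            except (DegenerateSplitError, DegenerateTestError, ValueError) as err:
                warnings.warn(f"{c.label}/{g}: {err}; recorded as NA")
                continue
            p.loc[g, c.label] = pval
            keep = lab != ""
            hi = lab[keep] == "high"
            km_hi = km_estimate(c.time[keep][hi], c.event[keep][hi])
            km_lo = km_estimate(c.time[keep][~hi], c.event[keep][~hi])
            m_hi, m_lo = km_hi.median_survival_time(), km_lo.median_survival_time()
            if np.isnan(m_hi) or np.isnan(m_lo) or m_hi == m_lo:
                oe, _ = _logrank_oe(hi, c.time[keep], c.event[keep])
                direction.loc[g, c.label] = np.sign(oe) if oe != 0 else 0.0
            else:
                direction.loc[g, c.label] = np.sign(m_lo - m_hi)
    flag = (p < alpha).where(p.notna())
    # BH view across all tested cells
    q = p.copy()
    mask = p.notna().to_numpy()
    if mask.any():
        from .expression import bh_adjust

        flat = p.to_numpy()[mask]
        qflat = bh_adjust(flat)
        qarr = q.to_numpy()
        qarr[mask] = qflat
        q = pd.DataFrame(qarr, index=p.index, columns=p.columns)
    return StratificationGrid(p=p, flag=flag, direction=direction, q=q, alpha=alpha)


def read_survival_tsv(path, label: str = "cohort") -> SurvivalCohort:
    """Read a cohort TSV: patient_id, time, event, then one column per gene."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "time" not in df.columns or "event" not in df.columns:
        raise ValueError("survival TSV needs 'time' and 'event' columns")
    gene_cols = [c for c in df.columns if c not in ("time", "event")]
    return SurvivalCohort(
        patients=[str(i) for i in df.index],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        expr=df[gene_cols].T.set_axis([str(i) for i in df.index], axis=1),
        label=label,
    )
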
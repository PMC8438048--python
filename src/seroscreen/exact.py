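"""Shared exact-test machinery for 2x2 tables, BH correction, dichotomization.

All association and characterization steps in this package reduce to the
same primitive: a 2x2 table tested two-sided with Fisher's exact test, with
the odds ratio estimated by the conditional MLE (the value maximizing the
noncentral hypergeometric likelihood) and an exact central 95% confidence
interval.  Zero cells yield 0 or infinity estimates and bounds, which are
legitimate outputs, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ExactResult:
    p: float
    odds_ratio: float  # conditional MLE; may be 0 or inf
    ci_low: float
    ci_high: float


def tabulate(calls, outcome) -> np.ndarray:
    """2x2 table [[pos&out, pos&not], [neg&out, neg&not]] with pairwise-complete
    handling of missing outcome values (NaN excluded together with their call).
    """
    c = np.asarray(calls, dtype=float)
    o = np.asarray(outcome, dtype=float)
    if c.shape != o.shape:
        raise ValueError("calls and outcome must have equal length")
    keep = ~(np.isnan(c) | np.isnan(o))
    c, o = c[keep].astype(int), o[keep].astype(int)
    if c.size == 0:
        raise ValueError("no complete observations to tabulate")
    return np.array([
        [int(((c == 1) & (o == 1)).sum()), int(((c == 1) & (o == 0)).sum())],
        [int(((c == 0) & (o == 1)).sum()), int(((c == 0) & (o == 0)).sum())],
    ])


def exact_or(table, confidence: float = 0.95) -> ExactResult:
    """Two-sided Fisher exact p, conditional-MLE OR, exact central CI.

    Degenerate tables (an empty margin) return p = 1 with an undefined (nan)
    odds ratio and a vacuous CI.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if t.sum() == 0:
        raise ValueError("table has zero grand total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ExactResult(p=1.0, odds_ratio=float("nan"),
                           ci_low=0.0, ci_high=float("inf"))
    p = float(fisher_exact(t, alternative="two-sided")[1])
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return ExactResult(p=p, odds_ratio=float(res.statistic),
                       ci_low=float(ci.low), ci_high=float(ci.high))


def fisher_p(a: int, r1: int, c1: int, n: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table given by its top-left cell
    and margins (row1 total, col1 total, grand total).

    Sums the hypergeometric pmf over all tables no more probable than the
    observed one (with the customary 1 + 1e-7 relative tolerance for
    floating-point ties).  Vectorized over the support via log-gamma, which
    makes the tens of thousands of calls in a full antigen x symptom screen
    affordable; agrees with ``scipy.stats.fisher_exact`` to float precision.
    """
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
              + gammaln(n - r1 + 1) - gammaln(c1 - support + 1)
              - gammaln(n - r1 - c1 + support + 1)
              + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1))
    pmf = np.exp(logpmf - logpmf.max())
    p = pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum() / pmf.sum()
    return float(min(1.0, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (q-values) for a family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def median_dichotomize(values) -> pd.Series:
    """Dichotomize a continuous vector at its median, median in the lower bin.

    Returns 0 for values <= median, 1 for values above it; NaN preserved.
    """
    s = pd.Series(values, dtype=float)
    med = s.median(skipna=True)
    out = (s > med).astype(float)
    out[s.isna()] = np.nan
    return out


def fmt_estimate(x: float) -> str:
    """Serialize an OR/bound the way exact-test tables print them (Inf/0)."""
    if np.isnan(x):
        return "NA"
    if np.isinf(x):
        return "Inf"
    if x == 0:
        return "0"
    return f"{x:g}"
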
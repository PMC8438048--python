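"""Per-individual autoantibody-count analysis.

The autoantibody count — the number of antigens an individual is
seropositive for — is summarized (with a Shapiro-Wilk normality check),
stratified at the 5th/95th percentiles into "low" and "high" count groups
with strict inequalities, and each stratum is characterized against a
targeted set of dichotomous clinical variables and median-dichotomized
cytokines using two-sided exact 2x2 tests (no FDR correction: the
characterization is explorative).  Individual profiles can also be
clustered (complete linkage, Euclidean distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.stats import shapiro

from .cutoffs import SeroCallSet
from .exact import ExactResult, exact_or, median_dichotomize, tabulate

logger = logging.getLogger(__name__)


@dataclass
class CountSummary:
    per_individual: dict
    per_antigen: dict

    @staticmethod
    def _describe(x: np.ndarray) -> dict:
        out = {"n": int(x.size), "median": float(np.median(x)),
               "mean": float(np.mean(x)),
               "range": (float(x.min()), float(x.max()))}
        if x.size >= 3 and np.ptp(x) > 0:
            w, p = shapiro(x)
            out["shapiro_w"], out["shapiro_p"] = float(w), float(p)
        return out


def count_distribution(calls: SeroCallSet) -> CountSummary:
    """Summaries of per-individual counts and per-antigen seropositive counts.

    The per-antigen summary is restricted to detected antigens (at least one
    positive), matching how prevalence of autoantibodies is reported.
    """
    counts = calls.counts.to_numpy(dtype=float)
    npos = calls.n_positive
    det = npos[npos > 0].to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError("empty call set")
    return CountSummary(
        per_individual=CountSummary._describe(counts),
        per_antigen=CountSummary._describe(det) if det.size else {"n": 0},
    )


@dataclass
class CountStrata:
    counts: pd.Series
    low_threshold: float
    high_threshold: float
    low_ids: list
    high_ids: list


def stratify_counts(counts: pd.Series, low_pct: float = 5.0,
                    high_pct: float = 95.0) -> CountStrata:
    """Split individuals into low/high count strata at two percentiles.

    Thresholds use linear interpolation between order statistics (the
    convention of ``numpy.percentile``); membership is strict — fewer than
    the low threshold, more than the high threshold — so boundary values
    belong to neither stratum and the strata are disjoint.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    counts = pd.Series(counts)
    x = counts.to_numpy(dtype=float)
    lo = float(np.percentile(x, low_pct))
    hi = float(np.percentile(x, high_pct))
    low_ids = list(counts.index[counts < lo])
    high_ids = list(counts.index[counts > hi])
    if not low_ids and not high_ids:
        logger.warning("both strata empty (degenerate count distribution)")
    return CountStrata(counts=counts, low_threshold=lo, high_threshold=hi,
                       low_ids=low_ids, high_ids=high_ids)


def characterize_group(member_ids, clinical: pd.DataFrame,
                       variables: list[str]) -> pd.DataFrame:
    """Exact-test comparison of a group against all remaining individuals.

    Dichotomous variables are used as-is; continuous ones (cytokines) are
    median-dichotomized with the median in the lower interval.  Tables are
    pairwise-complete on missingness.  Variables with fewer than two
    observed levels are skipped with a warning.  No multiplicity correction.
    """
    member = clinical.index.isin(set(member_ids)).astype(float)
    rows = []
    for var in variables:
        col = clinical[var]
        vals = col.dropna().unique()
        if set(np.unique(vals)) - {0.0, 1.0}:
            col = median_dichotomize(col)
            vals = col.dropna().unique()
        if len(vals) < 2:
            logger.warning("variable %r has < 2 observed levels; skipped", var)
            continue
        table = tabulate(member, col.to_numpy())
        res: ExactResult = exact_or(table)
        rows.append({"variable": var,
                     "n11": table[0, 0], "n10": table[0, 1],
                     "n01": table[1, 0], "n00": table[1, 1],
                     "p": res.p, "odds_ratio": res.odds_ratio,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    return pd.DataFrame(rows, columns=["variable", "n11", "n10", "n01", "n00",
                                       "p", "odds_ratio", "ci_low", "ci_high"])


def characterize_strata(strata: CountStrata, clinical: pd.DataFrame,
                        variables: list[str]) -> dict[str, pd.DataFrame]:
    """Characterize the low and high strata against the rest of the cohort."""
    return {"low": characterize_group(strata.low_ids, clinical, variables),
            "high": characterize_group(strata.high_ids, clinical, variables)}


def cluster_profiles(profiles: pd.DataFrame):
    """Complete-linkage hierarchical clustering on Euclidean distances.

    Returns ``(linkage_matrix, leaf_order)``; merge heights are permutation
    invariant, leaf order is deterministic (scipy's index-based tie-break).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles to cluster")
    Z = linkage(profiles.to_numpy(dtype=float), method="complete",
                metric="euclidean")
    order = [profiles.index[i] for i in leaves_list(Z)]
    return Z, order


def dendrogram_json(Z, labels) -> list:
    """Dendrogram as a nested-list (Newick-like) structure for JSON output."""
    n = len(labels)
    nodes: dict[int, object] = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        nodes[n + k] = [nodes[int(a)], nodes[int(b)], float(h)]
    return nodes[n + len(Z) - 1] if len(Z) else list(labels)
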
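"""Three-criterion antibody-symptom selection with FDR control.

Every (antigen, symptom) pair is screened through the stepwise procedure:

1. *group size*: the autoantibody must be present in at least ``min_positives``
   individuals (default 10, about 2% of the original cohort);
2. *symptom prevalence*: the symptom's prevalence among seropositive
   individuals must be at least ``min_prevalence_pos`` (default 0.85);
3. *prevalence ratio*: the prevalence must be at least 25% higher in the
   seropositive group, read as the ratio P(Sx|Pos)/P(Sx|Neg) >= 1.25 (a
   config switch selects the percentage-point-difference reading instead);
4. Fisher's exact test must be significant after Benjamini-Hochberg
   correction (q below ``alpha_fdr``), the BH family being all pairs that
   pass the group-size criterion.

Selected pairs are reported with the association-table statistics:
n(Pos), P(Sx|Pos), P(Sx|Neg), PR, p, q, conditional-MLE OR and exact 95% CI
(0/infinity permitted and serialized as "0"/"Inf").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoffs import SeroCallSet
from .exact import bh_adjust, exact_or, fisher_p, fmt_estimate
from .counts import characterize_group

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    min_positives: int = 10
    min_prevalence_pos: float = 0.85
    min_prevalence_ratio: float = 1.25
    alpha_fdr: float = 0.05
    #: "ratio": PR >= min_prevalence_ratio; "difference": the alternative
    #: reading, P(Sx|Pos) - P(Sx|Neg) >= min_prevalence_ratio - 1
    ratio_mode: str = "ratio"

    def __post_init__(self):
        if self.min_positives < 1:
            raise ValueError("min_positives must be >= 1")
        if not (0 < self.min_prevalence_pos <= 1):
            raise ValueError("min_prevalence_pos must be in (0, 1]")
        if self.min_prevalence_ratio <= 1:
            raise ValueError("min_prevalence_ratio must exceed 1")
        if self.ratio_mode not in ("ratio", "difference"):
            raise ValueError("ratio_mode must be 'ratio' or 'difference'")


@dataclass
class AssociationRecord:
    antigen_id: object
    symptom_id: object
    n_pos: int
    p_sx_pos: float
    p_sx_neg: float
    pr: float
    p: float
    q: float
    or_est: float
    ci: tuple[float, float]
    table: np.ndarray = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {"antigen": self.antigen_id, "symptom": self.symptom_id,
                "n_pos": self.n_pos,
                "p_sx_pos_pct": round(100 * self.p_sx_pos),
                "p_sx_neg_pct": round(100 * self.p_sx_neg),
                "pr": round(self.pr, 1) if np.isfinite(self.pr) else "Inf",
                "p": self.p, "q": self.q,
                "or": fmt_estimate(self.or_est),
                "ci_low": fmt_estimate(self.ci[0]),
                "ci_high": fmt_estimate(self.ci[1])}


def prevalence_ratio(p_pos: float, p_neg: float) -> float:
    return p_pos / p_neg if p_neg > 0 else float("inf")


def _passes_effect_criteria(p_pos, p_neg, criteria: SelectionCriteria) -> bool:
    if p_pos < criteria.min_prevalence_pos:
        return False
    if criteria.ratio_mode == "ratio":
        return prevalence_ratio(p_pos, p_neg) >= criteria.min_prevalence_ratio
    return (p_pos - p_neg) >= (criteria.min_prevalence_ratio - 1.0)


def screen_pairs(calls: SeroCallSet, clinical: pd.DataFrame,
                 symptoms: list[str],
                 criteria: SelectionCriteria = SelectionCriteria(),
                 p_cache: dict | None = None) -> list[dict]:
    """Test every (antigen, symptom) pair passing the group-size criterion.

    Returns one dict per tested pair with its 2x2 table, prevalences,
    exact p and BH q (the BH family is exactly this tested set).  Symptom
    columns constant in the whole cohort are degenerate and skipped.

    ``p_cache`` maps (antigen, symptom) to (table, p); entries are reused
    and new ones added.  Only valid across calls with an identical call
    matrix — the caller is responsible for invalidation.
    """
    clinical = clinical.loc[calls.calls.index]
    usable = []
    for s in symptoms:
        if clinical[s].dropna().nunique() < 2:
            logger.info("symptom %r constant in cohort; skipped", s)
            continue
        usable.append(s)

    npos = calls.n_positive
    antigens = [a for a in calls.calls.columns
                if npos[a] >= criteria.min_positives]

    # vectorized pairwise-complete tabulation: one matrix product per margin
    sym = clinical[usable].to_numpy(dtype=float)
    valid = ~np.isnan(sym)
    sym0 = np.where(valid, sym, 0.0)

    tested: list[dict] = []
    for a in antigens:
        col = calls.calls[a].to_numpy(dtype=float)
        # float, not bool: a bool-bool matmul in numpy is a logical "any"
        pos, neg = (col == 1).astype(float), (col == 0).astype(float)
        n11 = pos @ sym0
        n10 = pos @ valid - n11
        n01 = neg @ sym0
        n00 = neg @ valid - n01
        for j, s in enumerate(usable):
            if p_cache is not None and (a, s) in p_cache:
                table, p_val = p_cache[(a, s)]
            else:
                table = np.array([[n11[j], n10[j]], [n01[j], n00[j]]],
                                 dtype=np.int64)
                if table[0].sum() == 0 or table[1].sum() == 0:
                    continue
                p_val = fisher_p(int(table[0, 0]), int(table[0].sum()),
                                 int(table[:, 0].sum()), int(table.sum()))
                if p_cache is not None:
                    p_cache[(a, s)] = (table, p_val)
            tested.append({"antigen": a, "symptom": s, "table": table,
                           "p_sx_pos": table[0, 0] / table[0].sum(),
                           "p_sx_neg": table[1, 0] / table[1].sum(),
                           "p": float(p_val)})
    if tested:
        for t, q in zip(tested, bh_adjust([t["p"] for t in tested])):
            t["q"] = float(q)
    return tested


def select_associations(calls: SeroCallSet, clinical: pd.DataFrame,
                        symptoms: list[str],
                        criteria: SelectionCriteria = SelectionCriteria(),
                        p_cache: dict | None = None
                        ) -> list[AssociationRecord]:
    """Run the stepwise selection over all (antigen, symptom) pairs.

    ``symptoms`` names the dichotomous symptom columns of ``clinical``.
    A record is emitted iff all three criteria hold and q < alpha_fdr.
    An empty result is a valid outcome.
    """
    tested = screen_pairs(calls, clinical, symptoms, criteria, p_cache)
    records = []
    for t in tested:
        if t["q"] >= criteria.alpha_fdr:
            continue
        if not _passes_effect_criteria(t["p_sx_pos"], t["p_sx_neg"], criteria):
            continue
        res = exact_or(t["table"])
        records.append(AssociationRecord(
            antigen_id=t["antigen"], symptom_id=t["symptom"],
            n_pos=int(t["table"][0].sum()),
            p_sx_pos=float(t["p_sx_pos"]), p_sx_neg=float(t["p_sx_neg"]),
            pr=prevalence_ratio(t["p_sx_pos"], t["p_sx_neg"]),
            p=t["p"], q=t["q"],
            or_est=res.odds_ratio, ci=(res.ci_low, res.ci_high),
            table=t["table"]))
    records.sort(key=lambda r: (str(r.antigen_id), r.p))
    return records


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    cols = ["antigen", "symptom", "n_pos", "p_sx_pos_pct", "p_sx_neg_pct",
            "pr", "p", "q", "or", "ci_low", "ci_high"]
    return pd.DataFrame([r.as_row() for r in records], columns=cols)


def characterize_positives(record: AssociationRecord, calls: SeroCallSet,
                           clinical: pd.DataFrame,
                           variables: list[str]) -> pd.DataFrame:
    """Explorative characterization of one selected antibody's seropositive
    group against the seronegative group (no multiplicity correction)."""
    pos_ids = calls.calls.index[calls.calls[record.antigen_id] == 1]
    return characterize_group(pos_ids, clinical, variables)
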
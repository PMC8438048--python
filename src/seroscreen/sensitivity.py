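"""One-at-a-time sensitivity analysis of cutoffs and selection criteria.

Each parameter (count-stratum percentiles, the three selection criteria,
per-antigen score-cutoff offsets) is varied on its own grid while all other
parameters stay at baseline, only the affected downstream stages are re-run,
and every baseline finding is recorded as retained or lost at each grid
point.  Grid points that make a stage degenerate (an empty stratum, say)
are recorded as not evaluable rather than crashing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import (AssociationRecord, SelectionCriteria,
                           select_associations)
from .counts import characterize_strata, stratify_counts
from .cutoffs import CutoffRecord, SeroCallSet, call_seropositive
from .normalize import ScoreMatrix

logger = logging.getLogger(__name__)

ALPHA = 0.05

CRITERIA_PARAMS = ("min_positives", "min_prevalence_pos",
                   "min_prevalence_ratio")


@dataclass
class SensitivityGrid:
    parameter: str   # criteria field, "count_percentiles" or "cutoff_offset"
    values: list
    baseline: object

    def __post_init__(self):
        if not any(self._eq(v, self.baseline) for v in self.values):
            raise ValueError(f"grid for {self.parameter} must contain the "
                             f"baseline value {self.baseline!r}")

    @staticmethod
    def _eq(a, b):
        return np.all(np.asarray(a) == np.asarray(b))


@dataclass
class BaselineRun:
    """A completed primary analysis, with everything sensitivity must re-run."""

    score_matrix: ScoreMatrix
    cutoffs: list[CutoffRecord]
    calls: SeroCallSet
    clinical: pd.DataFrame
    symptoms: list[str]
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    low_pct: float = 5.0
    high_pct: float = 95.0
    strata_variables: list[str] = field(default_factory=list)
    records: list[AssociationRecord] = field(default_factory=list)


def default_grids(baseline: BaselineRun) -> list[SensitivityGrid]:
    """Symmetric one-step neighborhoods around the baseline parameters."""
    c = baseline.criteria
    return [
        SensitivityGrid("count_percentiles",
                        [(2.5, 97.5), (baseline.low_pct, baseline.high_pct),
                         (10.0, 90.0)],
                        (baseline.low_pct, baseline.high_pct)),
        SensitivityGrid("min_positives", [5, c.min_positives, 15],
                        c.min_positives),
        SensitivityGrid("min_prevalence_pos",
                        [0.80, c.min_prevalence_pos, 0.90],
                        c.min_prevalence_pos),
        SensitivityGrid("min_prevalence_ratio",
                        [1.15, c.min_prevalence_ratio, 1.35],
                        c.min_prevalence_ratio),
        SensitivityGrid("cutoff_offset", [-1, 0, 1], 0),
    ]


@dataclass
class SensitivityReport:
    table: pd.DataFrame

    def summary(self) -> dict:
        """Findings robust at every evaluable grid point vs fragile ones."""
        out = {"robust": [], "fragile": []}
        for f, grp in self.table.groupby("finding", sort=True):
            evaluable = grp[grp.retained != "not_evaluable"]
            (out["robust"] if (evaluable.retained == True).all()  # noqa: E712
             else out["fragile"]).append(f)
        return out


def _strata_findings(baseline: BaselineRun, low_pct, high_pct):
    """Characterize strata at given percentiles; returns finding -> (p, OR).

    A finding is a (stratum, variable) pair significant at the 0.05 level.
    Returns None for a stratum when it is empty (not evaluable).
    """
    strata = stratify_counts(baseline.calls.counts, low_pct, high_pct)
    tests = characterize_strata(strata, baseline.clinical,
                                baseline.strata_variables)
    out = {}
    for name, ids in (("low", strata.low_ids), ("high", strata.high_ids)):
        if not ids:
            out[name] = None
            continue
        frame = tests[name]
        out[name] = {row.variable: (row.p, row.odds_ratio)
                     for row in frame.itertuples()}
    return out


def _offset_cutoffs(cutoffs, steps: int):
    out = []
    for r in cutoffs:
        c = round(r.cutoff + 0.1 * steps, 1)
        c = min(max(c, 0.0), 1.6)  # cap 1.6, not 1.5: keeps undetected antigens undetected
        out.append(dataclasses.replace(r, cutoff=c))
    return out


def run_sensitivity(baseline: BaselineRun,
                    grids: list[SensitivityGrid] | None = None
                    ) -> SensitivityReport:
    """Re-run the affected stages at every grid point of every grid.

    Baseline findings are the selected association records plus the
    stratum-characterization variables significant at baseline.  The rows at
    each grid's baseline point reproduce the primary analysis exactly.
    """
    if grids is None:
        grids = default_grids(baseline)
    assoc_findings = [(r.antigen_id, r.symptom_id) for r in baseline.records]
    base_strata = _strata_findings(baseline, baseline.low_pct,
                                   baseline.high_pct)
    strata_findings = [(s, v) for s in ("low", "high")
                       if base_strata[s] is not None
                       for v, (p, _) in base_strata[s].items() if p < ALPHA]

    rows = []
    p_cache: dict = {}
    for grid in grids:
        for value in grid.values:
            is_base = SensitivityGrid._eq(value, grid.baseline)
            if grid.parameter == "count_percentiles":
                res = _strata_findings(baseline, *value)
                for s, v in strata_findings:
                    if res[s] is None:
                        rows.append(_row(grid, value, is_base, ("strata", s, v),
                                         "not_evaluable", np.nan, np.nan))
                        continue
                    p, _ = res[s].get(v, (np.nan, np.nan))
                    rows.append(_row(grid, value, is_base, ("strata", s, v),
                                     bool(p < ALPHA), p, np.nan))
            else:
                if grid.parameter == "cutoff_offset":
                    criteria = baseline.criteria
                    if value == 0:
                        calls, cache = baseline.calls, p_cache
                    else:
                        calls = call_seropositive(
                            baseline.score_matrix,
                            _offset_cutoffs(baseline.cutoffs, value))
                        cache = None  # call matrix changed
                else:
                    criteria = dataclasses.replace(
                        baseline.criteria, **{grid.parameter: value})
                    calls, cache = baseline.calls, p_cache
                records = select_associations(calls, baseline.clinical,
                                              baseline.symptoms, criteria,
                                              p_cache=cache)
                found = {(r.antigen_id, r.symptom_id): r for r in records}
                for pair in assoc_findings:
                    r = found.get(pair)
                    rows.append(_row(grid, value, is_base,
                                     ("association",) + pair,
                                     r is not None,
                                     r.p if r else np.nan,
                                     r.q if r else np.nan))
    table = pd.DataFrame(rows, columns=["finding", "finding_type", "parameter",
                                        "grid_value", "is_baseline",
                                        "retained", "p", "q"])
    return SensitivityReport(table=table)


def _row(grid, value, is_base, finding, retained, p, q):
    return {"finding": ":".join(str(x) for x in finding[1:]),
            "finding_type": finding[0], "parameter": grid.parameter,
            "grid_value": str(value), "is_baseline": bool(is_base),
            "retained": retained, "p": p, "q": q}
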
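#!/usr/bin/env python
"""Sensitivity of the findings to cutoffs and criteria.

Varies one parameter at a time — count-stratum percentiles, each selection
criterion, and all per-antigen score cutoffs shifted one step up/down —
re-runs the affected downstream stages, and reports which baseline findings
survive at each grid point.

Reads results/data/mfi.csv and results/data/clinical.csv (the baseline
stages are recomputed deterministically); writes results/sensitivity.csv
and results/sensitivity_summary.json.
"""

import json
import logging
from pathlib import Path

import pandas as pd

from seroscreen import (BaselineRun, call_seropositive, default_grids,
                        detect_cutoffs, run_sensitivity, score_matrix,
                        select_associations)
from seroscreen.synthetic import CLINICAL_VARS, CYTOKINES

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.disable(logging.WARNING)
    mfi = pd.read_csv(RESULTS / "data" / "mfi.csv", index_col=0)
    clinical = pd.read_csv(RESULTS / "data" / "clinical.csv", index_col=0)
    symptoms = [c for c in clinical.columns if c.startswith("sym_")]

    sm = score_matrix(mfi)
    cutoffs = detect_cutoffs(sm)
    calls = call_seropositive(sm, cutoffs)
    records = select_associations(calls, clinical, symptoms)
    baseline = BaselineRun(
        score_matrix=sm, cutoffs=cutoffs, calls=calls, clinical=clinical,
        symptoms=symptoms, records=records,
        strata_variables=[v for v in list(CLINICAL_VARS) + list(CYTOKINES)
                          if v in clinical.columns])

    report = run_sensitivity(baseline, default_grids(baseline))
    report.table.to_csv(RESULTS / "sensitivity.csv", index=False)
    summary = report.summary()
    (RESULTS / "sensitivity_summary.json").write_text(json.dumps(summary,
                                                                 indent=2))
    print(f"grid points evaluated: "
          f"{len(report.table.groupby(['parameter', 'grid_value']))}")
    print(f"robust findings ({len(summary['robust'])}): "
          f"{summary['robust']}")
    for f in summary["fragile"]:
        lost = report.table[(report.table.finding == f)
                            & (report.table.retained == False)]  # noqa: E712
        where = [f"{r.parameter}={r.grid_value}" for r in lost.itertuples()]
        print(f"fragile: {f} lost at {', '.join(where)}")


if __name__ == "__main__":
    main()
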
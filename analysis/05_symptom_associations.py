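#!/usr/bin/env python
"""Three-criterion antibody-symptom association screen.

For every (antigen, symptom) pair: group size >= 10 seropositive, symptom
prevalence >= 85% among seropositive, prevalence ratio >= 1.25, and a
Benjamini-Hochberg-corrected Fisher exact test at q < 0.05 (family: all
pairs passing the group-size criterion).  Selected pairs are reported in
the association-table schema and the seropositive groups are characterized
against clinical variables and cytokines (explorative, uncorrected).

Reads results/{calls.csv, cutoffs.csv} and results/data/{clinical.csv,
truth.json}; writes results/associations.csv and one characterization CSV
per selected antigen.
"""

import json
from pathlib import Path

import pandas as pd

from seroscreen import (SelectionCriteria, characterize_positives,
                        records_frame, select_associations)
from seroscreen.cutoffs import CutoffRecord, SeroCallSet
from seroscreen.synthetic import CLINICAL_VARS, CYTOKINES

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls_frame = pd.read_csv(RESULTS / "calls.csv", index_col=0)
    cutoffs = pd.read_csv(RESULTS / "cutoffs.csv")
    recs = [CutoffRecord(r.antigen_id, r.peak_x, r.direction, r.cutoff)
            for r in cutoffs.itertuples()]
    calls = SeroCallSet(cutoffs=recs, calls=calls_frame)
    clinical = pd.read_csv(RESULTS / "data" / "clinical.csv", index_col=0)
    symptoms = [c for c in clinical.columns if c.startswith("sym_")]

    records = select_associations(calls, clinical, symptoms,
                                  SelectionCriteria())
    frame = records_frame(records)
    frame.to_csv(RESULTS / "associations.csv", index=False)
    print(f"selected associations: {len(records)}")
    print(frame.to_string(index=False))

    truth = json.loads((RESULTS / "data" / "truth.json").read_text())
    planted = {tuple(p) for p in truth["planted_pairs"]}
    got = {(r.antigen_id, r.symptom_id) for r in records}
    print(f"planted pairs recovered: {len(got & planted)} of {len(planted)}; "
          f"spurious: {len(got - planted)}")

    variables = [v for v in list(CLINICAL_VARS) + list(CYTOKINES)
                 if v in clinical.columns]
    for r in records:
        characterize_positives(r, calls, clinical, variables).to_csv(
            RESULTS / f"characterize_{r.antigen_id}.csv", index=False)


if __name__ == "__main__":
    main()
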
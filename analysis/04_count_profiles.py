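#!/usr/bin/env python
"""Autoantibody-count profiles.

Summarizes the per-individual autoantibody count (with a Shapiro-Wilk
normality check), stratifies the cohort at the 5th/95th count percentiles
into "low" and "high" groups, characterizes both strata against clinical
variables and median-dichotomized cytokines with exact 2x2 tests (no FDR:
explorative), and clusters the profiles (complete linkage, Euclidean).

Reads results/{calls.csv, counts.csv} and results/data/clinical.csv;
writes results/{strata.csv, strata_low_tests.csv, strata_high_tests.csv,
dendrogram.json}.
"""

import json
from pathlib import Path

import pandas as pd

from seroscreen import (characterize_strata, cluster_profiles,
                        count_distribution, stratify_counts)
from seroscreen.counts import dendrogram_json
from seroscreen.cutoffs import CutoffRecord, SeroCallSet
from seroscreen.synthetic import CLINICAL_VARS, CYTOKINES

RESULTS = Path(__file__).resolve().parents[1] / "results"
ALPHA = 0.05


def main() -> None:
    calls_frame = pd.read_csv(RESULTS / "calls.csv", index_col=0)
    cutoffs = pd.read_csv(RESULTS / "cutoffs.csv")
    recs = [CutoffRecord(r.antigen_id, r.peak_x, r.direction, r.cutoff)
            for r in cutoffs.itertuples()]
    calls = SeroCallSet(cutoffs=recs, calls=calls_frame)
    clinical = pd.read_csv(RESULTS / "data" / "clinical.csv", index_col=0)

    s = count_distribution(calls)
    pi = s.per_individual
    print(f"autoantibody count per individual: median {pi['median']:.0f}, "
          f"mean {pi['mean']:.1f}, range {pi['range'][0]:.0f}-"
          f"{pi['range'][1]:.0f}, Shapiro-Wilk W={pi.get('shapiro_w', float('nan')):.3f} "
          f"(p={pi.get('shapiro_p', float('nan')):.3g})")

    strata = stratify_counts(calls.counts, 5, 95)
    print(f"low stratum: count < {strata.low_threshold:.0f} "
          f"(n={len(strata.low_ids)}); high stratum: count > "
          f"{strata.high_threshold:.0f} (n={len(strata.high_ids)})")
    pd.DataFrame({"individual_id": strata.low_ids + strata.high_ids,
                  "stratum": ["low"] * len(strata.low_ids)
                  + ["high"] * len(strata.high_ids)}
                 ).to_csv(RESULTS / "strata.csv", index=False)

    variables = [v for v in list(CLINICAL_VARS) + list(CYTOKINES)
                 if v in clinical.columns]
    tests = characterize_strata(strata, clinical, variables)
    for name, frame in tests.items():
        frame.to_csv(RESULTS / f"strata_{name}_tests.csv", index=False)
        hits = frame[frame.p < ALPHA]
        for row in hits.itertuples():
            print(f"  {name}-count group vs {row.variable}: "
                  f"p={row.p:.3f}, OR={row.odds_ratio:.2g} "
                  f"({row.ci_low:.2g}-{row.ci_high:.2g})")

    Z, order = cluster_profiles(calls.calls)
    (RESULTS / "dendrogram.json").write_text(
        json.dumps(dendrogram_json(Z, list(calls.calls.index))))
    print(f"clustered {len(order)} profiles "
          f"(max merge height {Z[-1, 2]:.1f})")


if __name__ == "__main__":
    main()
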
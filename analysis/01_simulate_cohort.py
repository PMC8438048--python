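#!/usr/bin/env python
"""Generate the synthetic study data.

Emulates the structure of a psychosis-cohort autoantibody study: a
461 x 380 bead-array MFI matrix with per-sample background level/scale and
sparse heavy-tailed seropositive spikes (~25 expected autoantibodies per
individual), a clinical table with 205 symptom indicators (six of them
carrying planted antibody-symptom associations), clinical covariates and
cytokines, and eight planar-array screening pools of 42,100 antigens.

Writes results/data/{mfi.csv, clinical.csv, truth.json, planar_pools.csv}.
"""

import argparse
from pathlib import Path

from seroscreen import CohortConfig, generate_cohort, generate_planar_pools

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    out = RESULTS / "data"
    cohort = generate_cohort(CohortConfig(seed=args.seed))
    cohort.write(out)
    print(f"cohort: {cohort.mfi.shape[0]} individuals x "
          f"{cohort.mfi.shape[1]} antigens, "
          f"{len(cohort.symptom_columns)} symptoms")
    print(f"planted associations: {cohort.planted_pairs}")
    print(f"expected autoantibody count per individual: "
          f"{cohort.truth.sum(axis=1).mean():.1f}")

    pools = generate_planar_pools(n_pools=8, n_antigens=42100,
                                  n_hits_per_pool=25, seed=args.seed + 1)
    pools.signals.to_csv(out / "planar_pools.csv", index_label="pool_id")
    print(f"planar pools: {pools.signals.shape[0]} pools x "
          f"{pools.signals.shape[1]} antigens, "
          f"{len(pools.planted_union)} distinct planted hits")


if __name__ == "__main__":
    main()
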
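#!/usr/bin/env python
"""Group-level planar-array screen.

Standardizes each screening pool to times-SD units and selects antigens at
or exceeding 8 SD above the pool mean — the broad screen that defines the
panel for the targeted bead-based assay.  Reports the union panel size and
the fraction of hits unique to a single pool.

Reads results/data/planar_pools.csv; writes results/planar_panel.csv.
"""

from pathlib import Path

import pandas as pd

from seroscreen import select_antigens

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pools = pd.read_csv(RESULTS / "data" / "planar_pools.csv", index_col=0)
    res = select_antigens(pools, threshold=8.0)
    res.to_frame().to_csv(RESULTS / "planar_panel.csv", index=False)
    per_pool = {p: len(v) for p, v in res.per_pool.items()}
    print(f"antigens at or above 8 SD in >= 1 pool: {len(res.union)}")
    print(f"per-pool hits: {per_pool}")
    print(f"fraction unique to one pool: {res.unique_fraction:.2f}")


if __name__ == "__main__":
    main()
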
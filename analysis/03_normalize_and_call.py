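#!/usr/bin/env python
"""Bead-array normalization and seropositivity calling.

Per-sample xMAD normalization (median/MAD with normal-consistency scaling),
discretization onto the 16-level score scale, per-antigen detection cutoffs
from the kernel-density peak/slope algorithm, and binary seropositivity
calls.  Reports how many antigens were detected at all and how sparse the
call matrix is among them.

Reads results/data/mfi.csv; writes results/{scores.csv, cutoffs.csv,
calls.csv, counts.csv}.
"""

import logging
from pathlib import Path

import pandas as pd

from seroscreen import call_seropositive, detect_cutoffs, score_matrix

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.disable(logging.WARNING)  # undetected antigens log constant-score
    mfi = pd.read_csv(RESULTS / "data" / "mfi.csv", index_col=0)
    sm = score_matrix(mfi)
    sm.scores.to_csv(RESULTS / "scores.csv")
    calls = call_seropositive(sm, detect_cutoffs(sm))
    calls.cutoff_frame().to_csv(RESULTS / "cutoffs.csv", index=False)
    calls.calls.to_csv(RESULTS / "calls.csv")
    calls.counts.rename("count").to_csv(RESULTS / "counts.csv")

    npos = calls.n_positive
    det = npos[npos > 0]
    print(f"antigens with >= 1 seropositive individual: "
          f"{len(det)} of {len(npos)}")
    print(f"sparsity among detected antigens: "
          f"{calls.sparsity_detected():.3f}")
    print(f"seropositive individuals per detected antigen: "
          f"median {det.median():.0f}, mean {det.mean():.1f}, "
          f"range {det.min()}-{det.max()}")


if __name__ == "__main__":
    main()
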
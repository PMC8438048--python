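"""Per-antigen detection cutoffs via the kernel-density peak/slope walk.

For each antigen, the cohort's score vector (461 values on the 16-level
scale in the original study) is smoothed with a Gaussian KDE.  Starting at
the tallest density peak, the algorithm walks the density curve — toward
higher scores when the peak sits at 0.75 or below, toward lower scores
otherwise — and stops at the first grid point where the directional slope
(density change per unit score along the traversal) falls below -0.5.  That
position, rounded up to the nearest 0.1 score step, is the detection cutoff;
individuals scoring at or above it are seropositive.

Kernel, bandwidth rule and grid are conventions, not part of the published
procedure, and are therefore configurable: Gaussian kernel, Silverman
bandwidth, 512 evaluation points spanning the data range padded by three
bandwidths.  One deliberate reading: the walk starts at the first grid point
strictly past the peak, so the peak itself can never be the found score.
Score vectors here are near-atomic (most mass on one or two adjacent score
levels), and at a sharp atom the discrete slope already exceeds |0.5| at the
peak's own grid point; admitting the peak would collapse the cutoff onto the
background atom on a floating-point coin flip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .normalize import SCORE_LEVELS, ScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_SLOPE_THRESHOLD = -0.5
DEFAULT_PEAK_SPLIT = 0.75
DEFAULT_GRID_SIZE = 512
DEFAULT_GRID_PAD_BW = 3.0


@dataclass(frozen=True)
class CutoffRecord:
    """Detection cutoff for one antigen."""

    antigen_id: object
    peak_x: float
    direction: str  # "up" | "down"
    cutoff: float
    n_positive: int = 0


def _round_up_step(x: float) -> float:
    """Round a score-scale position up to the nearest 0.1 step."""
    return math.ceil(round(x * 10, 6)) / 10


def detect_cutoff(scores,
                  antigen_id=None,
                  slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
                  peak_split: float = DEFAULT_PEAK_SPLIT,
                  grid_size: int = DEFAULT_GRID_SIZE,
                  bw_method="silverman",
                  clamp: tuple[float, float] = (0.0, 1.5)) -> CutoffRecord:
    """Run the density peak/slope walk on one antigen's score vector.

    A constant score vector has no density curve; the cutoff is then placed
    one step above the constant value (all individuals seronegative) with a
    logged warning, and deliberately not clamped so that a constant 1.5
    still yields zero positives.  A walk that reaches the grid end without
    crossing the slope threshold uses the grid end, logged.
    """
    v = np.asarray(scores, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("score vector must be 1-D with length >= 2")

    if np.ptp(v) == 0:
        cut = _round_up_step(v[0] + 0.1)
        logger.warning(
            "antigen %r: constant score vector (%.1f); cutoff set above it at %.1f",
            antigen_id, v[0], cut)
        return CutoffRecord(antigen_id=antigen_id, peak_x=float(v[0]),
                            direction="up", cutoff=cut)

    kde = gaussian_kde(v, bw_method=bw_method)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo, hi = v.min() - DEFAULT_GRID_PAD_BW * bw, v.max() + DEFAULT_GRID_PAD_BW * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    dx = grid[1] - grid[0]

    k = int(np.argmax(dens))  # ties: first (lowest x), deterministic
    peak_x = float(grid[k])
    direction = "up" if peak_x <= peak_split else "down"

    crossing = None
    if direction == "up":
        for j in range(k + 1, grid_size):
            if (dens[j] - dens[j - 1]) / dx < slope_threshold:
                crossing = grid[j]
                break
        if crossing is None:
            crossing = grid[-1]
            logger.warning("antigen %r: slope never crossed %.2f walking up; "
                           "using grid end", antigen_id, slope_threshold)
    else:
        for j in range(k - 1, -1, -1):
            if (dens[j] - dens[j + 1]) / dx < slope_threshold:
                crossing = grid[j]
                break
        if crossing is None:
            crossing = grid[0]
            logger.warning("antigen %r: slope never crossed %.2f walking down; "
                           "using grid end", antigen_id, slope_threshold)

    cut = _round_up_step(float(crossing))
    cut = min(max(cut, clamp[0]), clamp[1])
    return CutoffRecord(antigen_id=antigen_id, peak_x=peak_x,
                        direction=direction, cutoff=cut)


def detect_cutoffs(score_matrix: ScoreMatrix, **kwargs) -> list[CutoffRecord]:
    """Apply :func:`detect_cutoff` to every antigen column of a score matrix."""
    scores = score_matrix.scores
    return [detect_cutoff(scores[a].to_numpy(), antigen_id=a, **kwargs)
            for a in scores.columns]


class SeroCallSet:
    """Per-antigen cutoffs, the binary call matrix and per-individual counts."""

    def __init__(self, cutoffs: list[CutoffRecord], calls: pd.DataFrame):
        self.calls = calls
        self.cutoffs = [
            CutoffRecord(antigen_id=r.antigen_id, peak_x=r.peak_x,
                         direction=r.direction, cutoff=r.cutoff,
                         n_positive=int(calls[r.antigen_id].sum()))
            for r in cutoffs
        ]

    @property
    def counts(self) -> pd.Series:
        """Autoantibody count: number of positive calls per individual."""
        return self.calls.sum(axis=1)

    @property
    def n_positive(self) -> pd.Series:
        """Seropositive individuals per antigen."""
        return self.calls.sum(axis=0)

    @property
    def detected(self) -> pd.Index:
        """Antigens with at least one seropositive individual."""
        npos = self.n_positive
        return npos.index[npos > 0]

    def sparsity_detected(self) -> float:
        """Fraction of negative cells among detected antigens."""
        det = self.detected
        if len(det) == 0:
            return float("nan")
        sub = self.calls[det]
        return float(1.0 - sub.to_numpy().mean())

    def cutoff_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"antigen_id": r.antigen_id, "peak_x": r.peak_x,
              "direction": r.direction, "cutoff": r.cutoff,
              "n_positive": r.n_positive} for r in self.cutoffs])


def call_seropositive(score_matrix: ScoreMatrix,
                      cutoffs: list[CutoffRecord]) -> SeroCallSet:
    """Binary seropositivity calls: score at or above the antigen's cutoff.

    Every antigen in the score matrix must have a cutoff record; comparison
    is inclusive (a score exactly at the cutoff is positive).
    """
    scores = score_matrix.scores
    by_id = {r.antigen_id: r.cutoff for r in cutoffs}
    missing = [a for a in scores.columns if a not in by_id]
    if missing:
        raise ValueError(f"no cutoff for antigens: {missing[:5]}")
    # scores and cutoffs are exact tenths; compare on integer tenths
    s10 = np.round(scores.to_numpy() * 10).astype(int)
    c10 = np.array([round(by_id[a] * 10) for a in scores.columns])
    calls = pd.DataFrame((s10 >= c10[None, :]).astype(int),
                         index=scores.index, columns=scores.columns)
    return SeroCallSet(cutoffs=[r for r in cutoffs if r.antigen_id in set(scores.columns)],
                       calls=calls)
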
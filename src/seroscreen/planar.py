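"""Group-level screening on planar protein microarrays.

Each planar array (one per plasma pool) is standardized over all of its
antigens, ``times SD = (X - mean(X)) / SD(X)`` with the sample SD (n-1
denominator), and antigens at or exceeding a times-SD threshold (default 8)
in at least one pool are selected for the follow-up bead-array panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SD_THRESHOLD = 8.0


class ZeroVarianceError(ValueError):
    """Raised when an array's signals have zero variance (undefined transform)."""


def times_sd(signals) -> np.ndarray:
    """Standardize a raw-intensity vector to times-SD units.

    Uses the sample SD (n-1 denominator).  Output has mean 0 and SD 1 to
    numerical tolerance, order preserved.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("times_sd requires a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signals must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero-variance signal vector: times SD undefined")
    return (x - x.mean()) / sd


@dataclass
class ScreenResult:
    """Per-pool standardized signals and the antigens they select."""

    times_sd: pd.DataFrame  # pools x antigens, in times-SD units
    threshold: float
    per_pool: dict[str, list] = field(default_factory=dict)
    union: list = field(default_factory=list)

    @property
    def unique_fraction(self) -> float:
        """Fraction of the union panel detected in exactly one pool."""
        if not self.union:
            return float("nan")
        hits = (self.times_sd[self.union] >= self.threshold).sum(axis=0)
        return float((hits == 1).sum() / len(self.union))

    def to_frame(self) -> pd.DataFrame:
        """Union panel as a table: antigen, pools detecting it, max times-SD."""
        rows = []
        for a in self.union:
            col = self.times_sd[a]
            pools = [p for p in col.index if col[p] >= self.threshold]
            rows.append({"antigen_id": a, "pools": ";".join(map(str, pools)),
                         "max_times_sd": float(col.max())})
        return pd.DataFrame(rows, columns=["antigen_id", "pools", "max_times_sd"])


def select_antigens(pools: pd.DataFrame,
                    threshold: float = DEFAULT_SD_THRESHOLD) -> ScreenResult:
    """Standardize each pool and select antigens with times-SD >= threshold.

    Parameters
    ----------
    pools
        Pools x antigens matrix of raw intensities (one row per planar array).
    threshold
        Selection threshold in times-SD units; "at or exceeding" is inclusive.

    Returns a :class:`ScreenResult` with per-pool selections and their union.
    An empty input yields an empty result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if pools.shape[0] == 0 or pools.shape[1] == 0:
        empty = pd.DataFrame(index=pools.index, columns=pools.columns, dtype=float)
        return ScreenResult(times_sd=empty, threshold=threshold)

    std = pd.DataFrame(
        np.vstack([times_sd(pools.loc[p].to_numpy()) for p in pools.index]),
        index=pools.index, columns=pools.columns,
    )
    per_pool = {
        p: [a for a in pools.columns if std.at[p, a] >= threshold]
        for p in pools.index
    }
    seen: dict = {}
    for p in pools.index:
        for a in per_pool[p]:
            seen.setdefault(a, None)
    return ScreenResult(times_sd=std, threshold=threshold,
                        per_pool=per_pool, union=list(seen))
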
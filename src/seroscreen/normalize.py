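"""Per-sample robust normalization of bead-array MFI and the 16-level score scale.

Bead-based suspension arrays report one median fluorescence intensity (MFI)
per (sample, antigen) pair.  Absolute MFI is dominated by sample-specific
background level and scale, so each sample is normalized with its own robust
location/scale::

    xMAD = (MFI - median(MFI)) / mad(MFI)

where the median and MAD are taken over all antigens of that sample.  The
MAD carries the normal-consistency factor 1.4826 by default so that xMAD is
a robust z-score under Gaussian background.

Normalized values are then discretized onto a 16-level score scale
{0, 0.1, ..., 1.5}: negative xMAD scores 0, each further band of 5 xMAD
units adds one score step, and everything at or above 70 scores 1.5.  Bins
are closed below and open above, so xMAD = 0 scores 0.1 and xMAD = 5 scores
0.2.  Scores are exact decimals (integer tenths internally), which keeps
bin-edge comparisons free of floating-point artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Normal-consistency factor: MAD * 1.4826 estimates the SD under normality.
MAD_SCALE = 1.4826

#: The 16 attainable score levels.
SCORE_LEVELS = tuple(round(k / 10, 1) for k in range(16))

#: Width of one xMAD band per score step above zero.
XMAD_BAND = 5.0


class DegenerateSampleError(ValueError):
    """Raised when a sample's MAD is zero, making xMAD undefined."""


def xmad_normalize(mfi: pd.DataFrame, scaled_mad: bool = True) -> pd.DataFrame:
    """Normalize an MFI matrix (rows = samples, columns = antigens) per sample.

    Parameters
    ----------
    mfi
        Samples x antigens matrix of non-negative fluorescence intensities.
    scaled_mad
        If True (default) the MAD is multiplied by the normal-consistency
        factor 1.4826; if False the raw MAD is used.

    Returns
    -------
    DataFrame of the same shape with each row transformed to
    ``(value - row median) / row MAD``.  Every row of the result has median 0.

    Raises
    ------
    DegenerateSampleError
        If any sample row has MAD = 0 (fewer than two distinct values, or a
        pathological majority tie); the message names the sample.
    """
    values = np.asarray(mfi, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("MFI matrix must be 2-D with at least two antigens")
    if not np.all(np.isfinite(values)):
        raise ValueError("MFI matrix contains non-finite values")

    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    zero = np.flatnonzero(mad.ravel() == 0)
    if zero.size:
        name = mfi.index[zero[0]] if isinstance(mfi, pd.DataFrame) else zero[0]
        raise DegenerateSampleError(
            f"sample {name!r} has zero MAD; xMAD is undefined for it"
        )
    if scaled_mad:
        mad = mad * MAD_SCALE
    xmad = (values - med) / mad
    if isinstance(mfi, pd.DataFrame):
        return pd.DataFrame(xmad, index=mfi.index, columns=mfi.columns)
    return pd.DataFrame(xmad)


def score(xmad: float | np.ndarray | pd.DataFrame):
    """Map xMAD values onto the 16-level score scale.

    ``x < 0 -> 0``; ``0 <= x < 5 -> 0.1``; ...; ``65 <= x < 70 -> 1.4``;
    ``x >= 70 -> 1.5``.  Total on finite reals; vectorized.
    """
    arr = np.asarray(xmad, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("score() requires finite input")
    if np.ndim(xmad) == 0:
        x = float(arr)
        if x < 0:
            return 0.0
        return min(int(x // XMAD_BAND) + 1, 15) / 10.0
    levels = np.clip(np.floor(arr / XMAD_BAND).astype(np.int64) + 1, 0, 15)
    out = np.round(np.where(arr < 0, 0, levels) / 10.0, 1)
    if isinstance(xmad, pd.DataFrame):
        return pd.DataFrame(out, index=xmad.index, columns=xmad.columns)
    return out


def score_matrix(mfi: pd.DataFrame, scaled_mad: bool = True) -> "ScoreMatrix":
    """Convenience: normalize an MFI matrix and bin it in one step."""
    xmad = xmad_normalize(mfi, scaled_mad=scaled_mad)
    return ScoreMatrix(xmad=xmad, scores=score(xmad))


class ScoreMatrix:
    """Paired per-sample normalized (xMAD) and binned (score) matrices."""

    def __init__(self, xmad: pd.DataFrame, scores: pd.DataFrame):
        if xmad.shape != scores.shape:
            raise ValueError("xmad and scores must have identical shape")
        self.xmad = xmad
        self.scores = scores

    @property
    def sample_ids(self):
        return self.scores.index

    @property
    def antigen_ids(self):
        return self.scores.columns
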
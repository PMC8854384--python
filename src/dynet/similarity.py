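"""Temporal-similarity statistics of brain state configurations.

Two scalar summaries of how much a subject's brain pattern reconfigures
over the scan:

* local similarity ``S_L`` — the mean Pearson correlation between the
  patterns of every pair of *contiguous* epochs.  High values mean the
  configuration barely changes from one epoch to the next (stationary
  dynamics).
* global similarity ``S_G`` — the mean *absolute* correlation between
  all epoch pairs.  High values mean a small repertoire of
  configurations recurring over the whole scan.

Patterns can be either the raw activity vector at each TR
(``mode="activity"``) or the vectorised upper triangle of each windowed
connectivity matrix (``mode="connectivity"``); both are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ParcelTimeSeries
from .mtd import DynamicConnectivity

__all__ = [
    "SimilarityResult",
    "epoch_patterns",
    "similarity_matrix",
    "local_similarity",
    "global_similarity",
    "compute_similarity",
]

Mode = Literal["activity", "connectivity"]


@dataclass
class SimilarityResult:
    n: int
    r_matrix: np.ndarray
    s_local: float
    s_global: float
    mode: str


def epoch_patterns(
    ts: ParcelTimeSeries | None = None,
    dc: DynamicConnectivity | None = None,
    mode: Mode = "activity",
) -> np.ndarray:
    """One pattern vector per epoch, as an ``(n_epochs, p)`` array.

    ``activity`` mode returns the regions-long BOLD vector at each TR;
    ``connectivity`` mode returns the upper triangle (``i < j``,
    row-major order) of each window's coupling matrix.
    """
    if mode == "activity":
        if ts is None:
            raise ValueError("activity mode requires a ParcelTimeSeries")
        return ts.data.T.copy()
    if mode == "connectivity":
        if dc is None:
            raise ValueError("connectivity mode requires a DynamicConnectivity")
        iu = np.triu_indices(dc.n_regions, k=1)
        return dc.tensor[iu[0], iu[1], :].T.copy()
    raise ValueError(f"unknown mode {mode!r}")


def similarity_matrix(patterns: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between epoch patterns.

    Symmetric with unit diagonal.  A zero-variance pattern has no
    defined correlation and raises, naming the offending epoch.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("need at least 2 patterns")
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance pattern at epoch(s) {bad[:5].tolist()}")
    r = np.corrcoef(patterns)
    np.fill_diagonal(r, 1.0)
    return r


def local_similarity(r_matrix: np.ndarray) -> float:
    """Mean correlation between contiguous epochs (first off-diagonal)."""
    r_matrix = np.asarray(r_matrix)
    n = r_matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 epochs")
    return float(np.diagonal(r_matrix, offset=1).mean())


def global_similarity(r_matrix: np.ndarray) -> float:
    """Mean absolute correlation over all epoch pairs.

    Computed as ``(sum |r| - n) / (n (n - 1))``: the diagonal-inclusive
    sum of absolute correlations minus the ``n`` unit diagonal terms,
    normalised by the number of ordered off-diagonal pairs.  Equal to the
    mean absolute off-diagonal correlation; lies in [0, 1].
    """
    r_matrix = np.asarray(r_matrix)
    n = r_matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 epochs")
    return float((np.abs(r_matrix).sum() - n) / (n * (n - 1)))


def compute_similarity(
    ts: ParcelTimeSeries | None = None,
    dc: DynamicConnectivity | None = None,
    mode: Mode = "activity",
) -> SimilarityResult:
    """Convenience wrapper: patterns -> correlation matrix -> S_L, S_G."""
    patterns = epoch_patterns(ts=ts, dc=dc, mode=mode)
    r = similarity_matrix(patterns)
    return SimilarityResult(
        n=r.shape[0],
        r_matrix=r,
        s_local=local_similarity(r),
        s_global=global_similarity(r),
        mode=mode,
    )
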
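"""Time-resolved functional connectivity by multiplication of temporal
derivatives (MTD).

The MTD score between two regions at derivative sample ``t`` is the
product of their SD-normalised first differences, smoothed with a simple
moving average over a sliding window (15 samples by default, ~45 s at
TR = 3 s).  Windowing is "valid": only windows fully inside the
derivative series are produced, so a series of ``T`` timepoints yields
``T - window`` windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParcelTimeSeries

__all__ = ["DynamicConnectivity", "temporal_derivative", "mtd_tensor", "time_average"]

DEFAULT_WINDOW = 15


@dataclass
class DynamicConnectivity:
    """Regions x regions x windows tensor of coupling scores.

    Each windowed slice is symmetric with a zeroed diagonal; the diagonal
    is excluded from all downstream graph computations.  ``window_centres``
    gives the midpoint of each window in original sample index units.
    """

    tensor: np.ndarray
    window_length: int
    window_centres: np.ndarray
    parcel_labels: list[str]

    @property
    def n_regions(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_windows(self) -> int:
        return self.tensor.shape[2]


def temporal_derivative(ts: ParcelTimeSeries) -> np.ndarray:
    """First difference per region, normalised by its own standard deviation.

    The SD is the population SD of the derivative series over the whole
    scan (not per window), so scores are comparable across windows.  A
    region whose derivative has zero variance is degenerate and raises.
    """
    d = np.diff(ts.data, axis=1)
    sd = d.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.parcel_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance derivative in region(s): {names}")
    return d / sd[:, None]


def mtd_tensor(ts: ParcelTimeSeries, window: int = DEFAULT_WINDOW) -> DynamicConnectivity:
    """Sliding-window MTD tensor.

    Raw coupling ``(i, j, t)`` is the product of the two normalised
    derivatives at sample ``t``; the windowed score is its rectangular
    moving average over ``window`` consecutive derivative samples.
    """
    d = temporal_derivative(ts)
    n_d = d.shape[1]
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_d < window:
        raise ValueError(
            f"window {window} too long for {ts.n_timepoints} timepoints; "
            f"maximum feasible window is {n_d}"
        )
    raw = d[:, None, :] * d[None, :, :]
    csum = np.concatenate(
        [np.zeros(raw.shape[:2] + (1,)), np.cumsum(raw, axis=2)], axis=2
    )
    win = (csum[:, :, window:] - csum[:, :, :-window]) / window
    idx = np.arange(win.shape[2], dtype=float)
    # derivative sample t sits between samples t and t+1 of the original series
    centres = idx + (window - 1) / 2.0 + 0.5
    for t in range(win.shape[2]):
        np.fill_diagonal(win[:, :, t], 0.0)
    return DynamicConnectivity(
        tensor=win,
        window_length=window,
        window_centres=centres,
        parcel_labels=list(ts.parcel_labels),
    )


def time_average(dc: DynamicConnectivity) -> np.ndarray:
    """Mean coupling matrix over windows (time-averaged connectivity)."""
    if dc.n_windows < 1:
        raise ValueError("need at least one window")
    return dc.tensor.mean(axis=2)
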
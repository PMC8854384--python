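"""Quality control and temporal filtering of parcellated time series.

The stage order is fixed: motion/signal QC (framewise displacement and
DVARS) on the raw series, then nuisance regression, then a zero-phase
band-pass filter.  Everything operates on the regions-by-time matrix and
preserves its shape and labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import MotionParams, ParcelTimeSeries

__all__ = [
    "QCSeries",
    "framewise_displacement",
    "dvars",
    "flag_exceedance",
    "nuisance_regress",
    "bandpass",
]

FD_THRESHOLD_MM = 0.25
DVARS_THRESHOLD_PCT = 2.5
EXCLUSION_FRACTION = 0.10


@dataclass
class QCSeries:
    """Per-frame scan-quality metrics.

    ``fd`` is framewise displacement in mm (Power convention: sum of
    absolute backward differences of the six realignment parameters,
    rotations converted to arc length at the head radius).  ``dvars`` is
    the RMS frame-to-frame signal change as a percentage of the
    grand-mean signal.  Both are defined as 0 at the first frame.
    """

    fd: np.ndarray
    dvars: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape:
            raise ValueError("fd and dvars must be aligned")
        if np.any(self.fd < 0) or np.any(self.dvars < 0):
            raise ValueError("fd and dvars must be non-negative")


def framewise_displacement(
    motion: MotionParams, head_radius: float = 50.0
) -> np.ndarray:
    """Framewise displacement (mm) from rigid-body parameters.

    ``FD(t) = sum_k |delta p_k(t)|`` over the six parameters, with the
    three rotation increments expressed as arc length at ``head_radius``
    mm.  ``FD(0) = 0`` by convention.
    """
    p = motion.params.copy()
    p[:, 3:] *= head_radius
    if p.shape[0] < 2:
        return np.zeros(p.shape[0])
    fd = np.abs(np.diff(p, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(ts: ParcelTimeSeries) -> np.ndarray:
    """RMS frame-to-frame signal change as % of the grand-mean signal.

    The reference is the grand mean of the (unfiltered) series; a zero
    grand mean leaves the percent scale undefined and raises.
    """
    grand_mean = ts.data.mean()
    if abs(grand_mean) < 1e-12:
        raise ValueError("grand-mean signal is zero; DVARS percentage undefined")
    diff = np.diff(ts.data, axis=1)
    rms = np.sqrt((diff**2).mean(axis=0))
    out = 100.0 * rms / abs(grand_mean)
    return np.concatenate([[0.0], out])


@dataclass
class ExceedanceResult:
    qc: QCSeries
    fraction: float
    excluded: bool


def flag_exceedance(
    qc: QCSeries,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD_PCT,
    exclusion_fraction: float = EXCLUSION_FRACTION,
) -> ExceedanceResult:
    """Flag frames exceeding either QC threshold; mark subjects to exclude.

    A frame is flagged when FD > ``fd_thresh`` mm or DVARS >
    ``dvars_thresh`` %.  A subject is marked for exclusion when the
    flagged fraction strictly exceeds ``exclusion_fraction`` of frames.
    """
    flags = (qc.fd > fd_thresh) | (qc.dvars > dvars_thresh)
    fraction = float(flags.mean()) if flags.size else 0.0
    out = QCSeries(fd=qc.fd, dvars=qc.dvars, flags=flags)
    return ExceedanceResult(qc=out, fraction=fraction, excluded=fraction > exclusion_fraction)


def nuisance_regress(
    ts: ParcelTimeSeries, regressors: np.ndarray | None = None
) -> ParcelTimeSeries:
    """OLS residuals of each region on an intercept plus ``regressors``.

    ``regressors`` has one row per frame.  Rank-deficient designs are
    tolerated (a warning is emitted and the minimum-norm solution used;
    residuals are unaffected by which collinear column is dropped).
    With no regressors this demeans each region.
    """
    n_t = ts.n_timepoints
    if regressors is None or (hasattr(regressors, "size") and regressors.size == 0):
        design = np.ones((n_t, 1))
    else:
        regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
        if regressors.shape[0] != n_t:
            if regressors.shape[1] == n_t:
                regressors = regressors.T
            else:
                raise ValueError(
                    f"regressors have {regressors.shape[0]} rows for "
                    f"{n_t} timepoints"
                )
        design = np.column_stack([np.ones(n_t), regressors])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "rank-deficient nuisance design; collinear columns are "
                "redundant and effectively dropped",
                stacklevel=2,
            )
    beta, *_ = np.linalg.lstsq(design, ts.data.T, rcond=None)
    resid = ts.data.T - design @ beta
    return ts.with_data(resid.T)


def bandpass(
    ts: ParcelTimeSeries,
    low: float = 0.071,
    high: float = 0.125,
    order: int = 4,
) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass filter.

    Defaults to the 0.071–0.125 Hz band conventional for time-resolved
    connectivity at TR = 3 s.  Applied forward–backward (``sosfiltfilt``)
    so filtering cannot shift connectivity timing.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"band edge {high} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz for sampling interval {ts.sampling_interval} s"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=1.0 / ts.sampling_interval, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=1)
    return ts.with_data(filtered)
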
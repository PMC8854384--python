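"""Core data containers shared across the pipeline.

The pipeline operates on parcellated BOLD time series: one matrix per
subject with one row per cortical parcel (e.g. the 333 regions of the
Gordon atlas) and one column per imaging volume (TR).  All downstream
modules preserve this regions-by-time orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ParcelTimeSeries", "MotionParams"]


@dataclass
class ParcelTimeSeries:
    """A single subject's parcellated BOLD time series.

    Parameters
    ----------
    subject_id:
        Free-form subject identifier.
    data:
        ``(n_regions, n_timepoints)`` float array in arbitrary BOLD units.
    sampling_interval:
        Repetition time (TR) in seconds.
    parcel_labels:
        One unique label per region, in row order.
    """

    subject_id: str
    data: np.ndarray
    sampling_interval: float
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (regions x timepoints) array")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains missing or non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        self.parcel_labels = [str(x) for x in self.parcel_labels]
        if len(self.parcel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.parcel_labels)} parcel labels for "
                f"{self.data.shape[0]} regions"
            )
        if len(set(self.parcel_labels)) != len(self.parcel_labels):
            raise ValueError("parcel labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcelTimeSeries":
        """Return a copy carrying ``data`` but the same metadata."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class MotionParams:
    """Per-frame rigid-body realignment parameters.

    ``params`` has one row per frame and six columns: three translations
    (mm) followed by three rotations (radians).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                "motion parameters must have 6 columns "
                "(3 translations mm, 3 rotations rad); "
                f"got shape {self.params.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]
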
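"""Flat-file readers and writers for the pipeline's tabular formats.

Everything is plain text for inspectability: parcel time series as TSV
(regions as rows, a ``parcel`` label column, one column per timepoint),
motion as 6-column whitespace-delimited text, SART trials and expression
tables as CSV, and a cohort manifest CSV tying the files together.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MotionParams, ParcelTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "write_expression",
    "read_expression",
]


def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        ts.data,
        index=pd.Index(ts.parcel_labels, name="parcel"),
        columns=[f"t{j:04d}" for j in range(ts.n_timepoints)],
    )
    df.to_csv(path, sep="\t")


def read_timeseries(
    path: str | Path, subject_id: str | None = None, sampling_interval: float = 3.0
) -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ParcelTimeSeries(
        subject_id=subject_id or Path(path).stem,
        data=df.to_numpy(dtype=float),
        sampling_interval=sampling_interval,
        parcel_labels=[str(x) for x in df.index],
    )


def write_motion(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(path, motion.params, fmt="%.8f")


def read_motion(path: str | Path) -> MotionParams:
    return MotionParams(np.loadtxt(str(path), ndmin=2))


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("region_id").to_csv(path)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="region_id")
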
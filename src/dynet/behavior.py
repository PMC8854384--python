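"""Sustained-attention behaviour: summary statistics and the closed-form
drift-diffusion fit.

The fit inverts the simple three-parameter diffusion model from exactly
three moments — accuracy, mean correct RT and correct-RT variance — via
the standard closed-form method-of-moments solution, yielding drift rate
(processing efficiency), boundary separation (response caution) and
non-decision time (sensorimotor overhead).  The diffusion coefficient is
fixed (default 0.1, the conventional scaling) to resolve the model's
scale indeterminacy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BehavioralSummary", "DDMParams", "summarise_trials", "fit_ddm", "predict_moments"]


@dataclass
class BehavioralSummary:
    """Moments of one subject's Go/No-Go performance.

    ``accuracy`` is the raw proportion correct; ``accuracy_adj`` applies
    the standard ``1/(2n)`` edge correction when the raw value is exactly
    0, 0.5 or 1 (those values make the moment inversion singular).
    RT moments are over correct trials only.
    """

    mean_rt: float
    var_rt: float
    accuracy: float
    n_trials: int
    accuracy_adj: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.var_rt < 0:
            raise ValueError("var_rt must be non-negative")
        if not 0 <= self.accuracy <= 1:
            raise ValueError("accuracy must be in [0, 1]")
        if self.accuracy_adj is None:
            self.accuracy_adj = _edge_correct(self.accuracy, self.n_trials)


def _edge_correct(acc: float, n: int) -> float:
    """Nudge accuracies of exactly 0, 0.5 or 1 off the singular points."""
    eps = 1.0 / (2 * n) if n > 0 else 1e-4
    if acc == 1.0:
        return 1.0 - eps
    if acc == 0.0:
        return eps
    if acc == 0.5:
        return 0.5 + eps
    return acc


@dataclass
class DDMParams:
    drift: float  # evidence units per second
    boundary: float  # evidence units
    nondecision: float  # seconds

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.nondecision < -1e-9:
            warnings.warn(
                f"fitted non-decision time is negative ({self.nondecision:.3f} s)",
                stacklevel=2,
            )


def summarise_trials(trials: pd.DataFrame) -> BehavioralSummary:
    """Mean/variance of correct-trial RTs plus (edge-corrected) accuracy.

    ``trials`` needs ``rt`` (seconds) and ``correct`` (0/1) columns;
    omitted trials should already be excluded.
    """
    if not {"rt", "correct"} <= set(trials.columns):
        raise ValueError("trials table needs 'rt' and 'correct' columns")
    correct = trials["correct"].astype(bool)
    rts = trials.loc[correct, "rt"].to_numpy(dtype=float)
    if rts.size < 2:
        raise ValueError("need at least 2 correct trials")
    n = len(trials)
    return BehavioralSummary(
        mean_rt=float(rts.mean()),
        var_rt=float(rts.var(ddof=1)),
        accuracy=float(correct.mean()),
        n_trials=n,
    )


def fit_ddm(summary: BehavioralSummary, noise_scale: float = 0.1) -> DDMParams:
    """Closed-form moment inversion of the simple diffusion model.

    Drift comes from accuracy and RT variance, boundary from drift and
    accuracy, and non-decision time is the mean RT minus the predicted
    mean decision time.  Exact inverse of :func:`predict_moments`.
    """
    pc = summary.accuracy_adj
    if pc in (0.0, 0.5, 1.0):
        raise ValueError(
            "accuracy at an edge value; summarise_trials applies the "
            "required edge correction"
        )
    if summary.var_rt <= 0:
        raise ValueError("zero RT variance; drift undefined")
    s = noise_scale
    s2 = s * s
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / summary.var_rt
    drift = math.copysign(1.0, pc - 0.5) * s * x**0.25
    boundary = s2 * L / drift
    y = math.exp(-drift * boundary / s2)
    mdt = (boundary / (2.0 * drift)) * (1.0 - y) / (1.0 + y)
    return DDMParams(drift=drift, boundary=boundary, nondecision=summary.mean_rt - mdt)


def predict_moments(params: DDMParams, noise_scale: float = 0.1) -> BehavioralSummary:
    """Predicted accuracy, mean RT and RT variance of the diffusion model.

    The algebraic forward map inverted exactly by :func:`fit_ddm`
    (round trips agree to floating-point precision).
    """
    s = noise_scale
    s2 = s * s
    L = params.drift * params.boundary / s2
    pc = 1.0 / (1.0 + math.exp(-L))
    y = math.exp(-L)
    mdt = (params.boundary / (2.0 * params.drift)) * (1.0 - y) / (1.0 + y)
    var = L * (L * pc * pc - L * pc + pc - 0.5) * (s / params.drift) ** 4
    return BehavioralSummary(
        mean_rt=params.nondecision + mdt,
        var_rt=var,
        accuracy=pc,
        n_trials=0,
        accuracy_adj=pc,
    )
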
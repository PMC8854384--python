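"""Synthetic cohort generator.

No public dataset accompanies the clinical study this pipeline was built
for, so every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes:

* parcellated BOLD time series whose connectivity switches between
  modular hidden "states" (a hidden-Markov construction with geometric
  dwell times), with group-controlled dwell time, modular coupling and
  noise;
* rigid-body head-motion traces with optional displacement spikes of
  known size at known frames (to exercise FD/DVARS quality control);
* trial-level Go/No-Go reaction-time data from a first-passage diffusion
  process;
* spatially smooth region-by-gene expression maps with an optional gene
  planted at a chosen Spearman correlation against a target map.

Every generator is a pure function of its specification plus a seed, and
ground truth (hidden state sequences, spike frames, planted genes, true
diffusion parameters) is returned alongside the data so recovery can be
tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import ndtri
from scipy.stats import spearmanr

from .core import MotionParams, ParcelTimeSeries

__all__ = [
    "StateModel",
    "CohortSpec",
    "GroupSpec",
    "DiffusionSpec",
    "SubjectSimulation",
    "SimulatedSubject",
    "SimulatedMotion",
    "SartTrials",
    "SimulatedExpression",
    "simulate_subject",
    "simulate_cohort",
    "simulate_motion",
    "simulate_sart",
    "simulate_expression",
    "two_state_partitions",
    "control_like_model",
    "dlb_like_model",
    "demo_cohort_spec",
]


# ---------------------------------------------------------------------------
# hidden-state BOLD model
# ---------------------------------------------------------------------------


@dataclass
class StateModel:
    """Hidden-state generative model for one subject's parcel time series.

    The subject's brain wanders through ``n_states`` connectivity states.
    Within a state, each sample is drawn from a zero-mean Gaussian whose
    correlation is compound-symmetric per module block: ``within_coupling``
    for same-module region pairs and ``between_coupling`` otherwise
    (``between_coupling`` may be given per state to let integration vary
    across states).  Dwell times are geometric with mean ``dwell_mean``
    samples; white observation noise with standard deviation ``noise_sd``
    is added on top, as is a constant ``baseline`` so that percent-scale
    quality-control metrics (DVARS) are well defined.
    """

    n_regions: int
    n_states: int
    module_partitions: Sequence[np.ndarray]
    within_coupling: float
    between_coupling: float | Sequence[float]
    dwell_mean: float
    noise_sd: float
    seed: int = 0
    baseline: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be positive")
        if len(self.module_partitions) != self.n_states:
            raise ValueError(
                f"{len(self.module_partitions)} partitions for "
                f"{self.n_states} states"
            )
        self.module_partitions = [
            np.asarray(p, dtype=int) for p in self.module_partitions
        ]
        for k, part in enumerate(self.module_partitions):
            if part.shape != (self.n_regions,):
                raise ValueError(
                    f"state {k}: partition must assign every region exactly "
                    f"once (expected length {self.n_regions}, got {part.shape})"
                )
        between = np.broadcast_to(
            np.asarray(self.between_coupling, dtype=float), (self.n_states,)
        ).copy()
        self._between_per_state = between
        if not 0 <= self.within_coupling < 1:
            raise ValueError("within_coupling must be in [0, 1)")
        if np.any(between < 0) or np.any(between >= 1):
            raise ValueError("between_coupling must be in [0, 1)")
        if np.any(between > self.within_coupling):
            raise ValueError("between_coupling must not exceed within_coupling")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # precompute and PSD-check per-state signal covariances
        self._chols: list[np.ndarray] = []
        for k in range(self.n_states):
            cov = self.state_covariance(k)
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-10:
                raise ValueError(
                    f"state {k}: implied covariance is not positive "
                    f"semi-definite (min eigenvalue {w.min():.3g})"
                )
            # tiny jitter guards the Cholesky of a PSD-but-singular matrix
            self._chols.append(
                np.linalg.cholesky(cov + 1e-12 * np.eye(self.n_regions))
            )

    def state_covariance(self, state: int) -> np.ndarray:
        """Signal covariance of one state (unit variance per region)."""
        part = self.module_partitions[state]
        same = part[:, None] == part[None, :]
        b = self._between_per_state[state]
        cov = np.where(same, self.within_coupling, b)
        np.fill_diagonal(cov, 1.0)
        return cov


@dataclass
class SubjectSimulation:
    """One simulated subject: time series plus generative ground truth."""

    ts: ParcelTimeSeries
    states: np.ndarray  # hidden state index per timepoint
    model: StateModel


def _sample_states(
    rng: np.random.Generator, n_states: int, dwell_mean: float, n: int
) -> np.ndarray:
    """Geometric-dwell hidden state path (memoryless switching)."""
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(n_states)
    p_switch = 1.0 / dwell_mean
    for t in range(1, n):
        s = states[t - 1]
        if n_states > 1 and rng.random() < p_switch:
            other = rng.integers(n_states - 1)
            s = other if other < s else other + 1
        states[t] = s
    return states


def simulate_subject(
    model: StateModel,
    n_timepoints: int,
    sampling_interval: float = 3.0,
    subject_id: str = "sim",
) -> SubjectSimulation:
    """Draw one subject from the hidden-state model.

    Samples are conditionally independent given the hidden state; the
    state path uses geometric dwells with mean ``model.dwell_mean``.
    Identical seeds give bit-identical output.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(model.seed)
    states = _sample_states(rng, model.n_states, model.dwell_mean, n_timepoints)
    z = rng.standard_normal((model.n_regions, n_timepoints))
    data = np.empty((model.n_regions, n_timepoints))
    for k in range(model.n_states):
        idx = states == k
        if idx.any():
            data[:, idx] = model._chols[k] @ z[:, idx]
    data += model.noise_sd * rng.standard_normal(data.shape)
    data += model.baseline
    labels = [f"R{i:03d}" for i in range(model.n_regions)]
    ts = ParcelTimeSeries(subject_id, data, sampling_interval, labels)
    return SubjectSimulation(ts=ts, states=states, model=model)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One group of a simulated cohort.

    ``model`` is a template :class:`StateModel`; each subject receives an
    independent seed and, optionally, a subject-specific dwell time (see
    ``CohortSpec.severity_sd``).  Age and sex are drawn from group-specific
    distributions so that covariate adjustment has something real to do.
    """

    label: str
    n_subjects: int
    model: StateModel
    age_mean: float = 66.4
    age_sd: float = 8.5
    prob_female: float = 0.71


@dataclass
class CohortSpec:
    """Two-group (or k-group) cohort specification.

    ``severity_sd`` controls between-subject heterogeneity: each subject
    carries a latent severity ``u ~ N(0, 1)`` that scales their dwell time
    (``dwell * exp(severity_sd * u)``), stiffens their within-module
    coupling (``within * exp(within_severity_slope * u)``, the rigidity
    that makes dynamics stationary), and, through the drift-severity
    slope in the behavioural simulation, lowers their drift rate.  This
    latent pathway is what couples a subject's network dynamics to their
    attentional performance.
    """

    groups: Sequence[GroupSpec]
    n_timepoints: int = 200
    sampling_interval: float = 3.0
    severity_sd: float = 0.35
    within_severity_slope: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            if g.n_subjects < 1:
                raise ValueError(f"group '{g.label}' has zero subjects")
        n_regions = {g.model.n_regions for g in self.groups}
        if len(n_regions) != 1:
            raise ValueError("all groups must share n_regions")
        # the MTD window (15 samples) is the analysis scale; require room
        if self.n_timepoints < 2 * 15:
            raise ValueError("n_timepoints must be at least twice the analysis window")


@dataclass
class SimulatedSubject:
    """Cohort member: data, group membership, covariates, ground truth."""

    subject_id: str
    group: str
    age: float
    sex: int  # 0 = male, 1 = female
    severity: float
    sim: SubjectSimulation


def simulate_cohort(spec: CohortSpec) -> list[SimulatedSubject]:
    """Simulate every subject of a cohort.

    Subject-level randomness comes from independent substreams spawned
    from the master seed, so adding a subject never perturbs the others.
    """
    master = np.random.SeedSequence(spec.seed)
    out: list[SimulatedSubject] = []
    idx = 0
    for g in spec.groups:
        for j in range(g.n_subjects):
            child = master.spawn(1)[0]
            rng = np.random.default_rng(child)
            age = rng.normal(g.age_mean, g.age_sd)
            sex = int(rng.random() < g.prob_female)
            severity = rng.normal()
            dwell = g.model.dwell_mean * math.exp(spec.severity_sd * severity)
            max_between = float(np.max(g.model._between_per_state))
            within = float(
                np.clip(
                    g.model.within_coupling
                    * math.exp(spec.within_severity_slope * severity),
                    max_between + 0.02,
                    0.93,
                )
            )
            model = StateModel(
                n_regions=g.model.n_regions,
                n_states=g.model.n_states,
                module_partitions=g.model.module_partitions,
                within_coupling=within,
                between_coupling=g.model._between_per_state,
                dwell_mean=max(dwell, 1.0),
                noise_sd=g.model.noise_sd,
                baseline=g.model.baseline,
                seed=int(rng.integers(2**31)),
            )
            sim = simulate_subject(
                model,
                spec.n_timepoints,
                spec.sampling_interval,
                subject_id=f"{g.label}{j:03d}",
            )
            out.append(
                SimulatedSubject(
                    subject_id=f"{g.label}{j:03d}",
                    group=g.label,
                    age=float(age),
                    sex=sex,
                    severity=float(severity),
                    sim=sim,
                )
            )
            idx += 1
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def two_state_partitions(
    n_regions: int, n_modules: int = 4, n_movers_per_module: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a pair of module partitions differing by a few "mover" regions.

    The first partition splits regions into ``n_modules`` contiguous
    equal-sized modules.  The second moves the first
    ``n_movers_per_module`` regions of each module into the next module
    (cyclically).  Returns ``(partition_a, partition_b, mover_mask)``;
    movers are the regions whose module membership genuinely changes
    between states — the planted "unstable" regions.
    """
    if n_regions % n_modules:
        raise ValueError("n_regions must be divisible by n_modules")
    size = n_regions // n_modules
    if n_movers_per_module >= size:
        raise ValueError("too many movers per module")
    part_a = np.repeat(np.arange(n_modules), size)
    part_b = part_a.copy()
    movers = np.zeros(n_regions, dtype=bool)
    for m in range(n_modules):
        start = m * size
        sel = slice(start, start + n_movers_per_module)
        part_b[sel] = (m + 1) % n_modules
        movers[sel] = True
    return part_a, part_b, movers


def control_like_model(n_regions: int = 60, seed: int = 0) -> StateModel:
    """Preset emulating a healthy, temporally variable, integrated brain.

    Two states share one stable module partition but differ in
    integration level (between-module coupling 0.2 vs 0.4); switching is
    fast (mean dwell 4 samples), so the connectivity configuration is
    constantly reshuffled.
    """
    part_a, _, _ = two_state_partitions(n_regions)
    return StateModel(
        n_regions=n_regions,
        n_states=2,
        module_partitions=[part_a, part_a],
        within_coupling=0.6,
        between_coupling=[0.2, 0.4],
        dwell_mean=4.0,
        noise_sd=0.5,
        seed=seed,
    )


def dlb_like_model(n_regions: int = 60, seed: int = 0) -> StateModel:
    """Preset emulating the patient phenotype: slow, segregated, unstable.

    Dwell time is five times the control preset (mean 20 samples) and
    between-module coupling is low (0.1) in both states, so the network
    is more segregated and its configuration more stationary.  The two
    states differ in module membership for a minority of "mover" regions,
    so modular assignments are genuinely unstable.
    """
    part_a, part_b, _ = two_state_partitions(n_regions)
    return StateModel(
        n_regions=n_regions,
        n_states=2,
        module_partitions=[part_a, part_b],
        within_coupling=0.6,
        between_coupling=[0.1, 0.1],
        dwell_mean=20.0,
        noise_sd=0.5,
        seed=seed,
    )


def demo_cohort_spec(
    n_per_group: int = 20,
    n_regions: int = 60,
    n_timepoints: int = 200,
    seed: int = 0,
) -> CohortSpec:
    """Two-group study: control-like vs patient-like presets.

    Covariate distributions follow the clinical cohort structure this
    generator emulates: patients older (74.5 +- 6.1 vs 66.4 +- 8.5 years)
    and predominantly male.
    """
    return CohortSpec(
        groups=[
            GroupSpec(
                label="control",
                n_subjects=n_per_group,
                model=control_like_model(n_regions),
                age_mean=66.4,
                age_sd=8.5,
                prob_female=0.71,
            ),
            GroupSpec(
                label="dlb",
                n_subjects=n_per_group,
                model=dlb_like_model(n_regions),
                age_mean=74.5,
                age_sd=6.1,
                prob_female=0.18,
            ),
        ],
        n_timepoints=n_timepoints,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# head motion
# ---------------------------------------------------------------------------


@dataclass
class SimulatedMotion:
    motion: MotionParams
    spike_frames: np.ndarray


def simulate_motion(
    n_timepoints: int,
    spike_times: Sequence[int] = (),
    spike_size: float = 0.0,
    seed: int = 0,
) -> SimulatedMotion:
    """Smooth low-amplitude 6-parameter drift plus known displacement steps.

    The background is a sum of slow sinusoids whose frame-to-frame
    increments stay far below the 0.25 mm framewise-displacement
    threshold.  Each spike is a sustained step of ``spike_size`` mm in the
    first translation axis starting at the given frame, so FD flags
    exactly that frame.
    """
    spike_times = np.asarray(spike_times, dtype=int)
    if spike_times.size and spike_size < 0:
        raise ValueError("spike_size must be non-negative")
    if np.any(spike_times < 0) or np.any(spike_times >= n_timepoints):
        raise ValueError("spike indices must lie in [0, n_timepoints)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints)[:, None]
    freqs = rng.uniform(0.002, 0.008, size=6)[None, :]  # cycles per frame
    phases = rng.uniform(0, 2 * np.pi, size=6)[None, :]
    amp = np.array([0.04, 0.04, 0.04, 4e-4, 4e-4, 4e-4])[None, :]
    params = amp * np.sin(2 * np.pi * freqs * t + phases)
    for k in spike_times:
        params[k:, 0] += spike_size
    return SimulatedMotion(MotionParams(params), spike_frames=spike_times)


# ---------------------------------------------------------------------------
# diffusion-process reaction times
# ---------------------------------------------------------------------------


@dataclass
class DiffusionSpec:
    """Ground-truth parameters for the reaction-time simulator.

    Units follow the conventional diffusion-model scaling with the
    diffusion coefficient fixed (``noise_scale``, default 0.1): drift is
    evidence per second, boundary in evidence units, non-decision time in
    seconds.
    """

    drift: float
    boundary: float
    nondecision: float
    n_trials: int = 1000
    max_rt: float = 5.0
    dt: float = 0.001
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.nondecision < 0:
            raise ValueError("nondecision must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


@dataclass
class SartTrials:
    """Completed trials (rt seconds, correct flag) plus omission count."""

    trials: pd.DataFrame
    n_omitted: int
    spec: DiffusionSpec


def simulate_sart(spec: DiffusionSpec) -> SartTrials:
    """Euler–Maruyama simulation of a two-boundary diffusion.

    Evidence starts midway between boundaries at 0 and ``boundary``;
    a trial is correct when the upper boundary is hit first.  Trials that
    have not terminated by ``max_rt`` (decision time) are omissions and
    excluded from the returned table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    x = np.full(n, spec.boundary / 2.0)
    active = np.arange(n)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)
    step_sd = spec.noise_scale * math.sqrt(spec.dt)
    drift_step = spec.drift * spec.dt
    n_steps = int(math.ceil(spec.max_rt / spec.dt))
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        x[active] += drift_step + step_sd * rng.standard_normal(active.size)
        hit_up = x[active] >= spec.boundary
        hit_lo = x[active] <= 0.0
        done = hit_up | hit_lo
        if done.any():
            finished = active[done]
            rt[finished] = step * spec.dt + spec.nondecision
            correct[finished] = hit_up[done]
            active = active[~done]
    n_omitted = active.size
    if n_omitted == n:
        raise ValueError(
            "all trials exceeded max_rt; increase max_rt or check parameters"
        )
    keep = ~np.isnan(rt)
    trials = pd.DataFrame({"rt": rt[keep], "correct": correct[keep].astype(int)})
    return SartTrials(trials=trials, n_omitted=n_omitted, spec=spec)


# ---------------------------------------------------------------------------
# gene expression
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    """Region x gene table plus planted-gene bookkeeping."""

    expression: pd.DataFrame  # index = region labels, columns = gene symbols
    planted_gene: str | None
    realised_rho: float | None


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Map values to standard-normal scores of their ranks (ties averaged)."""
    from scipy.stats import rankdata

    r = rankdata(x)
    return ndtri(r / (len(x) + 1.0))


def simulate_expression(
    n_regions: int,
    n_genes: int,
    planted: tuple[np.ndarray, float] | None = None,
    seed: int = 0,
    region_labels: Sequence[str] | None = None,
    gene_names: Sequence[str] | None = None,
    planted_name: str = "PLANTED",
    smooth_sigma: float = 5.0,
) -> SimulatedExpression:
    """Generate a region-by-gene expression matrix.

    Background genes are spatially smooth random fields over the region
    index (Gaussian-smoothed white noise, standardised).  When
    ``planted=(target_map, rho)`` is given, one extra gene is built by
    blending normal scores of the target map's ranks with independent
    smooth noise; the blend weight is solved numerically so the realised
    Spearman correlation with ``target_map`` lands on ``rho`` (within the
    resolution that ranks at this ``n_regions`` permit).
    """
    rng = np.random.default_rng(seed)
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(n_regions)]
    if len(region_labels) != n_regions:
        raise ValueError("region_labels length must equal n_regions")
    if gene_names is None:
        gene_names = [f"G{i:03d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    def smooth_field() -> np.ndarray:
        f = gaussian_filter1d(rng.standard_normal(n_regions), smooth_sigma, mode="wrap")
        sd = f.std()
        return f / sd if sd > 0 else f

    cols = {g: smooth_field() for g in gene_names}
    planted_gene = None
    realised = None
    if planted is not None:
        target, rho = planted
        target = np.asarray(target, dtype=float)
        if target.shape != (n_regions,):
            raise ValueError(
                f"target_map length {target.shape} does not match "
                f"n_regions={n_regions}"
            )
        if not -1.0 <= rho <= 1.0:
            raise ValueError("planted rho must be in [-1, 1]")
        t = _normal_scores(target)
        g = smooth_field()

        def realised_rho_at(w: float) -> float:
            return spearmanr(w * t + (1.0 - abs(w)) * g, target).statistic

        if rho >= 1.0:
            gene_vals, realised = t, 1.0
        elif rho <= -1.0:
            gene_vals, realised = -t, -1.0
        else:
            w = brentq(lambda w: realised_rho_at(w) - rho, -1.0, 1.0, xtol=1e-4)
            gene_vals = w * t + (1.0 - abs(w)) * g
            realised = float(spearmanr(gene_vals, target).statistic)
        cols[planted_name] = gene_vals
        planted_gene = planted_name
    expr = pd.DataFrame(cols, index=list(region_labels))
    return SimulatedExpression(
        expression=expr, planted_gene=planted_gene, realised_rho=realised
    )
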
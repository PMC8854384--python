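"""End-to-end study orchestration.

``run_synthetic_study`` executes the whole analysis on a simulated
two-group cohort: simulate -> QC -> nuisance regression -> band-pass ->
MTD -> similarity -> communities -> label matching -> topology ->
flexibility -> behaviour -> group statistics -> gene mapping.  It is the
programmatic core behind the ``dynet run`` command and returns every
intermediate needed to reproduce the study's figure-analogue outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import fit_ddm, summarise_trials
from .core import ParcelTimeSeries
from .flexibility import match_labels, regional_flexibility
from .genemap import (
    DEFAULT_RECEPTOR_GENES,
    RegionDifferenceMap,
    gene_difference_correlation,
    regionset_expression_test,
)
from .mtd import mtd_tensor
from .preprocess import bandpass, dvars, flag_exceedance, framewise_displacement, nuisance_regress, QCSeries
from .similarity import compute_similarity
from .stats import (
    GroupStatResult,
    fdr_bh,
    permutation_correlation,
    permutation_group_test,
    permutation_group_test_regional,
)
from .synthetic import (
    DiffusionSpec,
    SimulatedSubject,
    demo_cohort_spec,
    simulate_cohort,
    simulate_expression,
    simulate_motion,
    simulate_sart,
)
from .topology import (
    cartographic_profile,
    detect_communities,
    segregated_occupancy,
    topology_series,
)

__all__ = ["AnalysisConfig", "StudyResult", "analyse_subject", "preprocess_subject", "run_synthetic_study", "run_study"]


@dataclass
class AnalysisConfig:
    """Analysis parameters with the study's defaults.

    ``window`` is the MTD sliding window in samples; ``band`` the
    band-pass in Hz; ``similarity_mode`` selects activity- or
    connectivity-pattern similarity; ``n_perm`` the permutation count for
    group tests; ``fdr_q_regions``/``fdr_q_genes`` the FDR thresholds for
    regional maps and the gene screen.
    """

    window: int = 15
    band: tuple[float, float] = (0.071, 0.125)
    similarity_mode: str = "connectivity"
    gamma: float = 1.0
    louvain_restarts: int = 10
    profile_bins: int = 100
    n_perm: int = 5000
    fdr_q_regions: float = 0.05
    fdr_q_genes: float = 0.1
    ddm_noise_scale: float = 0.1
    sart_trials: int = 2000
    base_drift: dict = field(default_factory=lambda: {"control": 0.25, "dlb": 0.15})
    drift_severity_slope: float = 0.3
    boundary: float = 0.12
    nondecision: float = 0.3
    planted_gene_rho: float = 0.6
    n_background_genes: int = 20


@dataclass
class SubjectMeasures:
    """Scalar and regional summaries of one analysed subject."""

    s_local: float
    s_global: float
    mean_participation: float
    mean_flexibility: float
    occupancy_mean: float
    participation_by_region: np.ndarray
    flexibility_by_region: np.ndarray
    occupancy_by_region: np.ndarray
    profile: np.ndarray  # normalised cartographic profile
    qc_fraction: float
    qc_excluded: bool


@dataclass
class StudyResult:
    subjects: pd.DataFrame
    group_tests: dict[str, GroupStatResult]
    correlations: dict[str, tuple[float, float]]
    region_difference: RegionDifferenceMap
    region_p: np.ndarray
    gene_correlations: pd.DataFrame
    regionset_tests: pd.DataFrame
    planted_gene: str | None
    profiles: np.ndarray
    parcel_labels: list[str]
    measures: list[SubjectMeasures]


def preprocess_subject(
    ts: ParcelTimeSeries,
    motion,
    config: AnalysisConfig,
) -> tuple[ParcelTimeSeries, "QCSeries", float, bool]:
    """QC then nuisance regression then band-pass, in the fixed order."""
    fd = framewise_displacement(motion)
    dv = dvars(ts)
    exc = flag_exceedance(QCSeries(fd=fd, dvars=dv))
    params = motion.params
    derivs = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    regressors = np.column_stack([params, derivs, fd, dv])
    import warnings

    with warnings.catch_warnings():
        # smooth sinusoidal motion makes parameter derivatives collinear
        # with the parameters themselves; the residuals are unaffected
        warnings.filterwarnings("ignore", message="rank-deficient")
        clean = nuisance_regress(ts, regressors)
    filtered = bandpass(clean, *config.band)
    return filtered, exc.qc, exc.fraction, exc.excluded


def analyse_subject(
    ts: ParcelTimeSeries,
    config: AnalysisConfig,
    seed: int = 0,
    qc_fraction: float = 0.0,
    qc_excluded: bool = False,
) -> SubjectMeasures:
    """Run the dynamic-network analysis on one preprocessed subject."""
    dc = mtd_tensor(ts, window=config.window)
    sim = compute_similarity(ts=ts, dc=dc, mode=config.similarity_mode)
    assign = detect_communities(
        dc, gamma=config.gamma, seed=seed, n_restarts=config.louvain_restarts
    )
    matched = match_labels(assign)
    topo = topology_series(dc, matched)
    prof = cartographic_profile(topo, n_bins=config.profile_bins, normalise=True)
    occ = segregated_occupancy(topo, seed=seed)
    flex = regional_flexibility(matched)
    return SubjectMeasures(
        s_local=sim.s_local,
        s_global=sim.s_global,
        mean_participation=float(topo.participation.mean()),
        mean_flexibility=float(flex.flexibility.mean()),
        occupancy_mean=float(occ.occupancy.mean()),
        participation_by_region=topo.participation.mean(axis=1),
        flexibility_by_region=flex.flexibility,
        occupancy_by_region=occ.occupancy,
        profile=prof.counts,
        qc_fraction=qc_fraction,
        qc_excluded=qc_excluded,
    )


def _behaviour_for_subject(
    subj: SimulatedSubject, config: AnalysisConfig, seed: int
) -> dict:
    base = config.base_drift.get(subj.group, 0.2)
    drift = base * math.exp(-config.drift_severity_slope * subj.severity)
    spec = DiffusionSpec(
        drift=drift,
        boundary=config.boundary,
        nondecision=config.nondecision,
        n_trials=config.sart_trials,
        noise_scale=config.ddm_noise_scale,
        seed=seed,
    )
    sart = simulate_sart(spec)
    summary = summarise_trials(sart.trials)
    params = fit_ddm(summary, noise_scale=config.ddm_noise_scale)
    return {
        "mean_rt": summary.mean_rt,
        "var_rt": summary.var_rt,
        "accuracy": summary.accuracy,
        "drift": params.drift,
        "boundary": params.boundary,
        "nondecision": params.nondecision,
        "true_drift": drift,
    }


def run_synthetic_study(
    n_per_group: int = 20,
    n_regions: int = 60,
    n_timepoints: int = 200,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> StudyResult:
    """Simulate a two-group cohort and run the full analysis on it.

    The patient-like group has slower state switching, lower
    between-module coupling and state-dependent module membership; the
    analysis should therefore find higher similarity statistics, lower
    participation, higher segregated-state occupancy and higher
    flexibility in that group, and the planted expression gene should
    surface in the transcriptomic screen.
    """
    config = config or AnalysisConfig()
    spec = demo_cohort_spec(
        n_per_group=n_per_group,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        seed=seed,
    )
    cohort = simulate_cohort(spec)
    ss = np.random.SeedSequence([seed, 1])
    analysis_seeds = ss.generate_state(len(cohort) * 3).reshape(-1, 3)

    rows = []
    measures: list[SubjectMeasures] = []
    labels = cohort[0].sim.ts.parcel_labels
    for i, subj in enumerate(cohort):
        motion_seed, louvain_seed, sart_seed = (int(x) for x in analysis_seeds[i])
        motion = simulate_motion(n_timepoints, seed=motion_seed).motion
        clean, _, frac, excluded = preprocess_subject(subj.sim.ts, motion, config)
        m = analyse_subject(
            clean, config, seed=louvain_seed, qc_fraction=frac, qc_excluded=excluded
        )
        measures.append(m)
        row = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "age": subj.age,
            "sex": subj.sex,
            "severity": subj.severity,
            "true_dwell": subj.sim.model.dwell_mean,
            "s_local": m.s_local,
            "s_global": m.s_global,
            "mean_participation": m.mean_participation,
            "mean_flexibility": m.mean_flexibility,
            "occupancy": m.occupancy_mean,
            "qc_fraction": m.qc_fraction,
        }
        row.update(_behaviour_for_subject(subj, config, sart_seed))
        rows.append(row)
    subjects = pd.DataFrame(rows)

    covariates = subjects[["age", "sex"]].to_numpy(dtype=float)
    groups = subjects["group"].to_numpy()
    stat_seed = int(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    group_tests = {}
    for name in ["s_local", "s_global", "mean_participation", "mean_flexibility", "occupancy"]:
        group_tests[name] = permutation_group_test(
            subjects[name].to_numpy(),
            groups,
            covariates=covariates,
            n_perm=config.n_perm,
            seed=stat_seed,
            statistic=name,
        )

    # brain-behaviour correlations within the patient-like group
    dlb = subjects[subjects["group"] == "dlb"]
    correlations = {
        "s_local_vs_rt_sd": permutation_correlation(
            dlb["s_local"].to_numpy(),
            np.sqrt(dlb["var_rt"].to_numpy()),
            n_perm=config.n_perm,
            seed=stat_seed,
            rank=True,
        ),
        "s_local_vs_drift": permutation_correlation(
            dlb["s_local"].to_numpy(),
            dlb["drift"].to_numpy(),
            n_perm=config.n_perm,
            seed=stat_seed,
            rank=True,
        ),
    }

    # regional participation difference map (control - patient) + FDR mask
    part = np.stack([m.participation_by_region for m in measures])  # subjects x regions
    diff_obs, region_p = permutation_group_test_regional(
        part, groups, covariates=covariates, n_perm=config.n_perm, seed=stat_seed
    )
    mask, _ = fdr_bh(region_p, q=config.fdr_q_regions)
    region_diff = RegionDifferenceMap(
        region_labels=list(labels), difference=diff_obs, significant=mask
    )

    # transcriptomic screen with a gene planted against the observed map
    gene_seed = int(np.random.SeedSequence([seed, 3]).generate_state(1)[0])
    background = [g for g in DEFAULT_RECEPTOR_GENES if g != "ADRA2A"]
    expr_sim = simulate_expression(
        n_regions=n_regions,
        n_genes=config.n_background_genes,
        planted=(diff_obs, config.planted_gene_rho),
        seed=gene_seed,
        region_labels=labels,
        gene_names=background[: config.n_background_genes],
        planted_name="ADRA2A",
    )
    gene_corr = gene_difference_correlation(
        expr_sim.expression, region_diff, q=config.fdr_q_genes
    )
    if mask.sum() >= 2 and (~mask).sum() >= 2:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # smooth fields often fail Shapiro
            regionset = regionset_expression_test(
                expr_sim.expression, region_diff, genes=[expr_sim.planted_gene]
            )
    else:
        regionset = pd.DataFrame(
            columns=["gene", "t", "p", "mean_significant", "mean_other", "q_value", "significant"]
        )

    return StudyResult(
        subjects=subjects,
        group_tests=group_tests,
        correlations=correlations,
        region_difference=region_diff,
        region_p=region_p,
        gene_correlations=gene_corr,
        regionset_tests=regionset,
        planted_gene=expr_sim.planted_gene,
        profiles=np.stack([m.profile for m in measures]),
        parcel_labels=list(labels),
        measures=measures,
    )


# ---------------------------------------------------------------------------
# file-level study runner (CLI backend)
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(
    out_dir: str | Path,
    n_per_group: int = 8,
    n_regions: int = 60,
    n_timepoints: int = 200,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> Path:
    """Run the synthetic study and write every output as flat files.

    Writes ``subjects.csv``, ``group_stats.csv``, ``correlations.csv``,
    ``region_difference.csv``, ``gene_correlations.csv``,
    ``regionset_tests.csv``, per-subject profiles, and a ``manifest.json``
    recording parameters, the master seed and a SHA-256 hash of every
    output so a rerun can be verified bit for bit.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_synthetic_study(
        n_per_group=n_per_group,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        seed=seed,
        config=config,
    )
    result.subjects.to_csv(out / "subjects.csv", index=False)
    pd.DataFrame(
        [
            {
                "measure": k,
                "statistic": v.statistic,
                "observed": v.observed,
                "p_value": v.p_value,
                "cohens_d": v.cohens_d,
                "n_permutations": v.n_permutations,
            }
            for k, v in result.group_tests.items()
        ]
    ).to_csv(out / "group_stats.csv", index=False)
    pd.DataFrame(
        [{"pair": k, "rho": r, "p_value": p} for k, (r, p) in result.correlations.items()]
    ).to_csv(out / "correlations.csv", index=False)
    pd.DataFrame(
        {
            "region_id": result.region_difference.region_labels,
            "difference": result.region_difference.difference,
            "p_value": result.region_p,
            "significant": result.region_difference.significant,
        }
    ).to_csv(out / "region_difference.csv", index=False)
    result.gene_correlations.to_csv(out / "gene_correlations.csv", index=False)
    result.regionset_tests.to_csv(out / "regionset_tests.csv", index=False)

    files = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "n_regions": n_regions,
        "n_timepoints": n_timepoints,
        "analysis": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
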
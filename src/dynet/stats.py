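"""Group inference and brain–behaviour correlation.

Permutation tests with covariate adjustment carry the main inferential
load: subject values are first residualised on an intercept plus the
covariates (Freedman–Lane style), then group labels are permuted and the
difference of group means recomputed.  All permutation p-values use the
``+1`` small-sample correction, so they are never exactly zero and never
smaller than ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupStatResult",
    "permutation_group_test",
    "cohens_d",
    "fdr_bh",
    "mannwhitney_u",
    "permutation_correlation",
    "cartographic_binwise",
    "BinwiseMap",
]


@dataclass
class GroupStatResult:
    statistic: str
    observed: float
    p_value: float
    n_permutations: int
    cohens_d: float


def _residualise(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of ``values`` on [intercept | covariates] (OLS)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if covariates is None:
        design = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariate rows must align with subjects")
        design = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, str, str]:
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels.tolist()))  # order of appearance
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    ind = (labels == uniq[0]).astype(float)
    if ind.sum() < 2 or (1 - ind).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    return ind, str(uniq[0]), str(uniq[1])


def permutation_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    statistic: str = "mean_difference",
) -> GroupStatResult:
    """Two-sided covariate-adjusted permutation test of a group difference.

    The observed statistic is the difference of group means of the
    covariate-residualised values (first group minus second, in order of
    label appearance).  ``p = (#{|T_perm| >= |T_obs|} + 1) / (n_perm + 1)``.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("values are constant; group test undefined")
    ind, label_a, label_b = _group_indicator(np.asarray(groups))
    resid = _residualise(values, covariates)
    n_a = ind.sum()
    n_b = len(ind) - n_a

    def mean_diff(indicator: np.ndarray) -> np.ndarray:
        return indicator @ resid / n_a - (1 - indicator) @ resid / n_b

    observed = float(mean_diff(ind))
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(ind))), axis=1)
    perm_ind = ind[order]
    perm_stats = perm_ind @ resid / n_a - (1 - perm_ind) @ resid / n_b
    p = (np.sum(np.abs(perm_stats) >= abs(observed)) + 1) / (n_perm + 1)
    d = cohens_d(resid[ind == 1], resid[ind == 0])
    return GroupStatResult(
        statistic=f"{statistic}({label_a} - {label_b})",
        observed=observed,
        p_value=float(p),
        n_permutations=n_perm,
        cohens_d=d,
    )


def permutation_group_test_regional(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-region version: ``values`` is (subjects, regions).

    Returns (observed mean differences, two-sided permutation p-values),
    one per region, using a single shared set of permutations.
    """
    values = np.asarray(values, dtype=float)
    ind, _, _ = _group_indicator(np.asarray(groups))
    resid = _residualise(values, covariates)
    n_a = ind.sum()
    n_b = len(ind) - n_a
    observed = ind @ resid / n_a - (1 - ind) @ resid / n_b
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(ind))), axis=1)
    perm_ind = ind[order]
    perm = perm_ind @ resid / n_a - (1 - perm_ind) @ resid / n_b
    p = (np.sum(np.abs(perm) >= np.abs(observed)[None, :], axis=0) + 1) / (n_perm + 1)
    return observed, p


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardised mean difference with the pooled (n-1 weighted) SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (significance mask, monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    mask = qvals <= q
    return mask, qvals


def mannwhitney_u(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U for the first group, with two-sided p.

    Exact enumeration when the combined sample size is <= 12 and there
    are no ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("need at least 1 value per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def permutation_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    rank: bool = False,
) -> tuple[float, float]:
    """Pearson (or Spearman with ``rank=True``) correlation with a
    label-permutation two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    if rank:
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    observed = float(xc @ yc / n)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_r = (yc[order] @ xc) / n
    p = (np.sum(np.abs(perm_r) >= abs(observed)) + 1) / (n_perm + 1)
    return observed, float(p)


@dataclass
class BinwiseMap:
    """Per-bin correlation of profile occupancy with a subject outcome."""

    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray  # significant after BH-FDR
    valid: np.ndarray  # bins with non-zero variance across subjects


def cartographic_binwise(
    profiles: np.ndarray, outcome: np.ndarray, q: float = 0.05
) -> BinwiseMap:
    """Correlate each cartographic-profile bin with an outcome across subjects.

    ``profiles`` is (n_subjects, nb, nz) of (normalised) bin occupancies
    sharing bin edges.  Bins with zero variance across subjects are
    masked out rather than raising; BH-FDR runs over the valid bins only.
    """
    profiles = np.asarray(profiles, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if profiles.ndim != 3 or profiles.shape[0] != outcome.size:
        raise ValueError("profiles must be (n_subjects, nb, nz) aligned with outcome")
    if np.ptp(outcome) == 0:
        raise ValueError("constant outcome; correlation undefined")
    n, nb, nz = profiles.shape
    flat = profiles.reshape(n, -1)
    valid = flat.std(axis=0) > 0
    r = np.full(flat.shape[1], np.nan)
    p = np.full(flat.shape[1], np.nan)
    yc = (outcome - outcome.mean()) / outcome.std()
    xc = flat[:, valid] - flat[:, valid].mean(axis=0)
    xs = xc / xc.std(axis=0)
    r[valid] = yc @ xs / n
    # two-sided t test p-values for Pearson r
    rr = np.clip(r[valid], -0.999999, 0.999999)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p[valid] = 2 * sps.t.sf(np.abs(t), df=n - 2)
    mask = np.zeros(flat.shape[1], dtype=bool)
    if valid.any():
        m, qv = fdr_bh(p[valid], q=q)
        mask[valid] = m
        qfull = np.full(flat.shape[1], np.nan)
        qfull[valid] = qv
    else:
        qfull = np.full(flat.shape[1], np.nan)
    shape = (nb, nz)
    return BinwiseMap(
        r=r.reshape(shape),
        p=p.reshape(shape),
        q=qfull.reshape(shape),
        mask=mask.reshape(shape),
        valid=valid.reshape(shape),
    )
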
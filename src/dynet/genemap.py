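"""Transcriptomic spatial correlation of regional group differences.

Given a region-by-gene mean expression table aligned to the imaging
parcellation and a per-region group-difference map (e.g. control minus
patient participation), this module asks which genes' spatial expression
patterns track the difference map (Spearman, BH-FDR across the gene
list), and whether a given gene is expressed more highly in the regions
that differ significantly than in those that do not (independent-samples
t test).

Alignment is always by region label, never by row order.  No correction
for spatial autocorrelation of expression maps is applied; an optional
region-permutation null (:func:`gene_difference_correlation` with
``n_perm > 0``) is available as an extra beyond the core analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fdr_bh

__all__ = [
    "RegionDifferenceMap",
    "gene_difference_correlation",
    "regionset_expression_test",
    "DEFAULT_RECEPTOR_GENES",
]

# default analysis list: adrenergic, cholinergic (muscarinic + nicotinic)
# and dopaminergic receptor genes
DEFAULT_RECEPTOR_GENES = [
    "ADRA1A", "ADRA1B", "ADRA1D", "ADRA2A", "ADRA2B", "ADRA2C",
    "ADRB1", "ADRB2", "ADRB3",
    "CHRM1", "CHRM2", "CHRM3", "CHRM4", "CHRM5",
    "CHRNA2", "CHRNA3", "CHRNA4", "CHRNA5", "CHRNA6", "CHRNA7",
    "CHRNB2", "CHRNB3", "CHRNB4",
    "DRD1", "DRD2", "DRD3", "DRD4", "DRD5",
]


@dataclass
class RegionDifferenceMap:
    """Per-region group difference with a significance mask."""

    region_labels: list[str]
    difference: np.ndarray
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.difference = np.asarray(self.difference, dtype=float)
        if len(self.region_labels) != self.difference.size:
            raise ValueError("difference length must match region labels")
        if self.significant is not None:
            self.significant = np.asarray(self.significant, dtype=bool)
            if self.significant.size != self.difference.size:
                raise ValueError("significance mask length must match regions")


def _align(expr: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    missing = [l for l in labels if l not in expr.index]
    extra = [l for l in expr.index if l not in set(labels)]
    if missing:
        raise ValueError(
            f"expression table is missing {len(missing)} region(s): "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    if extra:
        warnings.warn(f"{len(extra)} expression regions not in the difference map")
    return expr.loc[list(labels)]


def gene_difference_correlation(
    expr: pd.DataFrame,
    diff: RegionDifferenceMap,
    q: float = 0.1,
) -> pd.DataFrame:
    """Spearman correlation of every gene's expression with the difference map.

    Returns a table (gene, rho, p, q_value, significant) sorted by p.
    Constant genes have no defined rank correlation; they are reported
    with missing rho/p and excluded from the FDR family size.
    """
    aligned = _align(expr, diff.region_labels)
    rows = []
    for gene in aligned.columns:
        vals = aligned[gene].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            rows.append((gene, np.nan, np.nan))
            continue
        res = sps.spearmanr(vals, diff.difference)
        rows.append((gene, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p"])
    testable = out["p"].notna()
    qvals = np.full(len(out), np.nan)
    sig = np.zeros(len(out), dtype=bool)
    if testable.any():
        mask, qv = fdr_bh(out.loc[testable, "p"].to_numpy(), q=q)
        qvals[testable.to_numpy()] = qv
        sig[testable.to_numpy()] = mask
    out["q_value"] = qvals
    out["significant"] = sig
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def regionset_expression_test(
    expr: pd.DataFrame,
    diff: RegionDifferenceMap,
    genes: Sequence[str] | None = None,
    equal_var: bool = True,
    q: float = 0.05,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare gene expression between significant and non-significant regions.

    Independent-samples t test (pooled variance by default) of each
    gene's expression in the regions flagged significant in ``diff``
    versus all remaining regions, with BH correction across the tested
    genes.  Normality of both groups is checked with the Shapiro–Wilk
    test and a warning emitted when it fails.
    """
    if diff.significant is None:
        raise ValueError("difference map carries no significance mask")
    sig = diff.significant
    if sig.sum() < 2 or (~sig).sum() < 2:
        raise ValueError("both region sets need at least 2 regions")
    aligned = _align(expr, diff.region_labels)
    genes = list(genes) if genes is not None else list(aligned.columns)
    rows = []
    for gene in genes:
        if gene not in aligned.columns:
            raise ValueError(f"gene {gene!r} not in expression table")
        vals = aligned[gene].to_numpy(dtype=float)
        a, b = vals[sig], vals[~sig]
        if np.ptp(vals) == 0:
            rows.append((gene, 0.0, 1.0, a.mean(), b.mean()))
            continue
        for name, grp in (("significant", a), ("non-significant", b)):
            if np.ptp(grp) > 0 and len(grp) >= 3:
                w = sps.shapiro(grp)
                if w.pvalue < normality_alpha:
                    warnings.warn(
                        f"{gene}: {name} regions fail Shapiro-Wilk normality "
                        f"(p = {w.pvalue:.3g})"
                    )
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append((gene, float(res.statistic), float(res.pvalue), a.mean(), b.mean()))
    out = pd.DataFrame(
        rows, columns=["gene", "t", "p", "mean_significant", "mean_other"]
    )
    mask, qv = fdr_bh(out["p"].to_numpy(), q=q)
    out["q_value"] = qv
    out["significant"] = mask
    return out
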
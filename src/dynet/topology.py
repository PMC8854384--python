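"""Time-resolved community detection and integration/segregation measures.

Per temporal window the pipeline detects a modular partition (Louvain
modularity maximisation on the positive-weight graph), then summarises
each region's topological role along two axes:

* participation coefficient ``B`` — between-module connectivity, 0 when
  all of a region's links stay within one module, approaching 1 when its
  strength is spread uniformly across modules;
* module-degree z-score ``W`` — within-module strength standardised
  within the region's module.

The joint (B, W) histogram over all regions and windows is the
"cartographic profile"; k-means (k = 2) on the pooled participation
values yields the fraction of time each region spends in the
lower-participation ("segregated") cluster.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.cluster import KMeans

from .mtd import DynamicConnectivity

__all__ = [
    "ModuleAssignment",
    "TopologySeries",
    "CartographicProfile",
    "SegregationOccupancy",
    "detect_communities",
    "participation",
    "module_degree_z",
    "topology_series",
    "cartographic_profile",
    "segregated_occupancy",
]


@dataclass
class ModuleAssignment:
    """Integer module labels per region and window.

    Straight out of :func:`detect_communities` the labels are arbitrary
    within each window; after Hungarian matching (see
    :mod:`dynet.flexibility`) label identity is comparable across
    windows and ``matched`` is set.
    """

    labels: np.ndarray  # (n_regions, n_windows) ints
    modularity: np.ndarray  # Q per window
    matched: bool = False

    @property
    def n_windows(self) -> int:
        return self.labels.shape[1]

    @property
    def n_modules_per_window(self) -> np.ndarray:
        return np.array(
            [len(np.unique(self.labels[:, w])) for w in range(self.n_windows)]
        )


@dataclass
class TopologySeries:
    participation: np.ndarray  # (n_regions, n_windows) in [0, 1]
    module_z: np.ndarray  # (n_regions, n_windows)


@dataclass
class CartographicProfile:
    """2-D histogram of (participation, module-degree z) occupancy."""

    counts: np.ndarray
    b_edges: np.ndarray
    z_edges: np.ndarray
    normalised: bool = False

    def normalise(self) -> "CartographicProfile":
        total = self.counts.sum()
        return CartographicProfile(
            counts=self.counts / total if total > 0 else self.counts,
            b_edges=self.b_edges,
            z_edges=self.z_edges,
            normalised=True,
        )


@dataclass
class SegregationOccupancy:
    occupancy: np.ndarray  # per-region fraction of windows in the segregated cluster
    centroids: np.ndarray  # (2,) participation centroids, ascending


def _louvain_slice(
    w: np.ndarray, gamma: float, seed: int, n_restarts: int
) -> tuple[np.ndarray, float]:
    """Best-of-``n_restarts`` Louvain partition of one weighted slice.

    Negative weights are dropped (positive-weight graph); an all-zero
    slice degenerates to a single module with a warning.
    """
    n = w.shape[0]
    mask = np.triu(w, 1) > 0
    src, dst = np.nonzero(mask)
    if src.size == 0:
        warnings.warn("empty (all-non-positive) slice; single-module partition")
        return np.zeros(n, dtype=int), 0.0
    weights = w[src, dst].tolist()
    g = ig.Graph(n=n, edges=np.column_stack([src, dst]).tolist())
    py_rng = random.Random(seed)
    ig.set_random_number_generator(py_rng)
    best_q = -np.inf
    best = None
    for _ in range(n_restarts):
        vc = g.community_multilevel(weights=weights, resolution=gamma)
        q = g.modularity(vc.membership, weights=weights, resolution=gamma)
        if q > best_q:
            best_q = q
            best = np.asarray(vc.membership, dtype=int)
    return best, float(best_q)


def detect_communities(
    dc: DynamicConnectivity,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> ModuleAssignment:
    """Per-window Louvain partitions of the dynamic connectivity tensor.

    Deterministic given ``seed``: each window draws its restart seeds
    from an independent substream of the master seed and the best-Q
    partition of ``n_restarts`` runs is kept.
    """
    if dc.n_windows < 1:
        raise ValueError("need at least one window")
    ss = np.random.SeedSequence(seed)
    window_seeds = ss.generate_state(dc.n_windows)
    labels = np.empty((dc.n_regions, dc.n_windows), dtype=int)
    q = np.empty(dc.n_windows)
    for t in range(dc.n_windows):
        lab, qt = _louvain_slice(
            dc.tensor[:, :, t], gamma, int(window_seeds[t]), n_restarts
        )
        labels[:, t] = lab
        q[t] = qt
    return ModuleAssignment(labels=labels, modularity=q, matched=False)


def _positive_module_strengths(
    w: np.ndarray, partition: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region strength into each module, positive weights only."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0).copy()
    np.fill_diagonal(wp, 0.0)
    mods, inv = np.unique(partition, return_inverse=True)
    onehot = np.zeros((n, mods.size))
    onehot[np.arange(n), inv] = 1.0
    kappa = wp @ onehot  # (n_regions, n_modules)
    return kappa, inv


def participation(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient of every region for one weighted slice.

    ``B_i = 1 - sum_s (kappa_is / k_i)^2`` with ``kappa_is`` the sum of
    region i's positive edge weights into module s and ``k_i`` its total
    positive strength; isolated regions (``k_i = 0``) get ``B_i = 0``.
    """
    partition = np.asarray(partition)
    if partition.shape[0] != w.shape[0]:
        raise ValueError("partition must cover all regions")
    kappa, _ = _positive_module_strengths(w, partition)
    k = kappa.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = kappa / k[:, None]
    b = 1.0 - np.nansum(frac**2, axis=1)
    b[k == 0] = 0.0
    return b


def module_degree_z(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Module-degree z-score: within-module strength standardised in-module.

    Modules of size 1, or with zero spread of within-module strength,
    yield ``W = 0`` for their members.
    """
    partition = np.asarray(partition)
    if partition.shape[0] != w.shape[0]:
        raise ValueError("partition must cover all regions")
    kappa, inv = _positive_module_strengths(w, partition)
    own = kappa[np.arange(w.shape[0]), inv]
    z = np.zeros_like(own)
    for m in range(inv.max() + 1):
        members = inv == m
        if members.sum() < 2:
            continue
        vals = own[members]
        sd = vals.std()
        if sd > 0:
            z[members] = (vals - vals.mean()) / sd
    return z


def topology_series(dc: DynamicConnectivity, assign: ModuleAssignment) -> TopologySeries:
    """Participation and module-degree z for every region and window."""
    if assign.labels.shape != (dc.n_regions, dc.n_windows):
        raise ValueError("module assignment does not match the tensor")
    b = np.empty_like(assign.labels, dtype=float)
    z = np.empty_like(b)
    for t in range(dc.n_windows):
        w = dc.tensor[:, :, t]
        b[:, t] = participation(w, assign.labels[:, t])
        z[:, t] = module_degree_z(w, assign.labels[:, t])
    return TopologySeries(participation=b, module_z=z)


def cartographic_profile(
    topo: TopologySeries,
    n_bins: int = 100,
    b_range: tuple[float, float] = (0.0, 1.0),
    z_range: tuple[float, float] = (-5.0, 5.0),
    normalise: bool = False,
) -> CartographicProfile:
    """Joint histogram of (B, W) over all region-window pairs.

    Values are clipped into the bin ranges so counts are conserved:
    the histogram always sums to ``n_regions * n_windows`` (or 1 when
    normalised).
    """
    if topo.participation.shape != topo.module_z.shape:
        raise ValueError("participation and module_z must be aligned")
    b = np.clip(topo.participation.ravel(), *b_range)
    z = np.clip(topo.module_z.ravel(), *z_range)
    b_edges = np.linspace(*b_range, n_bins + 1)
    z_edges = np.linspace(*z_range, n_bins + 1)
    counts, _, _ = np.histogram2d(b, z, bins=(b_edges, z_edges))
    prof = CartographicProfile(counts=counts, b_edges=b_edges, z_edges=z_edges)
    return prof.normalise() if normalise else prof


def segregated_occupancy(
    topo: TopologySeries, k: int = 2, seed: int = 0, n_retries: int = 5
) -> SegregationOccupancy:
    """Fraction of windows each region spends in the segregated state.

    k-means (k = 2) is run on the subject's pooled participation values
    (all regions and windows); the cluster with the lower centroid is
    "segregated" and per-region occupancy is the fraction of that
    region's windows assigned to it.
    """
    vals = topo.participation.ravel()
    if np.unique(vals).size < 2:
        raise ValueError("need at least 2 distinct participation values")
    x = vals.reshape(-1, 1)
    last_err: Exception | None = None
    for attempt in range(n_retries):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(x)
        if np.unique(labels).size == k:
            break
        last_err = RuntimeError("degenerate k-means solution (empty cluster)")
    else:
        raise last_err  # pragma: no cover - k-means on >=2 distinct values
    centroids = km.cluster_centers_.ravel()
    seg_cluster = int(np.argmin(centroids))
    seg = (labels == seg_cluster).reshape(topo.participation.shape)
    return SegregationOccupancy(
        occupancy=seg.mean(axis=1), centroids=np.sort(centroids)
    )
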
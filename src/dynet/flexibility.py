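"""Temporal label matching and regional modular instability (flexibility).

Community labels are arbitrary within each temporal window, so before
counting label switches the partitions of consecutive windows are
aligned with a maximum-overlap (Hungarian) assignment.  A region's
flexibility is then the fraction of window transitions in which its
matched label changes, normalised by the total number of distinct
modules observed in the subject's data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .topology import ModuleAssignment

__all__ = ["FlexibilityMap", "match_labels", "regional_flexibility"]


@dataclass
class FlexibilityMap:
    switch_fraction: np.ndarray  # per region, in [0, 1]
    flexibility: np.ndarray  # switch_fraction / n_modules
    n_windows: int
    n_modules: int


def match_labels(assign: ModuleAssignment) -> ModuleAssignment:
    """Propagate consistent module labels across windows.

    For each consecutive window pair the contingency table between the
    previous (already matched) labels and the new raw labels is built and
    the Hungarian algorithm solves the maximum-overlap assignment.  A new
    module whose best match shares no region receives a fresh label.
    Region membership is never changed — only the label names.
    """
    if assign.n_windows < 2:
        raise ValueError("need at least 2 windows to match labels")
    raw = assign.labels
    out = np.empty_like(raw)
    # canonicalise the first window to 0..m-1
    first_ids, first_inv = np.unique(raw[:, 0], return_inverse=True)
    out[:, 0] = first_inv
    next_id = first_ids.size
    for t in range(1, raw.shape[1]):
        prev_ids = np.unique(out[:, t - 1])
        cur_ids, cur_inv = np.unique(raw[:, t], return_inverse=True)
        # contingency: overlap counts between previous and current modules
        cont = np.zeros((prev_ids.size, cur_ids.size), dtype=int)
        prev_index = {p: i for i, p in enumerate(prev_ids)}
        for r in range(raw.shape[0]):
            cont[prev_index[out[r, t - 1]], cur_inv[r]] += 1
        side = max(cont.shape)
        padded = np.zeros((side, side), dtype=int)
        padded[: cont.shape[0], : cont.shape[1]] = cont
        rows, cols = linear_sum_assignment(-padded)
        mapping = np.empty(cur_ids.size, dtype=int)
        assigned = {c: r for r, c in zip(rows, cols)}
        for c in range(cur_ids.size):
            r = assigned[c]
            if r < cont.shape[0] and cont[r, c] > 0:
                mapping[c] = prev_ids[r]
            else:
                mapping[c] = next_id
                next_id += 1
        out[:, t] = mapping[cur_inv]
    return ModuleAssignment(labels=out, modularity=assign.modularity.copy(), matched=True)


def regional_flexibility(assign: ModuleAssignment) -> FlexibilityMap:
    """Per-region modular instability from matched labels.

    ``switch_fraction_i`` is the fraction of the ``n_windows - 1`` window
    transitions at which region i's label changes; flexibility divides it
    by the total number of distinct matched modules in the data.
    """
    if not assign.matched:
        raise ValueError("labels must be temporally matched first (match_labels)")
    if assign.n_windows < 2:
        raise ValueError("flexibility undefined for a single window")
    lab = assign.labels
    switches = (lab[:, 1:] != lab[:, :-1]).sum(axis=1)
    switch_fraction = switches / (lab.shape[1] - 1)
    n_modules = int(np.unique(lab).size)
    return FlexibilityMap(
        switch_fraction=switch_fraction,
        flexibility=switch_fraction / n_modules,
        n_windows=lab.shape[1],
        n_modules=n_modules,
    )
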
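"""Merge ALS-derived (H, R) and TLS-derived DBH per-tree features.

Trees from the two sources are paired one-to-one by optimal assignment
on the planimetric distance matrix, thresholded at a maximum matching
distance.  Fused records take H and R from ALS, DBH and position from
TLS.  Unmatched trees are reported, never dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import TreeRecord

__all__ = ["MatchResult", "FusionOutput", "match_trees"]

DEFAULT_MAX_DISTANCE = 1.0


@dataclass
class MatchResult:
    als_tree_id: int
    tls_tree_id: int
    distance: float
    fused: TreeRecord


@dataclass
class FusionOutput:
    matches: List[MatchResult]
    unmatched_als: List[int]
    unmatched_tls: List[int]


def _fuse(als: TreeRecord, tls: TreeRecord) -> TreeRecord:
    dbh = tls.DBH if (tls.DBH is not None and not math.isnan(tls.DBH)) \
        else als.DBH
    species = als.species if als.species != "unknown" else tls.species
    return TreeRecord(
        tree_id=als.tree_id, plot_id=als.plot_id, species=species,
        x=tls.x, y=tls.y, H=als.H, DBH=dbh, R=als.R,
        W_ref=als.W_ref, source="fused")


def match_trees(als_trees: Sequence[TreeRecord],
                tls_trees: Sequence[TreeRecord],
                max_distance: float = DEFAULT_MAX_DISTANCE) -> FusionOutput:
    """One-to-one matching minimising total planimetric distance.

    Pairs farther apart than ``max_distance`` are disallowed.  Exact
    distance ties resolve in favour of lower tree ids.  Symmetric in its
    two inputs (up to the ALS/TLS roles of the fused attributes).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    als = sorted(als_trees, key=lambda t: t.tree_id)
    tls = sorted(tls_trees, key=lambda t: t.tree_id)
    if not als or not tls:
        return FusionOutput([], [t.tree_id for t in als],
                            [t.tree_id for t in tls])

    ax = np.array([[t.x, t.y] for t in als])
    tx = np.array([[t.x, t.y] for t in tls])
    dist = np.hypot(ax[:, None, 0] - tx[None, :, 0],
                    ax[:, None, 1] - tx[None, :, 1])

    big = 1e9
    cost = np.where(dist <= max_distance, dist, big)
    # Deterministic tie-break: bias exact ties toward earlier (lower-id)
    # rows/cols by an amount far below any physical distance difference.
    eps = 1e-9
    cost = cost + eps * (np.arange(len(als))[:, None]
                         + np.arange(len(tls))[None, :])
    rows, cols = linear_sum_assignment(cost)

    matches: List[MatchResult] = []
    matched_a, matched_t = set(), set()
    for i, j in zip(rows, cols):
        if dist[i, j] > max_distance:
            continue
        matches.append(MatchResult(
            als_tree_id=als[i].tree_id, tls_tree_id=tls[j].tree_id,
            distance=float(dist[i, j]), fused=_fuse(als[i], tls[j])))
        matched_a.add(i)
        matched_t.add(j)
    return FusionOutput(
        matches=matches,
        unmatched_als=[als[i].tree_id for i in range(len(als))
                       if i not in matched_a],
        unmatched_tls=[tls[j].tree_id for j in range(len(tls))
                       if j not in matched_t])
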
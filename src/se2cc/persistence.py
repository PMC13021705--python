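"""Persistence of delta-connected components: sweeps, diagrams, delta selection.

As delta grows, components only merge, so the component count K(delta) is
non-increasing.  For finite point clouds delta-connectivity is single-linkage
clustering at threshold delta: component deaths coincide with the edge
weights of the minimum spanning tree of the pairwise-distance graph, and the
elder rule (the older component survives each merge) yields the classical
(birth, death) persistence pairs, all born at 0.

A good delta is one on a long plateau of K(delta): persistent components,
at the smallest delta that achieves them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .components import find_all_components, find_all_components_points
from .fields import LiftedBinarySet
from .se2 import MetricWeights, pairwise_distances

logger = logging.getLogger("se2cc")


@dataclass(frozen=True)
class PersistencePair:
    """Birth/death record of one component; the representative is the lowest
    point index of the component (elder rule).  Death is +inf for the one
    survivor of each final connected cluster."""

    component: int
    birth: float
    death: float


@dataclass
class DeltaSweep:
    """K(delta) and component sizes over an increasing delta grid."""

    deltas: np.ndarray
    counts: np.ndarray
    sizes: list = field(default_factory=list)
    labelings: list = field(default_factory=list)


def sweep(I, delta_grid, w: MetricWeights) -> DeltaSweep:
    """Run the component algorithm for every delta in a strictly increasing grid.

    ``I`` may be a :class:`LiftedBinarySet` or an (n, 3) point array.
    """
    deltas = np.asarray(delta_grid, dtype=float)
    if len(deltas) == 0 or np.any(deltas <= 0) or np.any(np.diff(deltas) <= 0):
        raise ValueError("delta_grid must be strictly increasing and positive")
    counts, sizes, labelings = [], [], []
    for d in deltas:
        if isinstance(I, LiftedBinarySet):
            labels, diag = find_all_components(I, float(d), w,
                                               compute_bounds=False)
            lab = labels.labels
        else:
            lab, diag = find_all_components_points(I, float(d), w)
        counts.append(len(diag.sizes))
        sizes.append(list(diag.sizes))
        labelings.append(lab)
    return DeltaSweep(deltas=deltas, counts=np.asarray(counts, dtype=int),
                      sizes=sizes, labelings=labelings)


def persistence_diagram(points: np.ndarray, w: MetricWeights) -> list:
    """Elder-rule single-linkage persistence pairs of a finite point cloud.

    Every point is born at 0.  Processing minimum-spanning-tree edges in
    increasing order, each merge kills the younger (higher representative
    index) component at the edge weight; the survivor of each final cluster
    gets death +inf.  Returns n pairs sorted by representative index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 0:
        return []
    dist = pairwise_distances(pts, w)
    upper = np.triu(dist, k=1)
    # csr drops explicit zeros; keep duplicate points connected at ~0 weight
    iu, ju = np.triu_indices(n, k=1)
    zero = upper[iu, ju] == 0.0
    upper[iu[zero], ju[zero]] = 1e-300
    mst = minimum_spanning_tree(csr_matrix(upper))
    rows, cols = mst.nonzero()
    weights = np.asarray(mst[rows, cols]).ravel()
    order = np.argsort(weights, kind="stable")

    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    deaths = {}
    for e in order:
        ra, rb = find(rows[e]), find(cols[e])
        if ra == rb:
            continue
        old, young = (ra, rb) if ra < rb else (rb, ra)
        deaths[young] = float(weights[e])
        parent[young] = old
    pairs = [PersistencePair(component=i, birth=0.0,
                             death=deaths.get(i, np.inf)) for i in range(n)]
    return pairs


def plot_sweep(sw: DeltaSweep, ax=None):
    """Step plot of K(delta); returns the matplotlib axes."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.step(sw.deltas, sw.counts, where="post")
    ax.set_xlabel(r"$\delta$")
    ax.set_ylabel("number of components")
    return ax


def plot_diagram(pairs, ax=None):
    """Birth/death persistence diagram; infinite deaths drawn at the top."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    finite = [p.death for p in pairs if np.isfinite(p.death)]
    top = 1.1 * max(finite) if finite else 1.0
    for p in pairs:
        d = p.death if np.isfinite(p.death) else top
        ax.plot([p.birth, d], [p.component, p.component], lw=2)
    ax.set_xlabel(r"$\delta$")
    ax.set_ylabel("component")
    return ax


def suggest_delta(sw: DeltaSweep) -> tuple:
    """Longest plateau of K(delta) with 1 < K < K(min delta); ties to smaller delta.

    Returns ``((delta_lo, delta_hi), K)``.  If no interior plateau exists,
    the full range is returned with a logged warning.
    """
    deltas, counts = sw.deltas, sw.counts
    if len(deltas) == 0:
        raise ValueError("sweep is empty")
    runs = []  # (start_idx, end_idx) inclusive, constant K
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((start, i - 1))
            start = i
    k0 = counts[0]
    best = None
    for a, b in runs:
        k = int(counts[a])
        if not (1 < k < k0):
            continue
        length = deltas[b] - deltas[a]
        if best is None or length > best[0] + 1e-15:
            best = (length, a, b, k)
    if best is None:
        logger.warning("no interior plateau with 1 < K < K(min delta); "
                       "returning the full delta range")
        return (float(deltas[0]), float(deltas[-1])), int(k0)
    _, a, b, k = best
    return (float(deltas[a]), float(deltas[b])), k
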
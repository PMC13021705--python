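"""Affinity matrices between delta-connected components, and threshold grouping.

The affinity a_ij in (0, 1] measures how close and how well aligned two
components are under the left-invariant metric.  Component i is encoded as a
data-weighted, sup-normalized mass

    W_i^(0) = D * 1_{[g_i]} / sup_{[g_i]} D,

dilated once with the HJB kernel (alpha > 1) for a time t large enough that
the dilated mass is strictly positive on all of I (t above the
diameter-based threshold r^alpha * beta^(1-alpha)).  The affinity is the
larger of the two directed p-means

    a_ij = max_{(i,j),(j,i)} ( (1/mu([g_j])) int_{[g_j]} phi_t^alpha(W_i^(0))^p )^(1/p),

with mu the uniform Haar volume of the component (node count times cell
volume, which cancels in the normalized mean).  With a constant data term
the diagonal is exactly 1 and off-diagonal entries sit strictly between the
analytic bounds 1 - (t/beta)(r/t)^beta and 1 - (t/beta)(delta/t)^beta.

Components whose affinity exceeds a user threshold T are merged by taking
connected components of the graph with edges a_ij > T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import LabelField, LiftedBinarySet, LiftedField
from .morphology import MorphParams, dilate_exact
from .se2 import MetricWeights, _relative_offsets, log_norm


@dataclass
class AffinityMatrix:
    """Symmetric K x K affinities with the parameters that produced them."""

    values: np.ndarray
    alpha: float
    t: float
    p: float
    weights: MetricWeights

    @property
    def K(self) -> int:
        return self.values.shape[0]


def init_mass(component: LiftedBinarySet, D: LiftedField) -> LiftedField:
    """Sup-normalized data mass of one component: D * 1_C / sup_C D.

    Maximum value exactly 1, zero outside the component.  Raises if the data
    term vanishes identically on the component.
    """
    if component.grid != D.grid:
        raise ValueError("component and data term must share a grid")
    vals = np.where(component.mask, D.values, 0.0)
    peak = vals.max()
    if peak <= 0:
        raise ValueError("data term is identically zero on the component")
    return LiftedField(component.grid, vals / peak)


def set_diameter(I: LiftedBinarySet | np.ndarray, w: MetricWeights,
                 chunk: int = 512) -> float:
    """Maximum pairwise log-norm distance over the active nodes."""
    coords = I.node_coords() if isinstance(I, LiftedBinarySet) else \
        np.atleast_2d(np.asarray(I, dtype=float))
    n = len(coords)
    if n < 2:
        return 0.0
    r = 0.0
    for a in range(0, n, chunk):
        dx, dy, dth = _relative_offsets(coords[a:a + chunk, None, :],
                                        coords[None, :, :])
        r = max(r, float(log_norm(dx, dy, dth, w).max()))
    return r


def min_dilation_time(I: LiftedBinarySet | np.ndarray, alpha: float,
                      w: MetricWeights, floor: float = 1e-3,
                      safety: float = 1.01) -> float:
    """Dilation time guaranteeing nonzero affinities between all components.

    Returns ``safety * r^alpha * beta^(1-alpha)`` with r the diameter of the
    active set -- strictly above the analytic threshold, so one dilation of
    any component's mass is positive on all of I.  A degenerate set (r = 0)
    gets the configured floor.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    beta = alpha / (alpha - 1.0)
    r = set_diameter(I, w)
    if r == 0.0:
        return floor
    return max(floor, safety * r ** alpha * beta ** (1.0 - alpha))


def affinity_matrix(labels: LabelField, D: LiftedField, alpha: float,
                    t: float, p: float, w: MetricWeights) -> AffinityMatrix:
    """Pairwise affinities between all labeled components.

    ``t`` should be at least :func:`min_dilation_time` of the labeled set for
    the entries to be guaranteed positive.  K = 0 yields an empty matrix.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if p < 1:
        raise ValueError("p must be >= 1")
    K = labels.K
    A = np.zeros((K, K))
    if K == 0:
        return AffinityMatrix(A, alpha, t, p, w)
    params = MorphParams(alpha=alpha, t=t, weights=w)
    comp_nodes = [np.argwhere(labels.labels == c + 1) for c in range(K)]
    directed = np.zeros((K, K))
    for i in range(K):
        mass = init_mass(labels.component_mask(i + 1), D)
        dilated = dilate_exact(mass, params).values
        for j in range(K):
            nd = comp_nodes[j]
            vals = dilated[nd[:, 0], nd[:, 1], nd[:, 2]]
            directed[i, j] = float(np.mean(vals ** p) ** (1.0 / p))
    A = np.maximum(directed, directed.T)
    A[np.diag_indices(K)] = np.diag(directed)
    return AffinityMatrix(A, alpha, t, p, w)


def group_by_affinity(A: AffinityMatrix, T: float) -> dict:
    """Merge components whose affinity exceeds T (strict inequality).

    Builds the graph on components with edges a_ij > T (i != j) and returns
    an old-label -> new-label map; new labels are numbered by the smallest
    old label in each merged group.
    """
    if not (0 <= T <= 1):
        raise ValueError("T must be in [0, 1]")
    K = A.K
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(K):
        for j in range(i + 1, K):
            if A.values[i, j] > T:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(i) for i in range(K)})
    root_new = {r: idx + 1 for idx, r in enumerate(roots)}
    return {i + 1: root_new[find(i)] for i in range(K)}


def merge_labels(labels: LabelField, mapping: dict) -> LabelField:
    """Apply an old-label -> new-label map to a label field."""
    lut = np.zeros(labels.K + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return LabelField(labels.grid, lut[labels.labels])
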
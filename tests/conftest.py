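"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

import se2cc as s


@pytest.fixture
def w111():
    return s.MetricWeights(1.0, 1.0, 1.0)


@pytest.fixture
def w_aniso():
    return s.MetricWeights(0.1, 1.0, 4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------- oracles

def mat_of(g: s.GroupElement) -> np.ndarray:
    """Homogeneous 3x3 matrix of a group element (independent oracle)."""
    c, si = math.cos(g.theta), math.sin(g.theta)
    return np.array([[c, -si, g.x], [si, c, g.y], [0, 0, 1.0]])


def element_of(m: np.ndarray) -> s.GroupElement:
    return s.GroupElement(m[0, 2], m[1, 2], math.atan2(m[1, 0], m[0, 0]))


def bfs_partition(coords: np.ndarray, delta: float, w) -> set:
    """Partition of a point set into components of the <=delta graph (BFS)."""
    D = s.pairwise_distances(coords, w)
    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    ii, jj = np.where(np.triu(D <= delta, 1))
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return {frozenset(c) for c in nx.connected_components(G)}


def label_partition_points(labels: np.ndarray) -> set:
    return {frozenset(np.flatnonzero(labels == l).tolist())
            for l in range(1, int(labels.max(initial=0)) + 1)}


def label_partition_grid(label_field, nodes: np.ndarray) -> set:
    lab = label_field.labels[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
    return label_partition_points(lab)


def brute_force_dilate(f: s.LiftedField, params: s.MorphParams) -> np.ndarray:
    """sup_h { f(h) - kappa(d(h, g)) } by exhaustive distance evaluation."""
    grid = f.grid
    nodes = np.argwhere(np.ones(grid.shape, dtype=bool))
    coords = grid.node_coords(nodes)
    vals = f.values[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
    out = np.empty(len(nodes))
    for q, c in enumerate(coords):
        d = s.pairwise_distances(np.vstack([c[None, :], coords]),
                                 params.weights)[0, 1:]
        out[q] = np.max(vals - s.kernel_value(d, params))
    res = np.zeros(grid.shape)
    res[nodes[:, 0], nodes[:, 1], nodes[:, 2]] = out
    return res


def random_cloud(rng, n, extent=20.0) -> np.ndarray:
    return np.column_stack([
        rng.uniform(0, extent, n), rng.uniform(0, extent, n),
        rng.uniform(0, 2 * math.pi, n)])
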
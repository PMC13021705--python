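"""Dense containers for functions, binary sets and labels on an (x, y, theta) grid.

Arrays are stored with axis order (x-index, y-index, theta-index); the last
axis is periodic (orientations), the spatial axes are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .se2 import LiftedGrid


def _check_shape(grid: LiftedGrid, values: np.ndarray):
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} does not match grid "
                         f"shape {grid.shape}")


@dataclass
class LiftedField:
    """A real scalar per (i, j, k) node; finite values only."""

    grid: LiftedGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        _check_shape(self.grid, self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LiftedField values must be finite")

    @classmethod
    def zeros(cls, grid: LiftedGrid) -> "LiftedField":
        return cls(grid, np.zeros(grid.shape))

    def copy(self) -> "LiftedField":
        return LiftedField(self.grid, self.values.copy())


@dataclass
class LiftedBinarySet:
    """Indicator of a compact reference set on the grid (boolean mask)."""

    grid: LiftedGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_shape(self.grid, self.mask)

    @classmethod
    def empty(cls, grid: LiftedGrid) -> "LiftedBinarySet":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def from_nodes(cls, grid: LiftedGrid, nodes: np.ndarray) -> "LiftedBinarySet":
        """Build from an (n, 3) array of integer (i, j, k) node indices."""
        mask = np.zeros(grid.shape, dtype=bool)
        nodes = np.atleast_2d(np.asarray(nodes, dtype=int))
        if nodes.size:
            mask[nodes[:, 0], nodes[:, 1], nodes[:, 2] % grid.No] = True
        return cls(grid, mask)

    def nodes(self) -> np.ndarray:
        """Active nodes as an (n, 3) integer array in (i, j, k) scan order."""
        return np.argwhere(self.mask)

    def node_coords(self) -> np.ndarray:
        """World coordinates (x, y, theta) of the active nodes."""
        return self.grid.node_coords(self.nodes())

    @property
    def size(self) -> int:
        return int(np.count_nonzero(self.mask))

    def indicator(self) -> LiftedField:
        return LiftedField(self.grid, self.mask.astype(float))

    def copy(self) -> "LiftedBinarySet":
        return LiftedBinarySet(self.grid, self.mask.copy())


@dataclass
class LabelField:
    """Integer component labels per node; 0 = background, 1..K = components."""

    grid: LiftedGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        _check_shape(self.grid, self.labels)

    @property
    def K(self) -> int:
        return int(self.labels.max(initial=0))

    def component_mask(self, label: int) -> LiftedBinarySet:
        return LiftedBinarySet(self.grid, self.labels == label)

    def component_sizes(self) -> np.ndarray:
        """Node count per label 1..K."""
        return np.bincount(self.labels.ravel(), minlength=self.K + 1)[1:]
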
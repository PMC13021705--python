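"""Synthetic test scenes: crossing lines, ovals, interrupted vessels, point clouds.

Every fixture is deterministic given its seed and ships pixel-precise (or
point-index) ground truth per structure, so that split/merge scores can be
evaluated without any external data.  Image fixtures emulate the situations
where planar connected-component labeling fails: structures that cross (one
blob in 2D, distinct in SE(2)) and structures with small interruptions.

Conventions match the rest of the package: images are indexed (i, j) with i
the x-index, and angles are measured from +x toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class GroundTruthTrees:
    """Ground-truth structures: for images a list of 2D boolean masks, for
    point clouds a list of point-index arrays.

    ``angles`` optionally records one orientation per structure (straight
    lines); :meth:`lifted` then produces orientation-resolved 3D masks whose
    lifted supports are disjoint even where the 2D masks cross.
    """

    trees: list
    angles: list | None = None

    @property
    def N(self) -> int:
        return len(self.trees)

    def lifted(self, No: int, window: float | None = None) -> "GroundTruthTrees":
        """Lift 2D line masks to (x, y, theta) bands around each line's angle.

        A pixel of tree i becomes active on the orientation layers whose
        theta is within ``window`` of the line angle modulo pi (both
        antipodal bands; a line is an unoriented structure).  The default
        window is 1.25 grid steps, narrow enough that lines more than 2.5
        steps apart in angle get disjoint lifted supports.
        """
        if self.angles is None:
            raise ValueError("this ground truth has no per-structure angles")
        dtheta = 2.0 * math.pi / No
        if window is None:
            window = 1.25 * dtheta
        thetas = np.arange(No) * dtheta
        out = []
        for mask, a in zip(self.trees, self.angles):
            dist_mod_pi = np.abs((thetas - a + math.pi / 2) % math.pi
                                 - math.pi / 2)
            layers = dist_mod_pi <= window
            m3 = np.zeros(mask.shape + (No,), dtype=bool)
            m3[mask] = layers
            out.append(m3)
        return GroundTruthTrees(out, angles=self.angles)


def _line_mask(size: int, angle: float, offset: float = 0.0,
               width: float = 1.2) -> np.ndarray:
    """Pixels within ``width`` of the line through the center at ``angle``."""
    c = (size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    # signed distance to the line x(t) = center + t*(cos a, sin a) + offset*n
    nx, ny = -math.sin(angle), math.cos(angle)
    d = (ii - c) * nx + (jj - c) * ny - offset
    return np.abs(d) <= width


def _ellipse_ring_mask(size: int, ra: float, rb: float, angle: float,
                       width: float = 1.2) -> np.ndarray:
    c = (size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    ca, sa = math.cos(angle), math.sin(angle)
    u = (ii - c) * ca + (jj - c) * sa
    v = -(ii - c) * sa + (jj - c) * ca
    r = np.hypot(u / ra, v / rb)
    # approximate band of constant thickness around the unit level set
    grad = np.hypot(u / ra ** 2, v / rb ** 2) / np.maximum(r, 1e-9)
    return np.abs(r - 1.0) <= width * grad


def _curve_mask(size: int, x0: float, amp: float, period: float,
                phase: float, width: float = 1.2) -> np.ndarray:
    """Band around the smooth curve x(j) = x0 + amp*sin(2*pi*j/period + phase)."""
    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    center = x0 + amp * np.sin(2.0 * math.pi * jj / period + phase)
    return np.abs(ii - center) <= width


def _gap_mask(size: int, rng: np.random.Generator, n_gaps: int,
              gap_len: float, axis: int = 1) -> np.ndarray:
    """True outside the gaps; gaps are slabs perpendicular to ``axis``."""
    keep = np.ones(size, dtype=bool)
    starts = rng.choice(np.arange(int(0.15 * size), int(0.85 * size)),
                        size=n_gaps, replace=False)
    for s in starts:
        keep[s:s + int(round(gap_len))] = False
    out = np.ones((size, size), dtype=bool)
    if axis == 1:
        out[:, ~keep] = False
    else:
        out[~keep, :] = False
    return out


def generate_fixture(kind: str, size: int = 128, seed: int = 0, **kw):
    """Deterministic synthetic scene with ground truth.

    Kinds: ``crossing_lines`` (two straight lines sharing only the crossing
    pixels), ``ovals_lines`` (an ellipse ring plus lines), ``interrupted_vessels``
    (smooth curves with gaps; keyword ``gap_len`` sets the gap length in
    pixels), ``scatter7`` (seven planar points in three groups) and
    ``circle20plus2`` (20 points on a circle with tangential orientations,
    plus two outliers).  Image kinds return ``(image, GroundTruthTrees)``
    with per-structure pixel masks; point kinds return ``(points,
    GroundTruthTrees)`` with per-group index arrays.
    """
    rng = np.random.default_rng(seed)
    if kind == "crossing_lines":
        a1 = rng.uniform(0.0, math.pi / 6.0)
        a2 = a1 + math.pi / 2.0 + rng.uniform(-math.pi / 24.0, math.pi / 24.0)
        width = kw.get("width", 1.2)
        m1 = _line_mask(size, a1, width=width)
        m2 = _line_mask(size, a2, width=width)
        image = np.where(m1 | m2, 1.0, 0.0)
        return image, GroundTruthTrees([m1, m2], angles=[a1, a2])
    if kind == "ovals_lines":
        a_line = rng.uniform(-math.pi / 16.0, math.pi / 16.0)
        ring = _ellipse_ring_mask(size, 0.32 * size, 0.20 * size,
                                  rng.uniform(-math.pi / 12.0, math.pi / 12.0))
        line = _line_mask(size, a_line, offset=rng.uniform(-3, 3))
        image = np.where(ring | line, 1.0, 0.0)
        return image, GroundTruthTrees([ring, line])
    if kind == "interrupted_vessels":
        gap_len = kw.get("gap_len", 6.0)
        n_gaps = kw.get("n_gaps", 2)
        amp = kw.get("amp", 0.04 * size)
        masks = []
        for x0 in (0.35 * size, 0.65 * size):
            full = _curve_mask(size, x0, amp, period=1.6 * size,
                               phase=rng.uniform(0, 2 * math.pi))
            gaps = _gap_mask(size, rng, n_gaps, gap_len, axis=1)
            masks.append(full & gaps)
        image = np.where(masks[0] | masks[1], 1.0, 0.0)
        return image, GroundTruthTrees(masks)
    if kind == "scatter7":
        centers = np.array([[0.0, 0.0], [1.5, 1.0], [0.8, -1.2],
                            [8.0, 7.5], [9.2, 8.3],
                            [16.0, 1.0], [17.2, 0.2]])
        pts2 = centers + rng.normal(scale=0.15, size=centers.shape)
        points = np.column_stack([pts2, np.zeros(len(pts2))])
        groups = [np.array([0, 1, 2]), np.array([3, 4]), np.array([5, 6])]
        return points, GroundTruthTrees(groups)
    if kind == "circle20plus2":
        radius = kw.get("radius", 5.0)
        ang = 2.0 * math.pi * np.arange(20) / 20.0
        xs = radius * np.cos(ang)
        ys = radius * np.sin(ang)
        ths = np.mod(ang + math.pi / 2.0, 2.0 * math.pi)  # tangents
        circle = np.column_stack([xs, ys, ths])
        outliers = np.array([[3.0 * radius, 0.5 * radius, 0.3],
                             [-2.5 * radius, -2.0 * radius, 2.0]])
        points = np.vstack([circle, outliers])
        return points, GroundTruthTrees([np.arange(20), np.array([20]),
                                         np.array([21])])
    raise ValueError(f"unknown fixture kind: {kind!r}")
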
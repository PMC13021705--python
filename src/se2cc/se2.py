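"""Core operations on the roto-translation group SE(2).

SE(2) is the Lie group of planar roto-translations.  An element is a pair
``(x, R_theta)`` of a translation ``x = (x, y)`` and a rotation by ``theta``,
with (non-commutative) product

    (x1, R1) (x2, R2) = (x1 + R1 x2, R1 R2).

The group carries a left-invariant Riemannian metric with diagonal weights
``(w1, w2, w3)`` in the moving frame of forward (A1), lateral (A2) and
angular (A3) directions.  Exact Riemannian distances are expensive; this
module implements the standard *logarithmic norm approximation*

    d(g, h) ~ || Log(g^-1 h) ||_w
            = sqrt(w1 c1^2 + w2 c2^2 + w3 c3^2),

where (c1, c2, c3) are the Lie-algebra coordinates of the group logarithm.
The approximation is exact for small separations and is what every distance
in this package uses.

The module also builds discrete ball stencils: for each orientation layer of
an (x, y, theta) grid, the set of integer node offsets whose log-norm
distance (measured in that layer's rotated frame) does not exceed a given
radius.  These stencils drive the morphological dilations in
:mod:`se2cc.morphology`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("se2cc")

TWO_PI = 2.0 * math.pi


def wrap_2pi(theta):
    """Wrap angle(s) to [0, 2*pi)."""
    t = np.mod(theta, TWO_PI)
    # float mod of a tiny negative lands exactly on 2*pi; keep the interval
    return np.where(t >= TWO_PI, 0.0, t) if isinstance(t, np.ndarray) else (
        0.0 if t >= TWO_PI else t)


def wrap_pi(theta):
    """Wrap angle(s) to (-pi, pi]."""
    t = np.mod(theta, TWO_PI)
    return np.where(t > math.pi, t - TWO_PI, t) if isinstance(t, np.ndarray) else (
        t - TWO_PI if t > math.pi else t
    )


@dataclass(frozen=True)
class GroupElement:
    """An element (x, y, theta) of SE(2); theta stored wrapped to [0, 2*pi)."""

    x: float
    y: float
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "theta", float(wrap_2pi(self.theta)))

    @classmethod
    def identity(cls) -> "GroupElement":
        return cls(0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix representation."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s, self.x], [s, c, self.y], [0.0, 0.0, 1.0]])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "GroupElement":
        return cls(float(m[0, 2]), float(m[1, 2]),
                   math.atan2(float(m[1, 0]), float(m[0, 0])))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta])


@dataclass(frozen=True)
class AlgebraCoords:
    """Lie-algebra (logarithm) coordinates.

    ``c1``/``c2`` are the tangential/lateral log-coordinates, ``c3`` the
    angular one in (-pi, pi].
    """

    c1: float
    c2: float
    c3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3])


@dataclass(frozen=True)
class MetricWeights:
    """Diagonal left-invariant metric weights: all strictly positive.

    ``w1`` prices forward (tangential) motion, ``w2`` lateral motion and
    ``w3`` changes of orientation.
    """

    w1: float
    w2: float
    w3: float

    def __post_init__(self):
        if not (self.w1 > 0 and self.w2 > 0 and self.w3 > 0):
            raise ValueError(f"metric weights must be strictly positive, got "
                             f"({self.w1}, {self.w2}, {self.w3})")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


def group_product(g1: GroupElement, g2: GroupElement) -> GroupElement:
    """Group product (x1 + R1 x2, theta1 + theta2 mod 2*pi)."""
    c, s = math.cos(g1.theta), math.sin(g1.theta)
    return GroupElement(g1.x + c * g2.x - s * g2.y,
                        g1.y + s * g2.x + c * g2.y,
                        g1.theta + g2.theta)


def group_inverse(g: GroupElement) -> GroupElement:
    """Group inverse (-R_theta^-1 x, -theta mod 2*pi)."""
    c, s = math.cos(g.theta), math.sin(g.theta)
    return GroupElement(-(c * g.x + s * g.y), -(-s * g.x + c * g.y), -g.theta)


def _log_coords(dx, dy, dtheta):
    """Lie-algebra coordinates of the element (dx, dy, dtheta), vectorized.

    ``dtheta`` must already be wrapped to (-pi, pi].  Uses the closed form
    (c1, c2) = (theta/2) (x cot(theta/2) + y, -x + y cot(theta/2)),
    continuous at theta = pi (cot(pi/2) = 0) and equal to (x, y) at theta = 0.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    c3 = np.asarray(dtheta, dtype=float)
    half = 0.5 * c3
    small = np.abs(half) < 1e-12
    tan_half = np.where(small, 1.0, np.tan(half))
    a = np.where(small, 1.0, half / tan_half)  # (theta/2) cot(theta/2)
    c1 = a * dx + half * dy
    c2 = -half * dx + a * dy
    return c1, c2, c3


def log_map(g: GroupElement) -> AlgebraCoords:
    """Group logarithm of ``g``; the angle is wrapped to (-pi, pi] first."""
    th = wrap_pi(g.theta)
    c1, c2, c3 = _log_coords(g.x, g.y, th)
    return AlgebraCoords(float(c1), float(c2), float(c3))


def exp_map(c: AlgebraCoords) -> GroupElement:
    """Group exponential; inverse of :func:`log_map` (for c3 in (-pi, pi))."""
    th = c.c3
    if abs(th) < 1e-12:
        return GroupElement(c.c1, c.c2, th)
    s, co = math.sin(th), math.cos(th)
    # V = (1/theta) [[sin, -(1-cos)], [1-cos, sin]]
    x = (s * c.c1 - (1.0 - co) * c.c2) / th
    y = ((1.0 - co) * c.c1 + s * c.c2) / th
    return GroupElement(x, y, th)


def _relative_offsets(g_arr: np.ndarray, h_arr: np.ndarray):
    """Offsets (dx, dy, dtheta) of g^-1 h in the frame of g, vectorized.

    Inputs broadcast; columns are (x, y, theta).
    """
    dth = wrap_pi(np.asarray(h_arr[..., 2] - g_arr[..., 2], dtype=float))
    ex = h_arr[..., 0] - g_arr[..., 0]
    ey = h_arr[..., 1] - g_arr[..., 1]
    c, s = np.cos(g_arr[..., 2]), np.sin(g_arr[..., 2])
    # rotate the world-frame spatial offset by -theta_g
    dx = c * ex + s * ey
    dy = -s * ex + c * ey
    return dx, dy, dth


def log_norm(dx, dy, dtheta, w: MetricWeights):
    """Weighted log-norm of the element (dx, dy, dtheta); dtheta in (-pi, pi]."""
    c1, c2, c3 = _log_coords(dx, dy, dtheta)
    return np.sqrt(w.w1 * c1 ** 2 + w.w2 * c2 ** 2 + w.w3 * c3 ** 2)


def approx_distance(g: GroupElement, h: GroupElement, w: MetricWeights) -> float:
    """Left-invariant distance approximation ||Log(g^-1 h)||_w.

    Symmetric for diagonal weights, zero iff g == h, and left-invariant:
    d(pg, ph) = d(g, h) for any p.
    """
    dx, dy, dth = _relative_offsets(g.as_array(), h.as_array())
    return float(log_norm(dx, dy, dth, w))


def pairwise_distances(points: np.ndarray, w: MetricWeights) -> np.ndarray:
    """All pairwise log-norm distances between rows of an (n, 3) array."""
    p = np.asarray(points, dtype=float)
    dx, dy, dth = _relative_offsets(p[:, None, :], p[None, :, :])
    return log_norm(dx, dy, dth, w)


def distances_from(point: np.ndarray, points: np.ndarray, w: MetricWeights) -> np.ndarray:
    """Distances from one (3,) point to all rows of an (n, 3) array."""
    p0 = np.asarray(point, dtype=float)
    p = np.asarray(points, dtype=float)
    dx, dy, dth = _relative_offsets(p0[None, :], p)
    return log_norm(dx, dy, dth, w)


_SIGN_FLIPS = [(s1, s2, s3) for s1 in (1, -1) for s2 in (1, -1) for s3 in (1, -1)]


def reflection_invariance_count(w: MetricWeights, samples: np.ndarray,
                                tol: float = 1e-12) -> int:
    """Count Lie-algebra sign-flip maps leaving the weighted log-norm invariant.

    Enumerates all 8 maps (c1, c2, c3) -> (+-c1, +-c2, +-c3) and checks
    invariance of ||.||_w on the log-coordinates of every sample.  For a
    diagonal metric the norm is a sum of squares, so all 2^3 maps are
    invariances; this mirrors the reflectional symmetries that the distance
    (and hence the component algorithm) inherits.
    """
    p = np.atleast_2d(np.asarray(samples, dtype=float))
    if p.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    c1, c2, c3 = _log_coords(p[:, 0], p[:, 1], wrap_pi(p[:, 2]))
    base = np.sqrt(w.w1 * c1 ** 2 + w.w2 * c2 ** 2 + w.w3 * c3 ** 2)
    count = 0
    for s1, s2, s3 in _SIGN_FLIPS:
        flipped = np.sqrt(w.w1 * (s1 * c1) ** 2 + w.w2 * (s2 * c2) ** 2
                          + w.w3 * (s3 * c3) ** 2)
        if np.all(np.abs(flipped - base) <= tol):
            count += 1
    return count


@dataclass(frozen=True)
class LiftedGrid:
    """The discretized (x, y, theta) domain.

    ``Nx``/``Ny`` spatial sample counts, ``No`` equispaced orientations on the
    full circle [0, 2*pi); spacings ``dx``/``dy`` (pixels by default) and
    ``dtheta = 2*pi/No``.
    """

    Nx: int
    Ny: int
    No: int
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self):
        if self.Nx < 1 or self.Ny < 1 or self.No < 1:
            raise ValueError("all grid counts must be >= 1")

    @property
    def dtheta(self) -> float:
        return TWO_PI / self.No

    @property
    def shape(self) -> tuple:
        return (self.Nx, self.Ny, self.No)

    def theta(self, k) -> np.ndarray:
        return np.asarray(k) * self.dtheta

    def node_coords(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (x, y, theta) of integer nodes (i, j, k)."""
        idx = np.atleast_2d(np.asarray(idx))
        return np.column_stack([idx[:, 0] * self.dx, idx[:, 1] * self.dy,
                                idx[:, 2] * self.dtheta])

    def snap(self, points: np.ndarray) -> np.ndarray:
        """Nearest integer node (i, j, k) for each (x, y, theta) row."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        i = np.clip(np.rint(p[:, 0] / self.dx).astype(int), 0, self.Nx - 1)
        j = np.clip(np.rint(p[:, 1] / self.dy).astype(int), 0, self.Ny - 1)
        k = np.rint(wrap_2pi(p[:, 2]) / self.dtheta).astype(int) % self.No
        return np.column_stack([i, j, k])


@dataclass
class BallStencil:
    """Per-layer integer offsets within a log-norm ball, with kernel values.

    ``layers[k]`` is a pair ``(offsets, dist)``: an (m, 3) int array of
    (di, dj, dm) node offsets and the (m,) distances at which they sit.  The
    distance of offset (di, dj, dm) at layer k is the log-norm of the group
    element whose spatial part is (di*dx, dj*dy) rotated into the frame of
    theta_k = k*dtheta and whose angle is dm*dtheta wrapped to (-pi, pi] --
    exact at grid nodes, no interpolation.  Membership uses the closed
    inequality d <= radius.
    """

    grid: LiftedGrid
    weights: MetricWeights
    radius: float
    layers: list = field(default_factory=list)

    def kernel_values(self, kernel) -> list:
        """Apply ``kernel(dist)`` per layer, returning a list of value arrays."""
        return [np.asarray(kernel(d)) for _, d in self.layers]


def build_ball_stencil(grid: LiftedGrid, w: MetricWeights, radius: float) -> BallStencil:
    """Discrete ball B(., radius) per orientation layer of the grid.

    For output layer k the offsets point at neighbors h = (i+di, j+dj,
    (k+dm) mod No) of a node g = (i, j, k) with d(g, h) <= radius.  If the
    spatial reach of the ball exceeds the grid extent, a warning is logged
    and the stencil is clipped at the domain size.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    wmin = min(w.w1, w.w2)
    reach_x = radius / (math.sqrt(wmin))
    di_max = int(math.ceil(reach_x / grid.dx))
    dj_max = int(math.ceil(reach_x / grid.dy))
    if di_max > grid.Nx - 1 or dj_max > grid.Ny - 1:
        logger.warning("ball radius %.3g reaches past the grid extent "
                       "(spatial reach %.3g); stencil clipped at domain size",
                       radius, reach_x)
        di_max = min(di_max, grid.Nx - 1)
        dj_max = min(dj_max, grid.Ny - 1)
    # angular reach: |c3| = |dm*dtheta wrapped| <= radius/sqrt(w3)
    dm_half = grid.No // 2
    dm_all = np.arange(-dm_half, grid.No - dm_half)  # one full period
    ang_all = wrap_pi(dm_all * grid.dtheta)
    dm_keep = dm_all[np.abs(ang_all) * math.sqrt(w.w3) <= radius]

    di = np.arange(-di_max, di_max + 1)
    dj = np.arange(-dj_max, dj_max + 1)
    DI, DJ = np.meshgrid(di, dj, indexing="ij")
    DI, DJ = DI.ravel(), DJ.ravel()
    ox_base, oy_base = DI * grid.dx, DJ * grid.dy

    layers = []
    for k in range(grid.No):
        th = k * grid.dtheta
        c, s = math.cos(th), math.sin(th)
        offs, dists = [], []
        for dm in dm_keep:
            ang = wrap_pi(dm * grid.dtheta)
            # spatial offset pre-rotated by -theta_k
            rx = c * ox_base + s * oy_base
            ry = -s * ox_base + c * oy_base
            d = log_norm(rx, ry, np.full_like(rx, ang), w)
            keep = d <= radius
            if not np.any(keep):
                continue
            m = int(np.count_nonzero(keep))
            block = np.empty((m, 3), dtype=np.int64)
            block[:, 0] = DI[keep]
            block[:, 1] = DJ[keep]
            block[:, 2] = dm
            offs.append(block)
            dists.append(d[keep])
        offsets = np.concatenate(offs, axis=0)
        layers.append((offsets, np.concatenate(dists)))
    return BallStencil(grid=grid, weights=w, radius=radius, layers=layers)
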
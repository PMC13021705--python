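"""Morphological convolutions and Hamilton-Jacobi-Bellman dilations on SE(2).

The dilation flow phi_t^alpha is the viscosity solution of the HJB equation
dW/dt = (1/alpha) ||grad W||^alpha and equals a max-plus (morphological)
convolution with the analytic kernel

    k_t^alpha(g) = (t/beta) (d(g, e)/t)^beta,    1/alpha + 1/beta = 1,

where d is the left-invariant distance (here: its log-norm approximation).
In the steep limit alpha -> 1 the kernel becomes the flat 0/inf indicator of
the ball of radius t, and dilating an indicator function exactly produces the
t-thickened set.  Applied to [0, 1]-valued fields the flow preserves the
range, and the support of the dilated indicator is the epsilon(t, alpha)-
thickened set with

    epsilon(t, alpha) = t (beta/t)^(1/beta).

Discretely the dilation is a gather over a ball stencil: the kernel equals 1
exactly at distance epsilon(t, alpha), and offsets with kernel >= 1 can never
win the max against the identity offset for [0, 1]-valued fields, so
truncating the stencil at that radius is exact.

Spatial offsets leaving the domain are dropped (compact-set setting); the
orientation axis wraps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import LiftedBinarySet, LiftedField
from .se2 import (BallStencil, LiftedGrid, MetricWeights, build_ball_stencil,
                  log_norm, wrap_pi)


@dataclass(frozen=True)
class MorphParams:
    """Parameters of a dilation flow: kernel steepness alpha >= 1, time t > 0,
    and the metric weights used for distances."""

    alpha: float
    t: float
    weights: MetricWeights

    def __post_init__(self):
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.t <= 0:
            raise ValueError("t must be > 0")

    @property
    def beta(self) -> float:
        """Conjugate exponent: 1/alpha + 1/beta = 1 (inf when alpha = 1)."""
        if self.alpha == 1:
            return math.inf
        return self.alpha / (self.alpha - 1.0)

    @property
    def epsilon(self) -> float:
        return epsilon_of(self.t, self.alpha)


def epsilon_of(t: float, alpha: float) -> float:
    """Radius of the region of influence of one dilation: t*(beta/t)^(1/beta).

    Continuous limit value t at alpha = 1.  Strictly increasing in t.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if alpha == 1:
        return t
    beta = alpha / (alpha - 1.0)
    return t * (beta / t) ** (1.0 / beta)


def kernel_value(d, p: MorphParams):
    """Morphological kernel kappa_t^alpha(d) = (t/beta)(d/t)^beta.

    For alpha = 1 this is the steep limit: 0 where d <= t, +inf beyond.
    Vectorized in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if p.alpha == 1:
        return np.where(d <= p.t, 0.0, math.inf)
    beta = p.beta
    return (p.t / beta) * (d / p.t) ** beta


class StencilDilator:
    """Reusable per-layer dilation over a ball stencil.

    Groups the stencil offsets of each output layer k by their angular
    offset dm; each group becomes a 2D structuring element applied to input
    layer (k + dm) mod No.  The per-group spatial footprints are symmetric
    under (di, dj) -> (-di, -dj) (the log-norm flips sign of the spatial
    log-coordinates only), so gather and scatter coincide.
    """

    def __init__(self, stencil: BallStencil, kernel=None):
        self.stencil = stencil
        self.grid = stencil.grid
        self.flat = kernel is None
        self._groups = []  # per layer: list of (dm, footprint, structure)
        for offsets, dists in stencil.layers:
            vals = None if kernel is None else np.asarray(kernel(dists), dtype=float)
            groups = []
            for dm in np.unique(offsets[:, 2]):
                sel = offsets[:, 2] == dm
                di, dj = offsets[sel, 0], offsets[sel, 1]
                ri = int(np.max(np.abs(di)))
                rj = int(np.max(np.abs(dj)))
                fp = np.zeros((2 * ri + 1, 2 * rj + 1), dtype=bool)
                fp[di + ri, dj + rj] = True
                if vals is None:
                    st = None
                else:
                    st = np.full(fp.shape, -math.inf)
                    st[di + ri, dj + rj] = -vals[sel]
                groups.append((int(dm), fp, st))
            self._groups.append(groups)

    def binary(self, mask: np.ndarray) -> np.ndarray:
        """Flat (alpha = 1) dilation of a boolean mask."""
        out = np.zeros_like(mask)
        No = self.grid.No
        for k, groups in enumerate(self._groups):
            acc = out[:, :, k]
            for dm, fp, _ in groups:
                src = mask[:, :, (k + dm) % No]
                if fp.shape == (1, 1):
                    acc |= src
                else:
                    acc |= ndimage.binary_dilation(src, structure=fp,
                                                   border_value=0)
            out[:, :, k] = acc
        return out

    def grey(self, values: np.ndarray) -> np.ndarray:
        """Max-plus dilation max_h { f(h) - kappa(d(h, g)) } of f >= 0."""
        out = np.zeros_like(values, dtype=float)
        No = self.grid.No
        for k, groups in enumerate(self._groups):
            acc = None
            for dm, fp, st in groups:
                src = values[:, :, (k + dm) % No]
                if st is None:
                    lay = src if fp.shape == (1, 1) else ndimage.grey_dilation(
                        src, footprint=fp, mode="constant", cval=0.0)
                else:
                    lay = ndimage.grey_dilation(src, footprint=fp, structure=st,
                                                mode="constant", cval=0.0)
                acc = lay if acc is None else np.maximum(acc, lay)
            out[:, :, k] = acc
        return out


def dilate(f: LiftedField, p: MorphParams, stencil: BallStencil | None = None
           ) -> LiftedField:
    """Dilation flow phi_t^alpha applied to a [0, 1]-valued field.

    Computed by gather over a ball stencil truncated at radius
    epsilon(t, alpha) (exact for [0, 1] fields, see module docstring).
    The output is again in [0, 1] and dominates ``f`` pointwise.
    """
    if np.any(f.values < 0) or np.any(f.values > 1):
        raise ValueError("dilate expects values in [0, 1]")
    if stencil is None:
        stencil = build_ball_stencil(f.grid, p.weights, p.epsilon)
    if p.alpha == 1:
        if set(np.unique(f.values)) <= {0.0, 1.0}:
            dil = StencilDilator(stencil)
            return LiftedField(f.grid, dil.binary(f.values > 0).astype(float))
        # flat kernel on general values: running max over the ball
        dil = StencilDilator(stencil, kernel=lambda d: np.zeros_like(d))
        return LiftedField(f.grid, np.maximum(dil.grey(f.values), f.values))
    dil = StencilDilator(stencil, kernel=lambda d: kernel_value(d, p))
    out = np.maximum(dil.grey(f.values), f.values)
    return LiftedField(f.grid, out)


def dilate_exact(f: LiftedField, p: MorphParams) -> LiftedField:
    """Untruncated dilation by direct evaluation over the support of ``f``.

    Exact sup over all grid nodes for nonnegative fields (zero-valued nodes
    can contribute at most 0, which the g = h term already achieves).  Cost
    is O(|supp f| * N); intended for the affinity stage, where the dilation
    time exceeds the set diameter and stencils would span the whole grid.
    """
    if np.any(f.values < 0):
        raise ValueError("dilate_exact expects nonnegative values")
    grid = f.grid
    supp = np.argwhere(f.values > 0)
    out = np.zeros(grid.shape)
    if supp.size == 0:
        return LiftedField(grid, out)
    v = f.values[supp[:, 0], supp[:, 1], supp[:, 2]]
    sx = supp[:, 0] * grid.dx
    sy = supp[:, 1] * grid.dy
    sth = supp[:, 2] * grid.dtheta
    ii = np.arange(grid.Nx) * grid.dx
    jj = np.arange(grid.Ny) * grid.dy
    X, Y = np.meshgrid(ii, jj, indexing="ij")
    for k in range(grid.No):
        th = k * grid.dtheta
        ang = wrap_pi(th - sth)  # angle of h^-1 g
        c, s = np.cos(sth), np.sin(sth)
        best = np.full((grid.Nx, grid.Ny), 0.0)
        for m in range(len(v)):  # support nodes
            ex = X - sx[m]
            ey = Y - sy[m]
            dx = c[m] * ex + s[m] * ey
            dy = -s[m] * ex + c[m] * ey
            d = log_norm(dx, dy, np.full_like(dx, ang[m]), p.weights)
            best = np.maximum(best, v[m] - kernel_value(d, p))
        out[:, :, k] = best
    return LiftedField(grid, out)


def thicken(setA: LiftedBinarySet, eps: float, w: MetricWeights,
            stencil: BallStencil | None = None) -> LiftedBinarySet:
    """eps-thickened set: all nodes within log-norm distance <= eps of A.

    Equals the support of phi_eps^1(1_A); always contains A.  An empty set
    thickens to an empty set.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if not setA.mask.any():
        return setA.copy()
    if stencil is None:
        stencil = build_ball_stencil(setA.grid, w, eps)
    dil = StencilDilator(stencil)
    return LiftedBinarySet(setA.grid, dil.binary(setA.mask))


def morph_convolve(f1: LiftedField, f2: LiftedField) -> LiftedField:
    """Morphological (min-plus) convolution (f1 [] f2)(g) = min_h f1(h^-1 g) + f2(h).

    ``f1`` is a kernel sampled at group offsets, centered at node
    (Nx//2, Ny//2, 0); it is evaluated at the exact group offset h^-1 g by
    nearest-node lookup (off-grid spatial offsets count as +inf).  Exhaustive
    O(N^2) reference implementation for small grids; the production path for
    dilations is :func:`dilate`.
    """
    if f1.grid != f2.grid:
        raise ValueError("morph_convolve requires both fields on the same grid")
    grid = f1.grid
    ci, cj = grid.Nx // 2, grid.Ny // 2
    nodes = np.argwhere(np.ones(grid.shape, dtype=bool))
    xs = nodes[:, 0] * grid.dx
    ys = nodes[:, 1] * grid.dy
    ths = nodes[:, 2] * grid.dtheta
    cos_h, sin_h = np.cos(ths), np.sin(ths)
    f2_flat = f2.values[nodes[:, 0], nodes[:, 1], nodes[:, 2]]
    out = np.empty(grid.shape)
    for g in nodes:
        gx, gy, gth = g[0] * grid.dx, g[1] * grid.dy, g[2] * grid.dtheta
        ex, ey = gx - xs, gy - ys
        rx = cos_h * ex + sin_h * ey
        ry = -sin_h * ex + cos_h * ey
        ang = wrap_pi(gth - ths)
        ii = np.rint(rx / grid.dx).astype(int) + ci
        jj = np.rint(ry / grid.dy).astype(int) + cj
        kk = np.rint(np.mod(ang, 2 * math.pi) / grid.dtheta).astype(int) % grid.No
        ok = (ii >= 0) & (ii < grid.Nx) & (jj >= 0) & (jj < grid.Ny)
        vals = np.full(len(nodes), math.inf)
        vals[ok] = f1.values[ii[ok], jj[ok], kk[ok]] + f2_flat[ok]
        out[g[0], g[1], g[2]] = vals.min()
    return LiftedField(grid, out)


def kernel_1d_semigroup_check(t: float, s: float, alpha: float,
                              n: int = 4001, domain: float = 3.0,
                              x_max: float = 2.0) -> float:
    """Numerically verify kappa_t [] kappa_s = kappa_{t+s} on a 1D axis.

    Samples the 1D kernels kappa_t^alpha(x) = (t/beta)(|x|/t)^beta on
    [-domain, domain], forms the discrete inf-convolution, and returns the
    maximum absolute deviation from kappa_{t+s}^alpha on |x| <= x_max (the
    inner window avoids boundary effects).  The deviation shrinks under grid
    refinement.
    """
    if t <= 0 or s <= 0:
        raise ValueError("t and s must be > 0")
    if alpha <= 1:
        raise ValueError("alpha must be > 1 for the finite-kernel check")
    beta = alpha / (alpha - 1.0)

    def kappa(x, tt):
        return (tt / beta) * (np.abs(x) / tt) ** beta

    x = np.linspace(-domain, domain, n)
    kt = kappa(x, t)
    ks = kappa(x, s)
    # (kt [] ks)(x_i) = min_j kt(x_i - x_j) + ks(x_j)
    diff = x[:, None] - x[None, :]
    conv = np.min(kappa(diff, t) + ks[None, :], axis=1)
    target = kappa(x, t + s)
    inner = np.abs(x) <= x_max
    return float(np.max(np.abs(conv[inner] - target[inner])))
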
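"""Orientation scores: lifting 2D images to SE(2) with cake wavelets.

The orientation score of an image f is

    (W_phi f)(x, theta) = int phi(R_theta^-1 (y - x)) f(y) dy,

a cross-correlation with rotated copies of an anisotropic wavelet phi.  Cake
wavelets tile the Fourier plane with angular wedges (one per sampled
orientation), so that crossing line structures separate into different
orientation layers while the stack as a whole preserves the image content
on a calibrated frequency annulus.

Construction (Fourier domain, per orientation theta_k):
  * angular amplitude: square root of a B-spline partition of unity in the
    frequency angle, one wedge per theta_k, centered at theta_k + pi/2 (a
    spatial line along theta_k has its frequency content perpendicular to
    it), so the squared amplitudes of the wedges sum to 1 at every angle;
  * radial envelope: flat low-pass exp(-(rho/rho_c)^(2q)) that is ~1 on the
    working annulus and vanishes at the Nyquist rate, so the lift neither
    amplifies nor discards energy there;
  * the DC bin is shared equally over the orientations;
  * the spatial filter is sqrt(2) times the real part of the inverse
    transform (the sqrt(2) compensates the energy split between the wedge
    at theta_k and its antipodal twin introduced by taking the real part).

Conventions: 2D arrays are indexed (i, j) with i the x-index; theta is
measured from the +x axis toward +y; lifted arrays have axis order
(x, y, theta).  Lifting uses periodic (frequency-domain) boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .fields import LabelField, LiftedField
from .se2 import LiftedGrid, wrap_pi


def _bspline_profile(u: np.ndarray, order: int) -> np.ndarray:
    """Centered cardinal B-spline of the given order evaluated at u.

    Integer translates of this function form a partition of unity.
    """
    half = (order + 1) / 2.0
    knots = np.arange(-half, half + 1)
    b = BSpline.basis_element(knots, extrapolate=False)
    out = b(np.asarray(u, dtype=float))
    return np.nan_to_num(out, nan=0.0)


def angular_profiles(No: int, phi: np.ndarray, order: int = 3) -> np.ndarray:
    """B-spline angular wedges B((phi - theta_k - pi/2)/s_theta), k = 0..No-1.

    Returns an (No, ...) stack that sums to 1 at every frequency angle.
    """
    s_theta = 2.0 * math.pi / No
    out = np.empty((No,) + np.shape(phi))
    for k in range(No):
        d = wrap_pi(phi - k * s_theta - math.pi / 2.0) / s_theta
        # periodic copies matter only for very small No (spline support 4)
        prof = _bspline_profile(d, order)
        if No <= 2 * (order + 1):
            prof = prof + _bspline_profile(d - No, order) \
                + _bspline_profile(d + No, order)
        out[k] = prof
    return out


@dataclass
class WaveletStack:
    """No real spatial cake-wavelet filters of odd side length ``size``.

    The stored spatial filters are the exact inverse transform of the
    designed transfer functions on their own size x size grid; lifting
    re-evaluates the same analytic transfer on the image-sized frequency
    grid (equivalent to correlating with the untruncated filters).
    """

    filters: np.ndarray  # (No, size, size)
    spline_order: int
    radial_cutoff: float  # fraction of the Nyquist rate
    radial_power: int

    @property
    def No(self) -> int:
        return self.filters.shape[0]

    @property
    def size(self) -> int:
        return self.filters.shape[1]


def make_cake_wavelets(No: int, size: int = 49, spline_order: int = 3,
                       radial_cutoff: float = 0.9, radial_power: int = 16
                       ) -> WaveletStack:
    """Build the cake-wavelet stack (see module docstring for the recipe).

    ``radial_cutoff`` is the low-pass cutoff as a fraction of the Nyquist
    rate; ``radial_power`` q sets its steepness exp(-(rho/rho_c)^(2q)).
    """
    if No < 4:
        raise ValueError("No must be >= 4")
    if size % 2 == 0:
        raise ValueError("size must be odd")
    # the radial transition occupies ~rho_c/(2q) in frequency; the filter
    # needs ~1/(2 pi * width) pixels around its center to hold it
    width = radial_cutoff * 0.5 / (2.0 * radial_power)
    if size < 1.0 / (2.0 * math.pi * width) * 2:
        raise ValueError(f"size {size} too small to hold the radial envelope; "
                         f"need at least {int(2 / (2 * math.pi * width)) + 1}")
    transfer = _design_transfer(No, (size, size), spline_order, radial_cutoff,
                                radial_power)
    filters = np.empty((No, size, size))
    for k in range(No):
        spatial = math.sqrt(2.0) * np.real(np.fft.ifft2(transfer[k]))
        filters[k] = np.fft.fftshift(spatial)
    return WaveletStack(filters=filters, spline_order=spline_order,
                        radial_cutoff=radial_cutoff, radial_power=radial_power)


def _design_transfer(No: int, shape: tuple, spline_order: int,
                     radial_cutoff: float, radial_power: int) -> np.ndarray:
    """Complex one-sided wedge transfers sampled on an fft-ordered grid."""
    fx = np.fft.fftfreq(shape[0])
    fy = np.fft.fftfreq(shape[1])
    FX, FY = np.meshgrid(fx, fy, indexing="ij")
    rho = np.hypot(FX, FY)
    phi = np.arctan2(FY, FX)
    rho_c = radial_cutoff * 0.5  # Nyquist rate is 0.5 cycles/pixel
    radial = np.exp(-(rho / rho_c) ** (2 * radial_power))
    ang = angular_profiles(No, phi, spline_order)
    out = np.empty((No,) + shape, dtype=complex)
    for k in range(No):
        t = np.sqrt(ang[k]) * radial
        t[0, 0] = 1.0 / No  # DC shared equally
        out[k] = t
    return out


def fourier_transfer(stack: WaveletStack, shape: tuple) -> np.ndarray:
    """Transfer functions of the real filters on an image-sized frequency
    grid, stacked as (No, Nx, Ny) in fft order.

    Re-evaluates the analytic design at the requested shape; the real part
    taken in the spatial domain corresponds to hermitian symmetrization of
    the one-sided wedge (with the sqrt(2) energy compensation).
    """
    one_sided = _design_transfer(stack.No, tuple(shape), stack.spline_order,
                                 stack.radial_cutoff, stack.radial_power)
    out = np.empty_like(one_sided)
    for k in range(stack.No):
        t = one_sided[k]
        flipped = np.conj(t[tuple(np.ix_(*[(-np.arange(n)) % n
                                           for n in t.shape]))])
        out[k] = (t + flipped) / math.sqrt(2.0)
    return out


def lift(image: np.ndarray, wavelets: WaveletStack) -> LiftedField:
    """Orientation score of a 2D image: per-layer correlation with the
    rotated wavelet, evaluated by frequency-domain products (periodic
    boundary).  Linear in the image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    Nx, Ny = img.shape
    transfer = fourier_transfer(wavelets, (Nx, Ny))
    fhat = np.fft.fft2(img)
    values = np.empty((Nx, Ny, wavelets.No))
    for k in range(wavelets.No):
        values[:, :, k] = np.real(np.fft.ifft2(fhat * np.conj(transfer[k])))
    grid = LiftedGrid(Nx=Nx, Ny=Ny, No=wavelets.No)
    return LiftedField(grid, values)


def project_max_labels(labels: LabelField) -> np.ndarray:
    """Project a lifted label field to 2D: per pixel the maximum label over
    all orientations (0 = background)."""
    return np.asarray(labels.labels.max(axis=2))
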
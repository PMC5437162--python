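"""Piecewise constriction profile and exact-quadrature energies.

The shape family used throughout the analytic tiers is a surface of
revolution made of three pieces along the symmetry axis x (origin at the
mid-plane):

* a cosine neck on ``|x| <= L_m``::

      R(x) = R_m - u(x),   u(x) = (R_m/2) * s * (1 + cos(pi x / L_m)),

  which runs from the constriction radius ``R_c = (1-s) R_m`` at x = 0 to
  R_m at ``x = +-L_m``;

* two spheroidal polar caps with equatorial semi-axis R_m and polar
  semi-axis L_p, centered at ``x = +-L_m``.

All quantities here are exact quadratures of this profile (no series
truncation): the mean-curvature bending energy

    E_m = pi * kappa * int K_m(x) dx,
    K_m = [1 + R_x^2 - R_xx R - R C0 (1+R_x^2)^(3/2)]^2 / (R (1+R_x^2)^(5/2)),

the area ``A = 2 pi int R sqrt(1+R_x^2) dx`` and the enclosed volume
``V = pi int R^2 dx``.  Cap integrals are evaluated in the polar-angle
parameterization (x = L_m + L_p cos(theta), R = R_m sin(theta)) where the
pole singularity of R_x cancels analytically; the neck is integrated in x.

Reduced units: R_m = 1, kappa = 1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .core_model import DimensionlessState

__all__ = [
    "VesicleProfile",
    "ShapeObservables",
    "build_profile",
    "bending_energy",
    "area_volume",
    "total_energy",
    "profile_table",
    "profile_obj_mesh",
]

_QUAD_OPTS = dict(limit=200, epsabs=1e-12, epsrel=1e-10)


@dataclass(frozen=True)
class VesicleProfile:
    """Piecewise axisymmetric profile at constriction stage ``s``.

    ``L_m`` is the half-length of the cosine neck and ``L_p`` the polar
    distance of the spheroidal caps, both in R_m units;
    ``epsilon = L_p - 1`` is the cap deformation (oblate < 0 < prolate).
    """

    s: float
    L_m: float
    L_p: float

    @property
    def epsilon(self) -> float:
        return self.L_p - 1.0

    @property
    def half_length(self) -> float:
        """Half the axial extent, L_m + L_p."""
        return self.L_m + self.L_p

    # -- piecewise evaluators (vectorized in x) ---------------------------

    def R(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        out = np.empty_like(ax)
        neck = ax <= self.L_m
        out[neck] = 1.0 - 0.5 * self.s * (1.0 + np.cos(np.pi * x[neck] / self.L_m)) if self.L_m > 0 else 1.0
        w = np.clip((ax[~neck] - self.L_m) / self.L_p, 0.0, 1.0)
        out[~neck] = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
        return out

    def R_x(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        out = np.empty_like(ax)
        neck = ax <= self.L_m
        if self.L_m > 0:
            out[neck] = 0.5 * self.s * (np.pi / self.L_m) * np.sin(np.pi * x[neck] / self.L_m)
        else:
            out[neck] = 0.0
        w = (ax[~neck] - self.L_m) / self.L_p
        root = np.sqrt(np.clip(1.0 - w**2, 1e-300, None))
        out[~neck] = -np.sign(x[~neck]) * w / (self.L_p * root)
        return out

    def R_xx(self, x):
        x = np.asarray(x, dtype=float)
        ax = np.abs(x)
        out = np.empty_like(ax)
        neck = ax <= self.L_m
        if self.L_m > 0:
            out[neck] = 0.5 * self.s * (np.pi / self.L_m) ** 2 * np.cos(np.pi * x[neck] / self.L_m)
        else:
            out[neck] = 0.0
        w = (ax[~neck] - self.L_m) / self.L_p
        root = np.clip(1.0 - w**2, 1e-300, None)
        out[~neck] = -1.0 / (self.L_p**2 * root**1.5)
        return out


@dataclass(frozen=True)
class ShapeObservables:
    """Energies (kappa units), area (R_m^2) and volume (R_m^3) of a shape."""

    E_bend: float
    E_tension: float
    E_pressure: float
    A: float
    V: float
    E_bend_caps: float = math.nan
    E_bend_neck: float = math.nan
    A_caps: float = math.nan
    V_caps: float = math.nan

    @property
    def E_total(self) -> float:
        return self.E_bend + self.E_tension + self.E_pressure


def build_profile(s: float, L_m: float, L_p: float) -> VesicleProfile:
    """Validate and build a :class:`VesicleProfile`.

    ``L_m = 0`` is allowed only for the unconstricted stage s = 0 (the
    profile is then the bare spheroid); a constricted stage with a
    zero-length neck is degenerate and rejected.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    if L_p <= 0.0:
        raise ValueError("polar distance L_p must be positive")
    if L_m < 0.0:
        raise ValueError("neck half-length L_m must be non-negative")
    if L_m == 0.0 and s > 0.0:
        raise ValueError("degenerate neck: L_m = 0 requires s = 0")
    return VesicleProfile(s=s, L_m=L_m, L_p=L_p)


# -- kernels ---------------------------------------------------------------

def _neck_kernel(x, s, L_m, c0r):
    u = 0.5 * s * (1.0 + np.cos(np.pi * x / L_m))
    ux = -0.5 * s * (np.pi / L_m) * np.sin(np.pi * x / L_m)
    uxx = -0.5 * s * (np.pi / L_m) ** 2 * np.cos(np.pi * x / L_m)
    R, Rx, Rxx = 1.0 - u, -ux, -uxx
    op = 1.0 + Rx * Rx
    N = 1.0 + Rx * Rx - Rxx * R - R * c0r * op**1.5
    return N * N / (R * op**2.5)


def _cap_kernel(theta, L_p, c0r):
    """Bending kernel of one cap in theta, including the |dx| factor.

    x = L_m + L_p cos(theta), R = sin(theta), so R_x = -cot(theta)/L_p and
    R_xx = -1/(L_p^2 sin^3 theta); the 1/R pole of the kernel cancels
    against the sin(theta) of |dx| = L_p sin(theta) dtheta.
    """
    st, ct = np.sin(theta), np.cos(theta)
    Rx2 = (ct / (L_p * st)) ** 2
    op = 1.0 + Rx2
    # -R_xx * R = + sin(theta) / (L_p^2 sin^3 theta) = 1/(L_p^2 sin^2 theta)
    N = op + 1.0 / (L_p**2 * st * st) - st * c0r * op**1.5
    return N * N / (st * op**2.5) * (L_p * st)


def bending_energy(profile: VesicleProfile, c0r: float = 0.0) -> float:
    """Mean-curvature bending energy of the full shape, in kappa units."""
    e_caps, e_neck = _bending_parts(profile, c0r)
    return e_caps + e_neck


def _bending_parts(profile: VesicleProfile, c0r: float) -> tuple[float, float]:
    cap, cap_err = quad(_cap_kernel, 0.0, 0.5 * np.pi,
                        args=(profile.L_p, c0r), **_QUAD_OPTS)
    e_caps = 2.0 * np.pi * cap          # pi * (2 caps)
    e_neck = 0.0
    if profile.L_m > 0.0 and profile.s > 0.0:
        neck, neck_err = quad(_neck_kernel, 0.0, profile.L_m,
                              args=(profile.s, profile.L_m, c0r), **_QUAD_OPTS)
        e_neck = 2.0 * np.pi * neck     # pi * (both halves)
        _check_quad(neck, neck_err, "neck bending")
    _check_quad(cap, cap_err, "cap bending")
    return e_caps, e_neck


def _check_quad(value: float, err: float, what: str) -> None:
    if not np.isfinite(value) or err > 1e-6 * max(1.0, abs(value)):
        raise ArithmeticError(f"quadrature did not converge on the {what} segment "
                              f"(value={value!r}, err={err!r})")


def area_volume(profile: VesicleProfile) -> tuple[float, float]:
    """Total membrane area (R_m^2) and enclosed volume (R_m^3)."""
    (A_caps, V_caps), (A_neck, V_neck) = _area_volume_parts(profile)
    return A_caps + A_neck, V_caps + V_neck


def _area_volume_parts(profile: VesicleProfile):
    L_p = profile.L_p

    def cap_area(theta):
        st, ct = np.sin(theta), np.cos(theta)
        return st * np.sqrt(L_p**2 * st * st + ct * ct)

    a_cap, ea = quad(cap_area, 0.0, 0.5 * np.pi, **_QUAD_OPTS)
    _check_quad(a_cap, ea, "cap area")
    A_caps = 2.0 * (2.0 * np.pi * a_cap)
    V_caps = 4.0 * np.pi / 3.0 * L_p          # exact spheroid volume

    A_neck = V_neck = 0.0
    if profile.L_m > 0.0 and profile.s > 0.0:
        s, L_m = profile.s, profile.L_m

        def neck_area(x):
            u = 0.5 * s * (1.0 + np.cos(np.pi * x / L_m))
            ux = -0.5 * s * (np.pi / L_m) * np.sin(np.pi * x / L_m)
            return (1.0 - u) * np.sqrt(1.0 + ux * ux)

        def neck_vol(x):
            u = 0.5 * s * (1.0 + np.cos(np.pi * x / L_m))
            return (1.0 - u) ** 2

        an, ea = quad(neck_area, 0.0, L_m, **_QUAD_OPTS)
        vn, ev = quad(neck_vol, 0.0, L_m, **_QUAD_OPTS)
        _check_quad(an, ea, "neck area")
        _check_quad(vn, ev, "neck volume")
        A_neck = 2.0 * (2.0 * np.pi * an)
        V_neck = 2.0 * (np.pi * vn)
    return (A_caps, V_caps), (A_neck, V_neck)


def total_energy(profile: VesicleProfile, state: DimensionlessState) -> ShapeObservables:
    """Exact-quadrature total energy E_T = E_bend + sig*A + prs*V.

    The Gaussian term is omitted: it is topological and constant along the
    constriction pathway (it only enters at fission, see
    :func:`vesipinch.observables.fission_energy_step`).
    """
    e_caps, e_neck = _bending_parts(profile, state.c0r)
    (A_caps, V_caps), (A_neck, V_neck) = _area_volume_parts(profile)
    A = A_caps + A_neck
    V = V_caps + V_neck
    return ShapeObservables(
        E_bend=e_caps + e_neck,
        E_tension=state.sig * A,
        E_pressure=state.prs * V,
        A=A,
        V=V,
        E_bend_caps=e_caps,
        E_bend_neck=e_neck,
        A_caps=A_caps,
        V_caps=V_caps,
    )


# -- export ----------------------------------------------------------------

def profile_table(profile: VesicleProfile, n: int = 401) -> np.ndarray:
    """(n, 2) array of (x, R) samples over the full support."""
    L = profile.half_length
    x = np.linspace(-L, L, n)
    return np.column_stack([x, profile.R(x)])


def profile_obj_mesh(profile: VesicleProfile, n_axial: int = 120,
                     n_azimuthal: int = 48) -> str:
    """Wavefront OBJ text for the surface of revolution."""
    L = profile.half_length
    x = np.linspace(-L, L, n_axial)
    r = profile.R(x)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuthal, endpoint=False)
    buf = io.StringIO()
    buf.write("# vesipinch revolution mesh\n")
    for xi, ri in zip(x, r):
        for p in phi:
            buf.write(f"v {xi:.6f} {ri * np.cos(p):.6f} {ri * np.sin(p):.6f}\n")
    for i in range(n_axial - 1):
        for j in range(n_azimuthal):
            a = i * n_azimuthal + j + 1
            b = i * n_azimuthal + (j + 1) % n_azimuthal + 1
            c = a + n_azimuthal
            d = b + n_azimuthal
            buf.write(f"f {a} {b} {d} {c}\n")
    return buf.getvalue()
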
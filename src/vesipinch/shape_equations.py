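"""Exact tier: Euler-Lagrange shape equations for the constricted vesicle.

The stationarity conditions of the functional E_T = E_b + Sigma*A +
DeltaP*V for axisymmetric shapes are written in the standard
arclength/tangent-angle form.  With psi the tangent angle (dr/dl = cos
psi, dx/dl = sin psi), h = c_meridional + c_parallel - C0 the spontaneous-
curvature-shifted mean curvature sum, and gam the Lagrange multiplier
conjugate to r (scaled by 2 pi kappa), the first-order system in reduced
units (kappa = 1, lengths in R_m) reads::

    psi' = h - sin(psi)/r + c0
    h'   = (p r cos psi)/2 + gam sin(psi)/r
    r'   = cos psi
    x'   = sin psi
    gam' = h^2/2 - h sin(psi)/r + sigma + p r sin(psi)

with the conserved Hamiltonian (identically zero for free total length)

    H = r h psi' - r h^2/2 - sigma r - (p/2) r^2 sin psi + gam cos psi.

Boundary-value problem (half shape, mirrored at the mid-plane):

* pole (l=0): r = 0 with psi ~ a*l (regularized at a small offset), no
  point force (gam = 0, from H = 0);
* maximum-radius ring: psi = pi/2 and r = R_m; the fixed polar radius is
  maintained by a ring line tension, which appears as a jump ``dgam`` in
  the multiplier (the shape variables and h stay continuous);
* equator (mid-plane): psi = pi/2 (profile minimum, mirror-smooth) and
  r = R_c; the constriction ring tension enforcing r = R_c does the work
  measured by the constriction force F = dE_T/ds / R_m.

The two segments (pole -> ring, ring -> equator) are solved together with
scipy's collocation BVP solver, with the pole curvature a, the segment
lengths L1, L2 and the ring jump dgam as unknown parameters.  Observables
are quadratures over the dense solution, doubled for the mirror half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, solve_bvp

from .core_model import DimensionlessState, Regime
from .perturbation import cap_solution, neck_series_eval

__all__ = ["ExactShape", "ShapeEquationError", "SolverOptions",
           "solve_shape", "solve_unconstricted", "sweep_constriction",
           "two_sphere_energy"]

_POLE_OFFSET = 1e-4


class ShapeEquationError(RuntimeError):
    """Shooting/collocation failure; carries the best residual found."""


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-8
    max_nodes: int = 40000
    n_init: int = 120
    n_quad: int = 4001


@dataclass(frozen=True)
class ExactShape:
    """Converged Euler-Lagrange solution at one constriction stage."""

    state: DimensionlessState
    R_c: float
    # dense samples over the half shape (pole to equator), mirror implied
    ell: np.ndarray = field(repr=False)
    psi: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    h: np.ndarray = field(repr=False)
    gam: np.ndarray = field(repr=False)
    # unknowns of the BVP
    pole_curvature: float
    L1: float
    L2: float
    ring_jump: float
    # observables of the full (mirrored) shape, reduced units
    E_bend: float
    A: float
    V: float
    # cap-zone (pole -> maximum-radius ring) observables
    L_p: float
    A_caps: float
    V_caps: float
    max_r: float
    rms_residual: float
    _bvp_guess: tuple = field(repr=False, compare=False, default=None)

    @property
    def s(self) -> float:
        return 1.0 - self.R_c

    @property
    def E_total(self) -> float:
        return self.E_bend + self.state.sig * self.A + self.state.prs * self.V

    @property
    def c_meridional(self) -> np.ndarray:
        return self.h - np.sin(self.psi) / np.maximum(self.r, 1e-12) + self.state.c0r


def _rhs_factory(c0: float, sg: float, pr: float):
    def f(_t, y):
        psi, h, r, x, gam = y
        sp_, cp_ = np.sin(psi), np.cos(psi)
        spr = sp_ / r
        return np.vstack([
            h - spr + c0,
            pr * r * cp_ / 2.0 + gam * sp_ / r,
            cp_,
            sp_,
            h * h / 2.0 - h * spr + sg + pr * r * sp_,
        ])
    return f


def _default_guess(R_c: float, state: DimensionlessState, n: int):
    """Warm start from the perturbative ansatz (sphere cap + cosine neck)."""
    s = 1.0 - R_c
    c0 = state.c0r
    t = np.linspace(0.0, 1.0, n)

    # segment 1: spherical cap of radius ~1 (exact at Lambda=1)
    try:
        a0 = 1.0 + cap_solution(state).epsilon   # pole curvature ~ L_p
    except ValueError:
        a0 = 1.0
    psi1 = 0.5 * np.pi * np.maximum(t, _POLE_OFFSET)
    r1 = np.sin(psi1)
    r1[0] = _POLE_OFFSET
    x1 = 1.0 - np.cos(psi1)
    h1 = np.full(n, 2.0 - c0)
    g1 = np.zeros(n)
    L1g = 0.5 * np.pi

    # segment 2: cosine neck from the ring (r=1) to the mid-plane (r=R_c)
    lam = max(state.Lambda, 1e-3)
    Lmg = max(0.5 * np.pi * (6.0 / lam) ** 0.25 * math.sqrt(max(s, 1e-3)), 0.05)
    xx = np.linspace(-Lmg, 0.0, n)
    u = 0.5 * s * (1.0 + np.cos(np.pi * xx / Lmg))
    Rp = 1.0 - u
    Rx = -0.5 * s * (np.pi / Lmg) * np.sin(np.pi * xx / Lmg)
    Rxx = -0.5 * s * (np.pi / Lmg) ** 2 * np.cos(np.pi * xx / Lmg)
    psi2 = 0.5 * np.pi - np.arctan(Rx)
    cm = -Rxx / (1.0 + Rx**2) ** 1.5
    cpar = 1.0 / (Rp * np.sqrt(1.0 + Rx**2))
    h2 = cm + cpar - c0
    dl = np.sqrt(1.0 + Rx**2)
    ell2 = np.concatenate([[0.0], np.cumsum(0.5 * (dl[1:] + dl[:-1]) * np.diff(xx))])
    L2g = max(ell2[-1], 1e-2)
    tt = ell2 / ell2[-1] if ell2[-1] > 0 else np.linspace(0, 1, n)

    Y = np.zeros((10, n))
    Y[0], Y[1], Y[2], Y[3], Y[4] = psi1, h1, r1, x1, g1
    seg2 = [psi2, h2, Rp, x1[-1] + (xx + Lmg), np.zeros(n)]
    for i, arr in enumerate(seg2):
        Y[5 + i] = np.interp(t, tt, arr)
    p0 = np.array([a0, L1g, L2g, 0.0])
    return t, Y, p0


def solve_shape(R_c: float, state: DimensionlessState,
                opts: SolverOptions = SolverOptions(),
                guess=None) -> ExactShape:
    """Solve the shape equations at constriction radius R_c (R_m units).

    ``guess`` may be a previous :class:`ExactShape` (continuation) or a
    raw ``(t, Y, p)`` triple.  Raises :class:`ShapeEquationError` on
    non-convergence (used by the phase maps to mark impossible cells).
    """
    if not 0.0 < R_c <= 1.0:
        raise ValueError("R_c must lie in (0, R_m]")
    c0, sg, pr = state.c0r, state.sig, state.prs
    f = _rhs_factory(c0, sg, pr)

    def odes(t, Y, p):
        _a, L1, L2, _dg = p
        return np.vstack([L1 * f(t, Y[:5]), L2 * f(t, Y[5:])])

    delta = _POLE_OFFSET

    def bcs(Ya, Yb, p):
        a, _L1, _L2, dg = p
        h0 = 2.0 * a - c0
        g1 = h0 * h0 / 2.0 - a * h0 + sg
        return np.array([
            Ya[2] - delta,              # pole: r = delta
            Ya[0] - a * delta,          # pole: psi = a delta
            Ya[1] - h0,                 # pole: regular curvature
            Ya[3],                      # pole: x = 0
            Ya[4] - g1 * delta,         # pole: no point force (H=0)
            Yb[0] - 0.5 * np.pi,        # ring: psi = pi/2
            Yb[2] - 1.0,                # ring: r = R_m
            Ya[5] - 0.5 * np.pi,        # matching: psi
            Ya[6] - Yb[1],              # matching: h
            Ya[7] - 1.0,                # matching: r
            Ya[8] - Yb[3],              # matching: x
            Ya[9] - (Yb[4] + dg),       # ring line tension: gam jump
            Yb[5] - 0.5 * np.pi,        # equator: psi = pi/2 (mirror)
            Yb[7] - R_c,                # equator: r = R_c
        ])

    if guess is None:
        start = _default_guess(R_c, state, opts.n_init)
    elif isinstance(guess, ExactShape):
        start = guess._bvp_guess
    else:
        start = guess

    sol = solve_bvp(odes, bcs, *start[:2], p=start[2],
                    tol=opts.tol, max_nodes=opts.max_nodes, verbose=0)
    if sol.status != 0:
        # one retry from the cold ansatz start
        if guess is not None:
            cold = _default_guess(R_c, state, opts.n_init)
            sol = solve_bvp(odes, bcs, *cold[:2], p=cold[2],
                            tol=opts.tol, max_nodes=opts.max_nodes, verbose=0)
        if sol.status != 0:
            raise ShapeEquationError(
                f"shape equations did not converge at R_c={R_c:.4g} "
                f"(Lambda={state.Lambda:.4g}): {sol.message}")

    return _package(sol, R_c, state, opts)


def _package(sol, R_c, state, opts) -> ExactShape:
    a, L1, L2, dg = (float(v) for v in sol.p)
    t = np.linspace(0.0, 1.0, opts.n_quad)
    Y = sol.sol(t)
    seg = []
    E = A = V = 0.0
    for k, L in ((0, L1), (5, L2)):
        psi, h, r, x, gam = Y[k:k + 5]
        seg.append((psi, h, r, x, gam))
        E += simpson(h * h * r, x=t) * L
        A += simpson(r, x=t) * L
        V += simpson(r * r * np.sin(psi), x=t) * L

    # cap-zone observables from segment 1 alone
    psi1, h1, r1, x1, _ = seg[0]
    A_caps = 2.0 * (2.0 * np.pi * simpson(r1, x=t) * L1)
    V_caps = 2.0 * (np.pi * simpson(r1 * r1 * np.sin(psi1), x=t) * L1)
    L_p = float(x1[-1])

    ell = np.concatenate([t * L1, L1 + t * L2])
    stacked = [np.concatenate([seg[0][i], seg[1][i]]) for i in range(5)]
    psi_all, h_all, r_all, x_all, gam_all = stacked

    return ExactShape(
        state=state, R_c=R_c,
        ell=ell, psi=psi_all, r=r_all, x=x_all, h=h_all, gam=gam_all,
        pole_curvature=a, L1=L1, L2=L2, ring_jump=dg,
        E_bend=2.0 * np.pi * E, A=4.0 * np.pi * A, V=2.0 * np.pi * V,
        L_p=L_p, A_caps=A_caps, V_caps=V_caps,
        max_r=float(r_all.max()),
        rms_residual=float(np.sqrt(np.mean(sol.rms_residuals**2))),
        _bvp_guess=(sol.x, sol.y, sol.p),
    )


def solve_unconstricted(state: DimensionlessState,
                        opts: SolverOptions = SolverOptions()) -> ExactShape:
    """Exact s = 0 solution: the closed equilibrium shape at fixed R_m.

    A single segment from the pole to the mid-plane, where the maximum
    radius r = R_m and the mirror condition psi = pi/2 hold (the ring that
    maintains R_m sits at the equator itself).  At Lambda = 1 this is the
    unit sphere.
    """
    c0, sg, pr = state.c0r, state.sig, state.prs
    f = _rhs_factory(c0, sg, pr)

    def odes(t, Y, p):
        _a, L1 = p
        return L1 * f(t, Y)

    delta = _POLE_OFFSET

    def bcs(Ya, Yb, p):
        a, _L1 = p
        h0 = 2.0 * a - c0
        g1 = h0 * h0 / 2.0 - a * h0 + sg
        return np.array([
            Ya[2] - delta,
            Ya[0] - a * delta,
            Ya[1] - h0,
            Ya[3],
            Ya[4] - g1 * delta,
            Yb[0] - 0.5 * np.pi,
            Yb[2] - 1.0,
        ])

    n = opts.n_init
    t = np.linspace(0.0, 1.0, n)
    try:
        a0 = 1.0 + cap_solution(state).epsilon
    except ValueError:
        a0 = 1.0
    psi = 0.5 * np.pi * np.maximum(t, delta)
    Y = np.vstack([psi, np.full(n, 2.0 * a0 - c0), np.sin(psi),
                   1.0 - np.cos(psi), np.zeros(n)])
    Y[2, 0] = delta
    sol = solve_bvp(odes, bcs, t, Y, p=np.array([a0, 0.5 * np.pi]),
                    tol=opts.tol, max_nodes=opts.max_nodes, verbose=0)
    if sol.status != 0:
        raise ShapeEquationError(
            f"unconstricted shape did not converge (Lambda={state.Lambda:.4g}): "
            f"{sol.message}")

    a, L1 = (float(v) for v in sol.p)
    tq = np.linspace(0.0, 1.0, opts.n_quad)
    psi, h, r, x, gam = sol.sol(tq)
    E = simpson(h * h * r, x=tq) * L1
    A = simpson(r, x=tq) * L1
    V = simpson(r * r * np.sin(psi), x=tq) * L1
    return ExactShape(
        state=state, R_c=1.0,
        ell=tq * L1, psi=psi, r=r, x=x, h=h, gam=gam,
        pole_curvature=a, L1=L1, L2=0.0, ring_jump=0.0,
        E_bend=2.0 * np.pi * E, A=4.0 * np.pi * A, V=2.0 * np.pi * V,
        L_p=float(x[-1]), A_caps=4.0 * np.pi * A, V_caps=2.0 * np.pi * V,
        max_r=float(r.max()),
        rms_residual=float(np.sqrt(np.mean(sol.rms_residuals**2))),
        _bvp_guess=(sol.x, sol.y, sol.p),
    )


def sweep_constriction(state: DimensionlessState, s_grid,
                       opts: SolverOptions = SolverOptions()):
    """Solve along an increasing s grid with continuation.

    Returns ``(shapes, failures)`` where ``shapes`` maps s to
    :class:`ExactShape` and ``failures`` lists the s values where the
    continuation failed (flagged, never interpolated).  A failure at the
    first grid point aborts with diagnostics.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing")
    if s_grid[-1] > 0.98:
        raise ValueError("s_max must not exceed 0.98; treat full fission "
                         "analytically (two spheres)")

    shapes: dict[float, ExactShape] = {}
    failures: list[float] = []
    prev = None
    for i, s in enumerate(s_grid):
        try:
            if s == 0.0:
                shapes[0.0] = solve_unconstricted(state, opts=opts)
                continue
            shp = solve_shape(1.0 - s, state, opts=opts, guess=prev)
        except ShapeEquationError as err:
            if i == 0:
                raise ShapeEquationError(
                    f"continuation failed at the first grid point s={s}: {err}"
                ) from err
            failures.append(float(s))
            continue
        shapes[float(s)] = shp
        prev = shp
    return shapes, failures


def two_sphere_energy(state: DimensionlessState) -> dict:
    """Analytic fully-fissioned limit: two spheres of radius R_m.

    Reduced observables of the final state (before the Gaussian fission
    step): E_bend doubles the single-sphere value, area and volume double.
    """
    c0 = state.c0r
    e_sph = 8.0 * np.pi * (1.0 - c0 / 2.0) ** 2
    A = 2.0 * 4.0 * np.pi
    V = 2.0 * 4.0 * np.pi / 3.0
    return {
        "E_bend": 2.0 * e_sph,
        "A": A,
        "V": V,
        "E_total": 2.0 * e_sph + state.sig * A + state.prs * V,
    }
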
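"""Perturbative closed-form series for the constriction pathway.

This module re-derives, symbolically and at run time, the power series in
the constriction parameter ``s`` that describe the minimum-energy cosine
neck, and the quadratic cap expansion in the spheroid deformation
``epsilon = L_p/R_m - 1``:

* the reduced energy density (bending kernel + tension + pressure terms)
  is expanded in the small neck deformation ``u(x) = (s/2)(1 + cos(pi x /
  L_m))`` to fourth or sixth order of perturbation;
* each monomial ``u^a u_x^b u_xx^c`` is integrated in closed form over the
  neck, giving the zone energy E(s, L_m) as a Laurent polynomial in L_m;
* stationarity of E with respect to L_m is imposed order by order on the
  ansatz ``L_m = l1 sqrt(s) (1 + l2 s + l3 s^2)``, and the optimal L_m is
  back-substituted to produce series of the form
  ``sqrt(s) (c0 + c1 s + c2 s^2)`` for the energy increase, the area and
  volume of the zone, and (term-by-term derivative) the constriction force
  ``F = dE/ds`` in kappa/R_m units;
* the cap energy is expanded in ``epsilon`` in the polar-angle
  parameterization, giving the optimal cap shape
  ``epsilon = -5 (Lambda - 1) / (Gamma + 29)``.

At fourth order every coefficient is a function of (Lambda, Gamma) alone;
at sixth order an explicit dependence on C0*R_m remains (it cancels only
through fourth order), so the coefficient functions take (Lambda, Gamma,
c0r).  The derivation is cached per order within a process.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import sympy as sp

from .core_model import DimensionlessState, Regime

__all__ = [
    "SeriesCoefficients",
    "CapSolution",
    "NeckSeries",
    "derive_series",
    "cap_solution",
    "neck_series_eval",
    "series_to_json",
    "EPS_MAX",
]

#: |epsilon| beyond which cap results are flagged as outside the
#: perturbative window (the most deformed published shapes use 0.5).
EPS_MAX = 0.5

_LAM = sp.Symbol("Lambda", positive=True)
_GAM, _C = sp.symbols("Gamma c")


# --------------------------------------------------------------------------
# symbolic derivation
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _trig_moment(a: int, b: int, c: int):
    """int_{-pi}^{pi} (1+cos y)^a sin^b y cos^c y dy, exact."""
    y = sp.Symbol("y")
    return sp.integrate((1 + sp.cos(y)) ** a * sp.sin(y) ** b * sp.cos(y) ** c,
                        (y, -sp.pi, sp.pi))


def _integrate_neck(expr, u, ux, uxx, t, s, Lm):
    """Integrate a polynomial in (u, u_x, u_xx) over the neck [-L_m, L_m]."""
    total = 0
    for monom, coef in sp.Poly(expr, u, ux, uxx, t).terms():
        a, b, c, _ = monom
        piece = ((s / 2) ** (a + b + c) * (sp.pi / Lm) ** (b + 2 * c)
                 * (-1) ** (b + c) * (Lm / sp.pi) * _trig_moment(a, b, c))
        total += coef * piece
    return sp.expand(total)


def _subs_groups(expr, c0_sym):
    """Rewrite (sigma, p) in terms of (Lambda, Gamma, c0r)."""
    sg, pr = sp.symbols("sigma_t p_t")
    return expr.subs({
        pr: _LAM - _GAM + 2 * (1 - c0_sym),
        sg: (_GAM + 1 - (2 - c0_sym) ** 2) / 2,
    })


#: lamq stands for Lambda^(1/4); using it keeps every intermediate a
#: rational function (fractional powers of Lambda make sympy's series and
#: simplification machinery intractably slow at sixth order).
_LAMQ = sp.Symbol("lamq", positive=True)


def _laurent_terms(poly, s, Lm, max_neg: int = 8):
    """[(coef, a, e)] for poly = sum coef * s^a * Lm^e (e may be negative)."""
    shifted = sp.expand(poly * Lm**max_neg)
    out = []
    for monom, coef in sp.Poly(shifted, s, Lm).terms():
        a, epow = monom
        out.append((coef, a, epow - max_neg))
    return out


def _qseries_from_terms(terms, l_syms, n_corr, l1_expr, deriv=False):
    """Assemble the sqrt(s)-expansion of sum coef*s^a*Lm^e at the ansatz
    L_m = l1 q (1 + l2 q^2 + l3 q^4), q = sqrt(s), truncated at q^(1+2n).

    Returns dict {power of q: expression}.  With deriv=True the terms are
    first differentiated in L_m (coef*e*s^a*Lm^(e-1)).
    """
    l2 = l_syms[1] if n_corr >= 1 else sp.S.Zero
    l3 = l_syms[2] if n_corr >= 2 else sp.S.Zero
    qmax = 2 * n_corr + (0 if deriv else 1)
    acc: dict[int, sp.Expr] = {}
    for coef, a, e in terms:
        if deriv:
            if e == 0:
                continue
            coef = coef * e
            e = e - 1
        base = 2 * a + e          # q-power of the leading factor
        if base > qmax:
            continue
        # (1 + l2 q^2 + l3 q^4)^e up to q^4
        binom = [sp.S.One, sp.Integer(e) * l2,
                 sp.Integer(e) * l3 + sp.Rational(e * (e - 1), 2) * l2**2]
        pref = coef * l1_expr**e
        for k, bk in enumerate(binom):
            p = base + 2 * k
            if p <= qmax and bk != 0:
                acc[p] = acc.get(p, sp.S.Zero) + pref * bk
    return acc


@lru_cache(maxsize=None)
def _derive_neck_symbolic(order: int):
    """Symbolic neck series; returns dict of sympy expressions.

    Keys: 'l' -> [l1, l2, (l3)], 'E','A','V' -> lists of coefficients of
    s^(1/2+k) for the zone energy (kappa units), area (R_m^2) and volume
    (R_m^3).  All expressions in (lamq = Lambda^(1/4), Gamma, c).
    """
    if order not in (4, 6):
        raise ValueError("perturbation order must be 4 or 6")
    n_corr = order // 2 - 1          # corrections beyond the leading term

    t, s, Lm = sp.symbols("t s L_m", positive=True)
    u, ux, uxx = sp.symbols("u u_x u_xx")
    sg, pr = sp.symbols("sigma_t p_t")
    c = _C

    R, Rx, Rxx = 1 - t * u, -t * ux, -t * uxx
    op = 1 + Rx**2
    kernel = ((1 + Rx**2 - Rxx * R - R * c * op ** sp.Rational(3, 2)) ** 2
              / (R * op ** sp.Rational(5, 2))
              + 2 * sg * R * sp.sqrt(op) + pr * R**2)
    area_density = 2 * R * sp.sqrt(op)
    vol_density = sp.expand((1 - t * u) ** 2)

    kern_ser = sp.expand(sp.series(kernel, t, 0, order + 1).removeO())
    area_ser = sp.expand(sp.series(area_density, t, 0, order + 1).removeO())

    # zone integrals as functions of (s, L_m); per pi (energy per pi*kappa)
    polys = {}
    for name, ser in (("E", kern_ser), ("A", area_ser), ("V", vol_density)):
        p = _integrate_neck(ser, u, ux, uxx, t, s, Lm).subs(t, 1)
        p = _subs_groups(p, c).subs(_LAM, _LAMQ**4)
        polys[name] = sp.expand(p)

    ls = sp.symbols("l1 l2 l3", positive=True)
    l1_expr = sp.pi * sp.Rational(3, 8) ** sp.Rational(1, 4) / _LAMQ

    terms_E = _laurent_terms(polys["E"], s, Lm)
    grad = _qseries_from_terms(terms_E, ls, n_corr, l1_expr, deriv=True)

    # The q^0 equation fixes l1 and must be free of the higher corrections
    # (their feed-down cancels identically); the q^(2k) equation is linear
    # in l_{k+1} and must not involve corrections beyond it.
    resid = sp.cancel(sp.expand(grad.get(0, sp.S.Zero)))
    if resid != 0:
        raise ArithmeticError(f"leading-order stationarity failed: residual {resid}")
    l_sol: dict = {}
    l_exprs = [l1_expr]
    for k in range(1, n_corr + 1):
        unknown = ls[k]
        eq = sp.expand(grad[2 * k].subs(l_sol))
        for higher in ls[k + 1:3]:
            feed = sp.cancel(sp.expand(sp.diff(eq, higher)))
            if feed != 0:
                raise ArithmeticError(
                    f"stationarity order {k} unexpectedly involves {higher}: {feed}")
            eq = eq.subs(higher, 0)
        sol = sp.solve(sp.Eq(eq, 0), unknown)
        if len(sol) != 1:
            raise ArithmeticError(f"stationarity order {k}: expected a unique "
                                  f"solution for {unknown}, got {sol}")
        val = sp.cancel(sp.radsimp(sol[0]))
        l_sol[unknown] = val
        l_exprs.append(val)

    def _optimal_series(poly, prefactor):
        acc = _qseries_from_terms(_laurent_terms(poly, s, Lm), ls, n_corr, l1_expr)
        for p, expr in acc.items():
            if p < 0 and sp.cancel(sp.expand(expr.subs(l_sol))) != 0:
                raise ArithmeticError(f"spurious singular term at q^{p}")
        coeffs = []
        for k in range(n_corr + 1):
            ck = acc.get(2 * k + 1, sp.S.Zero).subs(l_sol) * prefactor
            coeffs.append(sp.cancel(sp.expand(ck)))
        return coeffs

    return {
        "l": l_exprs,
        "E": _optimal_series(polys["E"], sp.pi),  # energy carries the pi kappa
        "A": _optimal_series(polys["A"], sp.pi),
        "V": _optimal_series(polys["V"], sp.pi),
    }


def _cap_taylor_integral(dens, eps, th, k: int):
    """k-th Taylor coefficient in eps of int_0^(pi/2) dens dtheta.

    The theta integral is taken in w = sin(theta) (on the polar cap the
    cosine is non-negative, so odd cosine powers map to sqrt(1-w^2)),
    which turns the trig/radical integrand into an algebraic one.
    """
    w = sp.Symbol("w", positive=True)
    g = sp.diff(dens, eps, k).subs(eps, 0) / sp.factorial(k)
    g = sp.expand(sp.radsimp(g.subs(sp.sin(th), w).subs(sp.cos(th) ** 2, 1 - w**2)))
    if g.has(th):
        g = sp.expand(g.subs(sp.cos(th), sp.sqrt(1 - w**2)))
    g = sp.cancel(g)
    return sp.integrate(g / sp.sqrt(1 - w**2), (w, 0, 1))


@lru_cache(maxsize=None)
def _derive_cap_symbolic():
    """Quadratic cap expansion: E(eps), A(eps), exact V(eps).

    Returns dict with 'E_sph', 'E1', 'E2' (energy coefficients, kappa
    units), 'A1', 'A2' (area/4pi coefficients) and 'eps_opt'.
    """
    eps, th = sp.symbols("varepsilon theta")
    sg, pr = sp.symbols("sigma_t p_t")
    c = _C
    Lp = 1 + eps

    st, ct = sp.sin(th), sp.cos(th)
    op = 1 + (ct / (Lp * st)) ** 2
    # total-energy kernel in theta including |dx| = Lp sin(theta) dtheta;
    # -R_xx*R = 1/(L_p^2 sin^2 theta)
    N = op + 1 / (Lp**2 * st**2) - st * c * op ** sp.Rational(3, 2)
    dens = (N**2 / (st * op ** sp.Rational(5, 2))
            + 2 * sg * st * sp.sqrt(op) + pr * st**2) * (Lp * st)

    coeffs = {}
    for k in range(3):
        integ = _cap_taylor_integral(dens, eps, th, k)
        # both caps, times pi kappa
        coeffs[k] = sp.simplify(_subs_groups(2 * sp.pi * integ, c))

    area_dens = st * sp.sqrt(Lp**2 * st**2 + ct**2)
    acoef = {}
    for k in range(3):
        integ = _cap_taylor_integral(area_dens, eps, th, k)
        acoef[k] = sp.simplify(2 * (2 * sp.pi * integ) / (4 * sp.pi))  # per A_sph

    e1, e2 = coeffs[1], coeffs[2]
    eps_opt = sp.cancel(-e1 / (2 * e2))
    return {
        "E_sph": coeffs[0], "E1": e1, "E2": e2,
        "A1": acoef[1], "A2": acoef[2],
        "eps_opt": eps_opt,
    }


# --------------------------------------------------------------------------
# evaluators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesCoefficients:
    """Per-quantity series coefficients in s, as functions of state.

    ``coeffs`` are sympy expressions in (Lambda, Gamma, c0r); ``powers``
    are the corresponding powers of s.  ``funcs`` are the lambdified
    numeric versions.
    """

    quantity: str
    order: int
    powers: tuple
    coeffs: tuple
    funcs: tuple = field(repr=False, compare=False, default=())

    def evaluate(self, s, Lambda, Gamma, c0r=0.0):
        # funcs take lamq = Lambda^(1/4) (rationalized internal variable)
        lamq = float(Lambda) ** 0.25
        s = np.asarray(s, dtype=float)
        total = np.zeros_like(s)
        for p, f in zip(self.powers, self.funcs):
            total = total + f(lamq, Gamma, c0r) * s**float(p)
        return total


@dataclass(frozen=True)
class NeckSeries:
    """Bundle of the derived neck series at a given order."""

    order: int
    L_m: SeriesCoefficients
    dE: SeriesCoefficients
    dA: SeriesCoefficients
    dV: SeriesCoefficients
    F: SeriesCoefficients

    def as_dict(self):
        return {q.quantity: q for q in (self.L_m, self.dE, self.dA, self.dV, self.F)}


def _make_sc(quantity, order, powers, exprs):
    funcs = tuple(sp.lambdify((_LAMQ, _GAM, _C), e, modules="numpy") for e in exprs)
    display = tuple(e.subs(_LAMQ, _LAM ** sp.Rational(1, 4)) for e in exprs)
    return SeriesCoefficients(quantity=quantity, order=order,
                              powers=tuple(powers), coeffs=display,
                              funcs=funcs)


@lru_cache(maxsize=None)
def derive_series(order: int = 6) -> NeckSeries:
    """Derive (and cache) the neck series at perturbation order 4 or 6."""
    sym = _derive_neck_symbolic(order)
    n = len(sym["E"])
    half = sp.Rational(1, 2)
    powers = [half + k for k in range(n)]

    # L_m series: l1 sqrt(s) (1 + l2 s + ...) -> coefficients of s^(1/2+k)
    l = sym["l"]
    lm_coeffs = [l[0]] + [sp.cancel(l[0] * l[k]) for k in range(1, n)]

    # force: term-by-term derivative of the energy series
    f_coeffs = [sp.cancel((half + k) * sym["E"][k]) for k in range(n)]
    f_powers = [half + k - 1 for k in range(n)]

    return NeckSeries(
        order=order,
        L_m=_make_sc("L_m", order, powers, lm_coeffs),
        dE=_make_sc("dE", order, powers, sym["E"]),
        dA=_make_sc("dA", order, powers, sym["A"]),
        dV=_make_sc("dV", order, powers, sym["V"]),
        F=_make_sc("F", order, f_powers, f_coeffs),
    )


@lru_cache(maxsize=None)
def _cap_funcs():
    sym = _derive_cap_symbolic()
    return {k: sp.lambdify((_LAM, _GAM, _C), v, modules="numpy")
            for k, v in sym.items()}


@dataclass(frozen=True)
class CapSolution:
    """Optimal polar-cap shape and its observables (reduced units)."""

    epsilon: float
    L_p: float
    E_caps: float
    A_caps: float
    V_caps: float
    E_sph: float
    flagged: bool      # |epsilon| beyond the perturbative window


def cap_solution(state: DimensionlessState, eps_max: float = EPS_MAX) -> CapSolution:
    """Minimize the quadratic cap energy: epsilon = -5(Lambda-1)/(Gamma+29).

    Returns the optimal deformation, the polar distance L_p = 1 + epsilon,
    and the cap energy/area/volume series evaluated at the optimum.  A
    CAP_SINGULAR state is refused; |epsilon| >= eps_max is flagged, not
    refused.
    """
    state.require_valid()
    f = _cap_funcs()
    lam, gam, c = state.Lambda, state.Gamma, state.c0r
    eps = float(f["eps_opt"](lam, gam, c))
    e_sph = float(f["E_sph"](lam, gam, c))
    e_caps = e_sph + float(f["E1"](lam, gam, c)) * eps + float(f["E2"](lam, gam, c)) * eps**2
    a_caps = 4.0 * math.pi * (1.0 + float(f["A1"](lam, gam, c)) * eps
                              + float(f["A2"](lam, gam, c)) * eps**2)
    v_caps = 4.0 * math.pi / 3.0 * (1.0 + eps)     # exact spheroid volume
    return CapSolution(
        epsilon=eps, L_p=1.0 + eps,
        E_caps=e_caps, A_caps=a_caps, V_caps=v_caps, E_sph=e_sph,
        flagged=abs(eps) >= eps_max,
    )


def neck_series_eval(s, state: DimensionlessState, order: int = 6):
    """Evaluate the neck series at stage(s) s.

    Returns a dict with arrays ``L_m``, ``dE``, ``dA``, ``dV``, ``F``
    (reduced units).  Refuses IMPOSSIBLE and CAP_SINGULAR states.
    """
    state.require_valid()
    ns = derive_series(order)
    lam, gam, c = state.Lambda, state.Gamma, state.c0r
    return {name: sc.evaluate(s, lam, gam, c)
            for name, sc in ns.as_dict().items()}


def series_to_json(order: int, state: DimensionlessState | None = None) -> str:
    """Render the series coefficients (and optional numeric values) as JSON."""
    ns = derive_series(order)
    out = {"order": order, "quantities": {}}
    for name, sc in ns.as_dict().items():
        entry = {
            "powers_of_s": [str(p) for p in sc.powers],
            "coefficients": [sp.sstr(e) for e in sc.coeffs],
        }
        if state is not None:
            entry["numeric"] = [float(f(state.Lambda, state.Gamma, state.c0r))
                                for f in sc.funcs]
        out["quantities"][name] = entry
    return json.dumps(out, indent=2)
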
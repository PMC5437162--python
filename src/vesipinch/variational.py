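"""Mid-fidelity tier: numerical minimization over the ansatz lengths.

At each constriction stage the exact-quadrature total energy of the
cosine-neck / spheroidal-cap family (no series truncation) is minimized
over the two free lengths (L_m, L_p).  The perturbative series provides
the warm start; a Nelder-Mead search is followed by a gradient polish.
Because the family contains the series-optimal profile, the variational
energy always lower-bounds the series-evaluated ansatz energy, and is
itself an upper bound on the exact Euler-Lagrange minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core_model import DimensionlessState
from .perturbation import cap_solution, neck_series_eval
from .shape_ansatz import ShapeObservables, build_profile, total_energy

__all__ = ["VariationalResult", "minimize_ansatz"]

#: Search bounds in R_m units; hits are reported as suspicious.
L_M_BOUNDS = (1e-4, 5.0)
L_P_BOUNDS = (0.2, 5.0)


@dataclass(frozen=True)
class VariationalResult:
    s: float
    L_m: float
    L_p: float
    observables: ShapeObservables
    converged: bool
    grad_norm: float
    at_bounds: bool


def _initial_guess(s: float, state: DimensionlessState) -> tuple[float, float]:
    try:
        lp = 1.0 + cap_solution(state).epsilon
    except ValueError:
        lp = 1.0
    lp = min(max(lp, L_P_BOUNDS[0]), L_P_BOUNDS[1])
    if s == 0.0:
        return 0.0, lp
    try:
        lm = float(neck_series_eval(s, state, order=6)["L_m"])
    except Exception:
        lm = (math.pi / 2.0) * (6.0 / state.Lambda) ** 0.25 * math.sqrt(s)
    lm = min(max(lm, L_M_BOUNDS[0]), L_M_BOUNDS[1])
    return lm, lp


def minimize_ansatz(s: float, state: DimensionlessState,
                    grad_tol: float = 1e-8, max_restarts: int = 3) -> VariationalResult:
    """Minimize the exact-quadrature total energy over (L_m, L_p) at stage s.

    For s = 0 the neck is absent and the minimization runs over L_p alone.
    Raises RuntimeError (carrying the best iterate) if the optimizer fails
    to converge after bounded restarts.
    """
    state.require_valid()
    if not 0.0 <= s < 1.0:
        raise ValueError("s must lie in [0, 1) for the ansatz family")

    lm0, lp0 = _initial_guess(s, state)

    if s == 0.0:
        def fun1(v):
            return total_energy(build_profile(0.0, 0.0, float(v[0])), state).E_total
        res = minimize(fun1, [lp0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
        lp = float(res.x[0])
        h = 1e-6
        grad = abs(fun1([lp + h]) - fun1([lp - h])) / (2 * h)
        obs = total_energy(build_profile(0.0, 0.0, lp), state)
        return VariationalResult(s=0.0, L_m=0.0, L_p=lp, observables=obs,
                                 converged=bool(res.success and grad < 1e-5),
                                 grad_norm=grad, at_bounds=_near_bounds(0.0, lp))

    def fun(v):
        lm, lp = v
        if not (L_M_BOUNDS[0] <= lm <= L_M_BOUNDS[1] and L_P_BOUNDS[0] <= lp <= L_P_BOUNDS[1]):
            return 1e6 + 10.0 * (abs(lm) + abs(lp))
        return total_energy(build_profile(s, lm, lp), state).E_total

    best = None
    x0 = np.array([lm0, lp0])
    for attempt in range(max_restarts):
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
        # gradient polish
        pol = minimize(fun, best.x, method="Powell",
                       options={"xtol": 1e-10, "ftol": 1e-13, "maxiter": 200})
        if pol.fun <= best.fun:
            best = pol
        g = _fd_grad(fun, best.x)
        if np.linalg.norm(g) < max(grad_tol, 1e-7 * abs(best.fun)) or np.linalg.norm(g) < 1e-6:
            break
        x0 = best.x * (1.0 + 0.02 * (attempt + 1))
    else:
        g = _fd_grad(fun, best.x)
        if np.linalg.norm(g) > 1e-3:
            raise RuntimeError(
                f"variational minimization did not converge at s={s}: "
                f"best (L_m, L_p)={tuple(best.x)}, |grad|={np.linalg.norm(g):.3g}")

    lm, lp = float(best.x[0]), float(best.x[1])
    obs = total_energy(build_profile(s, lm, lp), state)
    g = _fd_grad(fun, best.x)
    return VariationalResult(s=s, L_m=lm, L_p=lp, observables=obs,
                             converged=True, grad_norm=float(np.linalg.norm(g)),
                             at_bounds=_near_bounds(lm, lp))


def _fd_grad(fun, x, h: float = 1e-6):
    g = np.zeros_like(np.asarray(x, dtype=float))
    for i in range(len(x)):
        e = np.zeros_like(g)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def _near_bounds(lm: float, lp: float, rel: float = 1e-3) -> bool:
    hit = lp < L_P_BOUNDS[0] * (1 + rel) or lp > L_P_BOUNDS[1] * (1 - rel)
    if lm > 0:
        hit = hit or lm > L_M_BOUNDS[1] * (1 - rel)
    return hit
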
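"""Derived quantities: forces, rescaled pathways, and force phase diagrams.

The constriction force is defined energetically,

    F_c = -dE_T/dR_c = (1/R_m) dE_T/ds,

reported in reduced units F~ = F_c R_m / kappa.  Negative values mean the
vesicle constricts spontaneously.  Phase diagrams classify F~ on a
(tension, pressure) grid against the reference force F_c0 (the force of
the bare vesicle, C0 = Sigma = DeltaP = 0, at the same stage) and against
zero; cells with Lambda <= 0 (or exact-solver failure) are impossible.

Constant-area and constant-volume protocols are obtained from the
fixed-R_m pathway by the similarity rescaling lam(s) with
lam = sqrt(A(0)/A(s)) or (V(0)/V(s))^(1/3); lengths scale by lam, the
constitutive parameters by 1/lam^k, and the total energy is invariant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import DimensionlessState, Regime, state_from_groups
from .perturbation import cap_solution, neck_series_eval
from .shape_equations import (ExactShape, ShapeEquationError, SolverOptions,
                              solve_shape, sweep_constriction, two_sphere_energy)
from .variational import minimize_ansatz

__all__ = [
    "ForceCurve", "PhaseMap", "PhaseCategory",
    "force_from_energy", "sustained_force_max", "rescale_constraint", "phase_map",
    "fission_energy_step", "series_sweep", "variational_sweep",
    "exact_sweep", "two_sphere_limit",
]

SWEEP_COLUMNS = ["s", "L_m", "L_p", "E_total", "E_bend", "A", "V", "F",
                 "tier", "flag"]


# --------------------------------------------------------------------------
# force
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceCurve:
    """Reduced constriction force F~ = F_c R_m / kappa on an s grid."""

    s: np.ndarray
    F: np.ndarray
    tier: str

    def at(self, s_eval: float) -> float:
        return float(np.interp(s_eval, self.s, self.F))


def force_from_energy(s_grid, E_grid, tier: str = "numeric") -> ForceCurve:
    """F~(s) = dE/ds by centered differences on a (non-uniform) grid.

    One-sided differences are used at the ends.  E must be in kappa units
    and the grid strictly increasing with at least 3 points.
    """
    s = np.asarray(s_grid, dtype=float)
    E = np.asarray(E_grid, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 grid points to differentiate")
    if np.any(np.diff(s) <= 0):
        raise ValueError("s grid must be strictly increasing")
    return ForceCurve(s=s, F=np.gradient(E, s), tier=tier)


def sustained_force_max(curve: ForceCurve) -> float:
    """Largest force the constriction machinery must sustain.

    The force curve has two branches: a kick-off transient diverging as
    s^(-1/2) at onset (needed only to break the initial symmetry) and a
    rising branch toward the pre-fission curvature barrier.  The sustained
    requirement is the maximum over the rising branch, from the force
    minimum onward.
    """
    i_min = int(np.nanargmin(curve.F))
    return float(np.nanmax(curve.F[i_min:]))


def fission_energy_step(kappa: float, kappa_G: float) -> float:
    """Gaussian-curvature energy step of the final fission, 4*pi*kappa_G.

    By Gauss-Bonnet the Gaussian term is constant while the topology is
    spherical; splitting into two spheres adds exactly 4*pi*kappa_G (about
    -100 k_BT for kappa_G = -0.8 * 10 k_BT).  This step applies only at
    the topology change and is never accumulated along the pathway.
    ``kappa`` fixes the unit system and does not enter the value.
    """
    del kappa
    return 4.0 * math.pi * kappa_G


# --------------------------------------------------------------------------
# sweeps (common table schema)
# --------------------------------------------------------------------------

def _frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    return df.sort_values("s", ignore_index=True)


def series_sweep(state: DimensionlessState, s_grid, order: int = 6) -> pd.DataFrame:
    """Closed-form pathway table from the perturbative series."""
    state.require_valid()
    cap = cap_solution(state)
    s = np.asarray(s_grid, dtype=float)
    pos = s > 0
    neck = neck_series_eval(s[pos], state, order=order)
    E0 = cap.E_caps
    rows = []
    flag = "eps_window_exceeded" if cap.flagged else ""
    for i, si in enumerate(s):
        if si == 0.0:
            rows.append([0.0, 0.0, cap.L_p, E0, math.nan, cap.A_caps,
                         cap.V_caps, math.nan, "series", flag])
        else:
            j = int(np.count_nonzero(pos[:i]))
            rows.append([si, float(neck["L_m"][j]), cap.L_p,
                         E0 + float(neck["dE"][j]), math.nan,
                         cap.A_caps + float(neck["dA"][j]),
                         cap.V_caps + float(neck["dV"][j]),
                         float(neck["F"][j]), "series", flag])
    return _frame(rows)


def variational_sweep(state: DimensionlessState, s_grid) -> pd.DataFrame:
    """Pathway table from exact-quadrature minimization over (L_m, L_p)."""
    rows = []
    for si in np.asarray(s_grid, dtype=float):
        res = minimize_ansatz(float(si), state)
        obs = res.observables
        rows.append([si, res.L_m, res.L_p, obs.E_total, obs.E_bend,
                     obs.A, obs.V, math.nan, "variational",
                     "at_bounds" if res.at_bounds else ""])
    df = _frame(rows)
    if len(df) >= 3:
        df["F"] = force_from_energy(df["s"], df["E_total"]).F
    return df


def exact_sweep(state: DimensionlessState, s_grid,
                opts: SolverOptions = SolverOptions()) -> pd.DataFrame:
    """Pathway table from the Euler-Lagrange solver (continuation in s)."""
    shapes, failures = sweep_constriction(state, np.asarray(s_grid, float), opts)
    rows = []
    for s, shp in shapes.items():
        rows.append([s, shp.L2, shp.L_p, shp.E_total, shp.E_bend,
                     shp.A, shp.V, math.nan, "exact", ""])
    for s in failures:
        rows.append([s, math.nan, math.nan, math.nan, math.nan,
                     math.nan, math.nan, math.nan, "exact", "failed"])
    df = _frame(rows)
    ok = df["flag"] != "failed"
    if ok.sum() >= 3:
        fc = force_from_energy(df.loc[ok, "s"], df.loc[ok, "E_total"])
        df.loc[ok, "F"] = fc.F
    return df


def two_sphere_limit(state: DimensionlessState) -> pd.DataFrame:
    """Analytic fully-fissioned endpoint (s = 1) in the sweep schema."""
    ts = two_sphere_energy(state)
    return _frame([[1.0, 0.0, math.nan, ts["E_total"], ts["E_bend"],
                    ts["A"], ts["V"], math.nan, "analytic", "two_sphere"]])


# --------------------------------------------------------------------------
# constant-area / constant-volume rescaling
# --------------------------------------------------------------------------

def rescale_constraint(trajectory: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Rescale a fixed-R_m pathway to constant area or constant volume.

    ``mode`` is ``"constant_area"`` (lam = sqrt(A(0)/A(s))) or
    ``"constant_volume"`` (lam = (V(0)/V(s))^(1/3)).  Lengths scale by
    lam, areas by lam^2, volumes by lam^3; the total energy is invariant
    and the constitutive parameters transform as C0 -> C0/lam,
    Sigma -> Sigma/lam^2, DeltaP -> DeltaP/lam^3 (columns ``c0_scale``
    etc. give the 1/lam^k factors).
    """
    if mode not in ("constant_area", "constant_volume"):
        raise ValueError("mode must be 'constant_area' or 'constant_volume'")
    df = trajectory.sort_values("s", ignore_index=True).copy()
    A = df["A"].to_numpy(dtype=float)
    V = df["V"].to_numpy(dtype=float)
    if np.any(~np.isfinite(A)) or np.any(A <= 0) or np.any(V <= 0):
        raise ValueError("trajectory must have positive finite areas and volumes")
    if mode == "constant_area":
        lam = np.sqrt(A[0] / A)
    else:
        lam = (V[0] / V) ** (1.0 / 3.0)
    out = df.copy()
    out["mode"] = mode
    out["lam"] = lam
    out["A_rescaled"] = A * lam**2
    out["V_rescaled"] = V * lam**3
    for col in ("L_m", "L_p"):
        if col in out:
            out[col + "_rescaled"] = out[col] * lam
    out["R_m_rescaled"] = lam
    out["c0_scale"] = 1.0 / lam
    out["sigma_scale"] = 1.0 / lam**2
    out["pressure_scale"] = 1.0 / lam**3
    return out


# --------------------------------------------------------------------------
# phase diagrams
# --------------------------------------------------------------------------

class PhaseCategory(enum.IntEnum):
    IMPOSSIBLE = 0
    ABOVE_REF = 1      # F~ > F_c0: harder than the bare vesicle
    BELOW_REF = 2      # 0 <= F~ <= F_c0: easier than the bare vesicle
    SPONTANEOUS = 3    # F~ < 0


@dataclass(frozen=True)
class PhaseMap:
    """Force classification on a (pressure, tension) grid at fixed c0r."""

    c0r: float
    sig_grid: np.ndarray
    prs_grid: np.ndarray
    s_eval: float
    tier: str
    F: np.ndarray = field(repr=False)          # (n_sig, n_prs), NaN = impossible
    category: np.ndarray = field(repr=False)   # PhaseCategory codes
    F_ref: float

    def fraction(self, cat: PhaseCategory) -> float:
        return float(np.mean(self.category == int(cat)))

    def legend(self) -> dict:
        return {int(c): c.name for c in PhaseCategory}


def _series_force_with_validity(state: DimensionlessState, s_eval: float,
                                order: int) -> tuple[float, bool]:
    """Series force and an optimal-truncation validity check.

    An asymptotic series is meaningless where its last retained term
    exceeds the leading one; near the Lambda -> 0 boundary the s-corrections
    blow up and the truncated force is unusable (the exact solver fails in
    the same band).
    """
    from .perturbation import derive_series
    ns = derive_series(order)
    lamq = state.Lambda ** 0.25
    terms = [f(lamq, state.Gamma, state.c0r) * s_eval ** float(p)
             for p, f in zip(ns.F.powers, ns.F.funcs)]
    F = float(sum(terms))
    valid = abs(terms[-1]) < abs(terms[0])
    return F, valid


def _force_at(state: DimensionlessState, s_eval: float, tier: str,
              order: int, ds: float, exact_opts: SolverOptions) -> float:
    if tier == "series":
        return float(neck_series_eval(s_eval, state, order=order)["F"])
    if tier == "variational":
        em = minimize_ansatz(s_eval - ds, state).observables.E_total
        ep = minimize_ansatz(s_eval + ds, state).observables.E_total
        return (ep - em) / (2.0 * ds)
    if tier == "exact":
        lo = solve_shape(1.0 - (s_eval - ds), state, opts=exact_opts)
        hi = solve_shape(1.0 - (s_eval + ds), state, opts=exact_opts, guess=lo)
        return (hi.E_total - lo.E_total) / (2.0 * ds)
    raise ValueError(f"unknown tier {tier!r}")


def phase_map(c0r: float, sig_grid, prs_grid, s_eval: float = 0.2,
              tier: str = "series", order: int = 6, ds: float = 0.01,
              exact_opts: SolverOptions = SolverOptions()) -> PhaseMap:
    """Classify the constriction force over a (sig, prs) grid.

    The reference force F_c0 is computed once for the bare vesicle
    (c0r = sig = prs = 0) at the same stage and tier.  Any cell with
    Lambda <= 0, a singular cap series, or a solver failure is marked
    IMPOSSIBLE.
    """
    sig_grid = np.asarray(sig_grid, dtype=float)
    prs_grid = np.asarray(prs_grid, dtype=float)
    ref_state = state_from_groups(0.0, 0.0, 0.0)
    F_ref = _force_at(ref_state, s_eval, tier, order, ds, exact_opts)

    F = np.full((sig_grid.size, prs_grid.size), np.nan)
    cat = np.full(F.shape, int(PhaseCategory.IMPOSSIBLE), dtype=int)
    for i, sg in enumerate(sig_grid):
        for j, pr in enumerate(prs_grid):
            st = state_from_groups(c0r, sg, pr)
            if st.regime is not Regime.VALID:
                continue
            try:
                if tier == "series":
                    f, ok = _series_force_with_validity(st, s_eval, order)
                    if not ok:
                        continue       # divergent truncation: no usable result
                else:
                    f = _force_at(st, s_eval, tier, order, ds, exact_opts)
            except (ShapeEquationError, RuntimeError, ValueError, TypeError):
                continue
            F[i, j] = f
            if f < 0.0:
                cat[i, j] = int(PhaseCategory.SPONTANEOUS)
            elif f > F_ref:
                cat[i, j] = int(PhaseCategory.ABOVE_REF)
            else:
                cat[i, j] = int(PhaseCategory.BELOW_REF)
    return PhaseMap(c0r=c0r, sig_grid=sig_grid, prs_grid=prs_grid,
                    s_eval=s_eval, tier=tier, F=F, category=cat, F_ref=F_ref)
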
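"""Constitutive parameters, nondimensionalization and regime classification.

The mechanics of a symmetrically constricted vesicle is governed by the
Helfrich energy functional

    E_T = E_b + Sigma*A + DeltaP*V,
    E_b = (kappa/2) int (C1 + C2 - C0)^2 dA  +  kappa_G int C1*C2 dA,

whose minimum-energy shapes, at fixed polar radius R_m, depend on the
constitutive parameters only through the dilatation-invariant products
``C0*R_m``, ``Sigma*R_m^2/kappa`` and ``DeltaP*R_m^3/kappa``.  Two linear
combinations of these control the whole perturbative solution:

    Lambda = (1 - C0*R_m)^2 + 2*sig + prs        (neck stiffness group)
    Gamma  = (2 - C0*R_m)^2 + 2*sig - 1          (cap stiffness group)

with ``sig = Sigma*R_m^2/kappa`` and ``prs = DeltaP*R_m^3/kappa``.  They act
as generalized Young-Laplace conditions: ``Lambda = 1`` corresponds to
spherical polar caps, ``Lambda <= 0`` makes constriction impossible (the
perturbative series turn imaginary and the boundary-value solver finds no
shape), and ``Gamma = -29`` is a removable singularity of the cap series.

Everything downstream of this module works in reduced units: lengths in
R_m, energies in kappa, tensions in kappa/R_m^2, pressures in kappa/R_m^3,
forces in kappa/R_m.  Physical units enter only through
:func:`to_physical` / :func:`from_physical`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "BOLTZMANN_J_PER_K",
    "Regime",
    "MembraneParams",
    "DimensionlessState",
    "ConstrictionStage",
    "make_dimensionless",
    "classify_regime",
    "state_from_groups",
    "to_physical",
    "from_physical",
    "params_from_config",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Default tolerance below which Lambda is treated as non-positive.
LAMBDA_TOL = 1e-9
#: Default half-width of the excluded band around Gamma = -29.
GAMMA_SINGULAR_TOL = 1e-6


class Regime(enum.Enum):
    """Validity regime of the perturbative solution."""

    VALID = "valid"
    IMPOSSIBLE = "impossible"          # Lambda <= 0: no constricted shape
    CAP_SINGULAR = "cap_singular"      # Gamma = -29: cap series diverges


@dataclass(frozen=True)
class MembraneParams:
    """Physical constitutive parameters of the vesicle membrane.

    Parameters
    ----------
    kappa_kT : float
        Bending modulus in units of k_B*T at `temperature`.  Fluid lipid
        bilayers have kappa ~ 10-20 k_B*T; the default 10 corresponds to a
        flexible membrane.
    kappa_G_ratio : float
        Gaussian modulus as a fraction of kappa.  The Gaussian term is
        topological (Gauss-Bonnet) and only enters at fission; experiments
        on bilayer phase behavior suggest kappa_G ~ -0.8 kappa.
    C0 : float
        Spontaneous curvature, 1/m.  Positive C0 prefers convex membranes.
    Sigma : float
        Surface tension, N/m (energy per area added to the functional).
    DeltaP : float
        Pressure difference, Pa; enters the energy as ``+DeltaP*V``.
    R_m : float
        Polar (maximum) radius, m; held constant along constriction.
    temperature : float
        Absolute temperature in K, used only to convert kappa to joules.
    """

    kappa_kT: float = 10.0
    kappa_G_ratio: float = -0.8
    C0: float = 0.0
    Sigma: float = 0.0
    DeltaP: float = 0.0
    R_m: float = 1.0e-6
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.kappa_kT <= 0:
            raise ValueError("bending modulus kappa must be positive")
        if self.R_m <= 0:
            raise ValueError("polar radius R_m must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kappa_J(self) -> float:
        """Bending modulus in joules."""
        return self.kappa_kT * BOLTZMANN_J_PER_K * self.temperature

    @property
    def kappa_G_J(self) -> float:
        """Gaussian modulus in joules."""
        return self.kappa_G_ratio * self.kappa_J


@dataclass(frozen=True)
class DimensionlessState:
    """Reduced parameter groups and the shape functionals Lambda, Gamma."""

    c0r: float
    sig: float
    prs: float
    Lambda: float = field(init=False)
    Gamma: float = field(init=False)
    regime: Regime = field(init=False)

    def __post_init__(self) -> None:
        lam = (1.0 - self.c0r) ** 2 + 2.0 * self.sig + self.prs
        gam = (2.0 - self.c0r) ** 2 + 2.0 * self.sig - 1.0
        object.__setattr__(self, "Lambda", lam)
        object.__setattr__(self, "Gamma", gam)
        object.__setattr__(self, "regime", classify_regime(lam, gam))

    def require_valid(self) -> "DimensionlessState":
        if self.regime is Regime.IMPOSSIBLE:
            raise ValueError(
                f"Lambda = {self.Lambda:.6g} <= 0: constriction impossible "
                "(perturbative series imaginary, no equilibrium shape)"
            )
        if self.regime is Regime.CAP_SINGULAR:
            raise ValueError(
                f"Gamma = {self.Gamma:.6g} ~ -29: cap series singular"
            )
        return self


@dataclass(frozen=True)
class ConstrictionStage:
    """Constriction stage s = 1 - R_c/R_m, with R_c the equator radius."""

    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("constriction parameter s must lie in [0, 1]")

    @property
    def R_c(self) -> float:
        """Constriction radius in R_m units."""
        return 1.0 - self.s


def classify_regime(
    Lambda: float,
    Gamma: float,
    lambda_tol: float = LAMBDA_TOL,
    gamma_tol: float = GAMMA_SINGULAR_TOL,
) -> Regime:
    """Classify a (Lambda, Gamma) pair.

    ``Lambda <= lambda_tol`` is IMPOSSIBLE (the series carry Lambda^(1/4)
    and the exact solver fails); ``|Gamma + 29| <= gamma_tol`` is
    CAP_SINGULAR (the optimal cap deformation diverges); anything else is
    VALID.
    """
    if Lambda <= lambda_tol:
        return Regime.IMPOSSIBLE
    if abs(Gamma + 29.0) <= gamma_tol:
        return Regime.CAP_SINGULAR
    return Regime.VALID


def make_dimensionless(params: MembraneParams) -> DimensionlessState:
    """Reduce physical parameters to the invariant groups (c0r, sig, prs)."""
    kappa = params.kappa_J
    return DimensionlessState(
        c0r=params.C0 * params.R_m,
        sig=params.Sigma * params.R_m**2 / kappa,
        prs=params.DeltaP * params.R_m**3 / kappa,
    )


def state_from_groups(c0r: float = 0.0, sig: float = 0.0, prs: float = 0.0) -> DimensionlessState:
    """Build a state directly from the reduced groups."""
    return DimensionlessState(c0r=c0r, sig=sig, prs=prs)


_PHYSICAL_SCALES = {
    # kind -> exponent n such that physical = value * kappa / R_m**n
    "tension": 2,
    "pressure": 3,
    "force": 1,
    "curvature": None,   # special-cased: C0 = c0r / R_m
    "energy": 0,
}


def to_physical(value: float, kind: str, params: MembraneParams) -> float:
    """Convert a reduced quantity to SI units.

    kind is one of ``tension`` (-> N/m), ``pressure`` (-> Pa), ``force``
    (-> N), ``curvature`` (-> 1/m) or ``energy`` (-> J).
    """
    if kind not in _PHYSICAL_SCALES:
        raise ValueError(f"unknown physical kind {kind!r}")
    if kind == "curvature":
        return value / params.R_m
    n = _PHYSICAL_SCALES[kind]
    return value * params.kappa_J / params.R_m**n


def from_physical(value: float, kind: str, params: MembraneParams) -> float:
    """Inverse of :func:`to_physical`."""
    if kind not in _PHYSICAL_SCALES:
        raise ValueError(f"unknown physical kind {kind!r}")
    if kind == "curvature":
        return value * params.R_m
    n = _PHYSICAL_SCALES[kind]
    return value * params.R_m**n / params.kappa_J


def params_from_config(cfg: dict) -> MembraneParams:
    """Build :class:`MembraneParams` from a configuration mapping.

    Recognized keys: ``kappa_kT``, ``kappa_G_ratio``, ``R_m_um``,
    ``temperature_K``, ``C0_per_um``, and per quantity either the physical
    key (``Sigma_N_per_m``, ``DeltaP_Pa``) or the reduced one
    (``sig_reduced``, ``prs_reduced``) -- mutually exclusive.
    """
    kappa_kT = float(cfg.get("kappa_kT", 10.0))
    temperature = float(cfg.get("temperature_K", 298.15))
    R_m = float(cfg.get("R_m_um", 1.0)) * 1e-6
    kappa_J = kappa_kT * BOLTZMANN_J_PER_K * temperature

    if "Sigma_N_per_m" in cfg and "sig_reduced" in cfg:
        raise ValueError("give either Sigma_N_per_m or sig_reduced, not both")
    if "DeltaP_Pa" in cfg and "prs_reduced" in cfg:
        raise ValueError("give either DeltaP_Pa or prs_reduced, not both")

    Sigma = float(cfg.get("Sigma_N_per_m", 0.0))
    if "sig_reduced" in cfg:
        Sigma = float(cfg["sig_reduced"]) * kappa_J / R_m**2
    DeltaP = float(cfg.get("DeltaP_Pa", 0.0))
    if "prs_reduced" in cfg:
        DeltaP = float(cfg["prs_reduced"]) * kappa_J / R_m**3

    return MembraneParams(
        kappa_kT=kappa_kT,
        kappa_G_ratio=float(cfg.get("kappa_G_ratio", -0.8)),
        C0=float(cfg.get("C0_per_um", 0.0)) * 1e6,
        Sigma=Sigma,
        DeltaP=DeltaP,
        R_m=R_m,
        temperature=temperature,
    )


def rescaled_params(params: MembraneParams, lam: float) -> MembraneParams:
    """Apply the scale transformation r -> lam*r to the parameter set.

    Lengths scale by lam, C0 by 1/lam, Sigma by 1/lam^2, DeltaP by 1/lam^3;
    kappa and the total energy are invariant, so the dimensionless state is
    unchanged.
    """
    if lam <= 0:
        raise ValueError("scale factor must be positive")
    return replace(
        params,
        R_m=params.R_m * lam,
        C0=params.C0 / lam,
        Sigma=params.Sigma / lam**2,
        DeltaP=params.DeltaP / lam**3,
    )
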
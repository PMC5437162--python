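# Methods

## Model and energy functional

A vesicle is modelled as a closed, axisymmetric, centrally symmetric
surface of revolution around the x-axis.  Its energy is the
spontaneous-curvature (Helfrich) bending energy plus tension and pressure
work terms,

    E_T = (κ/2) ∮ (C₁+C₂−C₀)² dA + κ_G ∮ C₁C₂ dA + Σ A + Δp V.

The functional is taken literally as written: Δp multiplies the enclosed
volume with a plus sign, so positive Δp penalizes volume.  Narrative sign
conventions for "inflated/hypertonic" are not relied on anywhere; every
classification in the package is derived from this functional.  The
Gaussian term is constant for all shapes of spherical topology
(Gauss–Bonnet) and is excluded from pathway energies; the final fission
step adds exactly ΔE_G = 4πκ_G, reported separately and never accumulated
along the pathway.

All internal computation is nondimensional — lengths in units of the polar
radius R_m, energies in κ — because the mechanics depends on the
parameters only through C₀R_m, Σ̃R_m² = ΣR_m²/κ and Δp̃R_m³ = ΔpR_m³/κ.
Physical units (SI) appear only in `to_physical` / `from_physical`, with
κ given in k_BT at a configurable temperature (default 298.15 K, default
κ = 10 k_BT, κ_G = −0.8 κ: the flexible-bilayer regime).

Two derived groups control everything:

    Λ = (1−C₀R_m)² + 2Σ̃R_m² + Δp̃R_m³,
    Γ = (2−C₀R_m)² + 2Σ̃R_m² − 1  =  Λ + 2(1−C₀R_m) − Δp̃R_m³.

Regimes: Λ ≤ 0 (tolerance 1e−9) means no constricted equilibrium exists —
the series carry Λ^(1/4) and turn imaginary, and the exact solver finds no
solution; Γ = −29 (tolerance 1e−6) is a pole of the cap series.  These
tolerances reflect the factors 1/Λ^(1/4) and 1/(Γ+29) that the series
divide by.

## Constriction protocol

Constriction is driven at the equator at fixed polar radius R_m: the stage
is s = 1 − R_c/R_m ∈ [0, 1].  Holding R_m fixed emulates cells whose wall
or cytoskeleton maintains the polar caps (rod-shaped bacteria being the
canonical case); mechanically it corresponds to an outward ring line
tension at the maximum-radius circle, and a constriction ring tension at
the equator.  Under this protocol the polar caps are stage-independent;
all energy variation comes from the neck region.  Constant-area and
constant-volume protocols are obtained afterwards by the similarity
rescaling λ(s) = √(A(0)/A(s)) or (V(0)/V(s))^(1/3) (lengths ×λ, C₀ → C₀/λ,
Σ → Σ/λ², Δp → Δp/λ³, E_T invariant).

## Analytic tier (perturbation engine)

The shape family is two spheroidal caps (equatorial semi-axis R_m, polar
semi-axis L_p = R_m(1+ε)) joined to a cosine neck
u(x) = (R_m/2)s(1+cos πx/L_m) on |x| ≤ L_m.

The engine re-derives all series symbolically at run time (sympy), caches
them per process, and lambdifies the coefficients:

* Caps: the total-energy density is Taylor-expanded to ε² in the polar
  angle parameterization and integrated in w = sin θ (which turns the
  trig/radical integrand algebraic).  This yields
  E_caps = E_sph + (4π/3)(Λ−1)ε + (2π/15)(Γ+29)ε² (κ units),
  A_caps/4πR_m² = 1 + (2/3)ε + (1/15)ε², V_caps = (4π/3)R_m³(1+ε) exactly,
  and the optimum ε = −5(Λ−1)/(Γ+29).
* Neck: the combined kernel (bending + 2Σ̃R√(1+R_x²) + Δp̃R²) is expanded
  in the deformation u to fourth or sixth order; each monomial u^a u_x^b
  u_xx^c integrates to a closed trig moment.  Internally Λ^(1/4) is a
  primitive symbol so every intermediate stays a rational function — this
  is what makes the sixth-order derivation run in seconds.  Stationarity
  in L_m is imposed order by order on L_m = l₁√s(1 + l₂s + l₃s²); the
  leading result is L_m/R_m = (π/2)(6/Λ)^(1/4)√s, confirming that the
  nascent neck is a near-cylinder (its leading area and volume increments
  are exactly those of a cylinder of radius R_m and length 2L_m).
* The force series is the term-by-term s-derivative of the energy series,
  F̃ = F_c R_m/κ = d(ΔE_T/κ)/ds, with leading behavior
  (2/3)π²6^(1/4)Λ^(3/4) s^(−1/2): a diverging "kick-off" at onset.

The derivation is the canonical source of all coefficients; the package's
tests pin the regenerated fourth-order coefficients against independent
brute-force quadrature minimization (the printed-formula fixtures carry
typographic ambiguities, and the symbolic engine arbitrates them — e.g.
the first L_m correction has denominator 576Λ).  Two facts worth noting:
at fourth order every coefficient is a function of (Λ, Γ) alone, and the
engine asserts this; at sixth order an explicit C₀R_m dependence survives
in the s^(5/2) coefficients (verified against direct quadrature), so the
coefficient functions take (Λ, Γ, C₀R_m).

Validity: the expansion assumes |ε| ≪ 1 and Λ not close to 0.  Cap
results with |ε| ≥ 0.5 are flagged (not refused): 0.5 is the most
deformed case the model is meant to describe.  For truncated series
evaluated at finite s the package applies the standard optimal-truncation
rule where a usability decision is needed (phase maps): if the last
retained term is at least as large as the leading term, the series value
is discarded.  In practice this removes only a thin band of cells hugging
the Λ = 0 boundary, where the exact solver fails as well.

## Variational tier

At each s the exact-quadrature energy of the same two-length family is
minimized over (L_m, L_p) with Nelder–Mead plus a derivative-free polish,
warm-started from the series.  Bending quadratures evaluate the caps in
the polar angle (the 1/R pole of the kernel cancels against the area
element analytically) and the neck in x, each with adaptive Gauss–Kronrod
(relative tolerance 1e−10, absolute floor 1e−12, convergence checked and
errored on, never silently accepted).  Search bounds L_m ∈ (0, 5],
L_p ∈ [0.2, 5] R_m; bound hits are reported as suspicious.  By
construction the variational energy lower-bounds any fixed-length member
of the family (in particular the series-optimal lengths) and
upper-bounds the exact solution.

## Exact tier (shape equations)

Stationarity of E_T for axisymmetric shapes gives, in arclength ℓ and
tangent angle ψ (dr/dℓ = cos ψ, dx/dℓ = sin ψ), with
h = ψ̇ + sin ψ/r − C₀ and γ the multiplier conjugate to r (scaled by
2πκ):

    ψ̇ = h − sin ψ/r + C₀
    ḣ = (Δp̃ r cos ψ)/2 + γ sin ψ/r
    γ̇ = h²/2 − h sin ψ/r + Σ̃ + Δp̃ r sin ψ

with the identically-zero Hamiltonian
H = r h ψ̇ − r h²/2 − Σ̃ r − (Δp̃/2) r² sin ψ + γ cos ψ used as an
internal consistency check (tests verify |H| < 1e−5 along solutions).

The half shape (pole to mid-plane; the other half is the mirror image) is
solved as a two-segment collocation BVP (scipy `solve_bvp`, tolerance
1e−8): segment 1 from the pole to the maximum-radius ring (ψ = π/2,
r = R_m), segment 2 from the ring to the equator (ψ = π/2, r = R_c).
Unknown parameters: the pole meridional curvature, the two segment
lengths, and a jump in γ at the ring — the ring line tension that holds
the polar radius fixed.  Pole regularity is handled by starting the
segment at a 1e−4 offset with the local series (r ≈ ℓ, ψ ≈ aℓ,
γ(0) = 0 from H = 0, i.e. no point force at the pole).  Warm starts come
from the ansatz profile; sweeps continue each solution into the next
stage.  Observables are Simpson quadratures of the dense solution (4001
points per segment; refinement tests show <1e−6 relative change on
doubling).  The cap zone of the exact solution (pole → ring) is
stage-independent to solver tolerance, consistent with the fixed-R_m
protocol.

Sweeps stop at s_max = 0.98; the fissioned endpoint is handled
analytically as two spheres of radius R_m (E_bend doubles, A and V
double), not by continuation through the singular neck.

## Forces and phase diagrams

F_c ≡ −dE_T/dR_c = (1/R_m)dE_T/ds.  Numeric tiers differentiate the
energy with centered differences on the sweep grid (one-sided at the
ends); the series tier uses the analytic term-by-term derivative (the two
agree to O(h²), which a Richardson test verifies).  The force curve has
two branches: the kick-off transient ∝ s^(−1/2) needed to break the
initial symmetry, and a rising branch toward the pre-fission curvature
barrier.  `sustained_force_max` reports the maximum over the rising
branch (from the force minimum onward) — the force the machinery must
sustain to complete division, which is the quantity bounded by ~1 pN for
a micron-sized vesicle with κ = 10 k_BT; the transient itself exceeds
that bound near onset and is reported in full in the sweep tables.

Phase maps evaluate F̃ at s = 0.2 (configurable) on a (Σ̃R_m², Δp̃R_m³)
grid at fixed C₀R_m, classifying each cell against the bare-vesicle
reference force and against zero: ABOVE_REF / BELOW_REF / SPONTANEOUS
(F̃ < 0) / IMPOSSIBLE (Λ ≤ 0, solver failure, or no usable truncation).
The default tier is the sixth-order series (cheap enough for 61×61
grids); any cell can be spot-checked with the exact solver.  Spontaneous
cells appear only for C₀R_m > 1.

## Study conditions and problem sizes

The canonical parameter families (in `vesipinch.fixtures`) are: the cap
exemplars (Λ, Γ) = (0.5, −24), (1, −24), (1.5, −24); the
tension/pressure pathway family Σ̃R_m², Δp̃R_m³ ∈ {−0.3, 0, +0.3} at
C₀ = 0 excluding the doubly negative corner, whose Λ = 0.1 lies outside
the validity domain (the family's smallest member is Λ = 0.4); the
curvature family C₀R_m ∈ {−0.3, 0, +0.3} at Σ = Δp = 0; and phase panels
C₀R_m ∈ {−0.3, 0, 0.3, 0.8, 1.5} over Σ̃R_m² ∈ [−0.6, 0.6],
Δp̃R_m³ ∈ [−0.3, 0.3] (61×61 by default).  Cross-tier comparisons in the
tests and the acceptance script use exact-tier sweeps over
s ∈ [0.1, 0.95] at Δs = 0.05 (refined near 0.9), which keeps a full
family sweep around half a minute on one core; finer grids change the
reported quantities well below their comparison tolerances.

On this family the perturbative cap quantities (L_p, cap area, cap
volume) agree with the exact solver to within 5% (worst ≈ 4.5% at
Λ = 0.4); series and exact total energies agree within 5% up to s ≈ 0.65;
the exact energy lower-bounds the variational energy, which lower-bounds
the family energy at the series lengths, at every stage tested.

## What the model does not cover

Heterogeneous or multi-component membranes, spatially varying C₀, shear
rigidity of composite shells, asymmetric (budding) branches and their
stability, protein coats, thermal fluctuations, and any kinetics — the
pathway is a quasi-static minimum-energy sequence.  The neck ansatz is
the zeroth-order cosine family only; its known cost is the growing error
of the analytic tiers at high constriction (s ≳ 0.65), which is why the
exact tier exists.  Degenerate inputs are refused rather than
approximated: Λ ≤ 0, Γ = −29, zero-length necks at s > 0, s outside
[0, 1].
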
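# vesipinch

Mechanics of symmetric vesicle constriction: minimum-energy axisymmetric
shapes, energies and constriction forces of a membrane vesicle pinched at
its equator, as a function of bending rigidity, spontaneous curvature,
surface tension and osmotic pressure.

The package is aimed at membrane biophysicists and synthetic-biology
modellers who want quantitative estimates of the mechanical work and force
a divisome (FtsZ ring, actomyosin furrow, or an artificial constriction
machinery) must deliver to divide a cell-sized vesicle.

## The model

The vesicle is a closed axisymmetric surface with total energy

```
E_T = E_b + Σ A + Δp V,
E_b = (κ/2) ∮ (C₁ + C₂ − C₀)² dA + κ_G ∮ C₁C₂ dA,
```

where κ is the bending modulus, C₀ the spontaneous curvature, Σ the
surface tension and Δp the osmotic pressure difference (the Gaussian term
is topological and only enters at fission, as ΔE_G = 4πκ_G).  Constriction
is parameterized by s = 1 − R_c/R_m, with R_c the equatorial radius and
R_m the polar (maximum) radius, held constant along the pathway.  All
results depend on the parameters only through the dilatation-invariant
groups C₀R_m, Σ̃R_m² = ΣR_m²/κ and Δp̃R_m³ = ΔpR_m³/κ, combined into

```
Λ = (1 − C₀R_m)² + 2Σ̃R_m² + Δp̃R_m³,     Γ = (2 − C₀R_m)² + 2Σ̃R_m² − 1.
```

Λ ≤ 0 makes constriction impossible; Λ ≷ 1 selects oblate/prolate polar
caps via the optimal cap deformation ε = −5(Λ−1)/(Γ+29), L_p = R_m(1+ε).

Three solution tiers share one interface:

* **series** — closed-form perturbative expansions (fourth or sixth
  order), e.g. the neck half-length L_m/R_m = (π/2)(6/Λ)^¼ √s (1 + …) and
  the energy rise ΔE_T/κ = (4/3)π² 6^¼ Λ^¾ √s (1 + …), with the
  constriction force F_c = (1/R_m) dE_T/ds obtained term by term;
* **variational** — numerical minimization of the exact-quadrature energy
  of the cosine-neck/spheroidal-cap shape family over (L_m, L_p);
* **exact** — the Euler–Lagrange shape equations in arclength/tangent-angle
  form, solved as a two-segment boundary-value problem with the fixed
  polar radius enforced by a ring line tension.

## Worked example

```python
import vesipinch as vp
from vesipinch.observables import exact_sweep

state = vp.state_from_groups(c0r=0.0, sig=0.0, prs=0.0)   # bare vesicle
df = exact_sweep(state, [0.0, 0.3, 0.5, 0.7, 0.9])
print(df[["s", "E_total", "A", "V", "F"]].round(3))
```

prints

```
     s  E_total       A      V       F
0  0.0   25.133  12.566  4.189  38.999
1  0.3   36.832  25.787  9.726  27.295
2  0.5   40.731  26.853  9.582  18.739
3  0.7   44.328  26.561  9.084  18.356
4  0.9   48.073  25.645  8.597  18.727
```

Energies are in units of κ, areas in R_m², volumes in R_m³, forces in
κ/R_m (finite differences on this coarse grid; the large value at s = 0
is the kick-off transient).  The s = 0 row is the unit sphere
(E = 8π ≈ 25.13); by s = 0.9 the energy has nearly doubled toward the
two-sphere limit 16π, and the force needed to advance constriction is
≈ 20 κ/R_m — about 0.8 pN for a 1 µm vesicle with κ = 10 k_BT, i.e.

```python
params = vp.MembraneParams(kappa_kT=10.0, R_m=1e-6)
vp.to_physical(20.0, "force", params)     # 8.2e-13 N
```

The `examples/` directory holds short narrative scripts, one per
capability (reduced groups and units, cap shapes, the three tiers, force
phase diagrams, constant-area/volume division).  A thin CLI mirrors the
library:

```bash
vesipinch caps --Lambda 1.5 --Gamma -24          # cap shape report
vesipinch sweep --tier exact --smax 0.9 -o sweep.csv
vesipinch phase --c0r 1.5 -o phase               # force phase diagram
```

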
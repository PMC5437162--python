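"""Reduced parameter groups and unit conversions.

A micron-sized vesicle with a flexible bilayer (kappa = 10 kBT) under
modest tension and osmotic pressure is reduced to the dimensionless
groups that control its constriction mechanics, and back.
"""

import vesipinch as vp

params = vp.MembraneParams(
    kappa_kT=10.0,          # bending modulus, k_B T units
    C0=0.3e6,               # spontaneous curvature, 1/m  (0.3 per um)
    Sigma=1.2e-8,           # surface tension, N/m
    DeltaP=1.2e-2,          # osmotic pressure difference, Pa
    R_m=1e-6,               # polar radius, m
)
state = vp.make_dimensionless(params)

print(f"C0*R_m          = {state.c0r:.3f}")
print(f"Sigma*R_m^2/k   = {state.sig:.3f}")
print(f"DeltaP*R_m^3/k  = {state.prs:.3f}")
print(f"Lambda          = {state.Lambda:.3f}   (1 = spherical caps)")
print(f"Gamma           = {state.Gamma:.3f}")
print(f"regime          = {state.regime.value}")

# a reduced force of 20 kappa/R_m in piconewtons
F_pN = vp.to_physical(20.0, "force", params) * 1e12
print(f"F~ = 20  ->  F_c = {F_pN:.2f} pN")

# Lambda and Gamma are the two combinations of the groups that enter the
# minimum-energy series; the regime tells whether constriction is possible
# (Lambda > 0) and the cap series regular (Gamma != -29).
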
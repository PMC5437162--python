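"""Constriction-force phase diagram and spontaneous constriction.

The reduced force F~ = F_c R_m / kappa at the beginning of constriction
(s = 0.2) is classified on a (tension, pressure) grid.  Below C0*R_m = 1
no combination of tension and pressure makes the force negative; above
it, a region of spontaneous constriction (F~ < 0) opens up at low or
negative tension.
"""

import numpy as np

from vesipinch.observables import PhaseCategory, phase_map

sig = np.linspace(-0.6, 0.6, 31)
prs = np.linspace(-0.3, 0.3, 31)

for c0r in (0.0, 0.8, 1.5):
    pm = phase_map(c0r, sig, prs, s_eval=0.2, tier="series")
    print(f"C0*R_m = {c0r}:")
    print(f"  reference force F_c0       = {pm.F_ref:6.2f} kappa/R_m")
    for cat in (PhaseCategory.BELOW_REF, PhaseCategory.ABOVE_REF,
                PhaseCategory.SPONTANEOUS, PhaseCategory.IMPOSSIBLE):
        print(f"  {cat.name.lower():<12} cell fraction = {pm.fraction(cat):.3f}")

# The 'impossible' cells are the Lambda <= 0 region (and the thin band
# where the truncated series has no usable value); 'spontaneous' appears
# only on the C0*R_m = 1.5 panel.
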
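"""One constriction pathway, three fidelity tiers.

The bare vesicle (C0 = Sigma = DeltaP = 0) is constricted at fixed polar
radius.  The closed-form sixth-order series, the numerical minimization
over the cosine-neck/spheroid-cap family, and the exact Euler-Lagrange
solution are compared stage by stage: the exact energy lower-bounds the
family, and the series tracks both to a few percent up to s ~ 0.65.
"""

import numpy as np

import vesipinch as vp
from vesipinch.observables import exact_sweep, series_sweep, variational_sweep

state = vp.state_from_groups(0.0, 0.0, 0.0)
s_grid = np.array([0.1, 0.3, 0.5, 0.7])

ser = series_sweep(state, s_grid)
var = variational_sweep(state, s_grid)
exa = exact_sweep(state, s_grid)

print("  s   E_series  E_variational  E_exact   (kappa units)")
for i, s in enumerate(s_grid):
    print(f"{s:4.1f}  {ser['E_total'][i]:8.3f}  {var['E_total'][i]:13.3f}"
          f"  {exa['E_total'][i]:8.3f}")

print(f"\nunconstricted sphere: E = 8 pi = {8 * np.pi:.3f} kappa")
print("E_exact <= E_variational everywhere (the exact shape is the true")
print("minimum over all profiles, the variational one only over the")
print("two-length family).  The series column is a truncated expansion,")
print("not the energy of any profile, and tracks both to within 5% up to")
print("s ~ 0.65 before drifting.")
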
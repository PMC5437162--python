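"""Division at constant membrane area or constant volume.

The fixed-R_m pathway is rescaled by the similarity transformation
lam(s): holding total membrane area fixed, completing division into two
equal spheres requires losing 1 - 2^(-1/2) ~ 29.3% of the enclosed
volume; holding volume fixed instead requires 2^(1/3) - 1 ~ 26% extra
area.  The Gaussian-curvature step 4 pi kappa_G is paid only at the final
topology change.
"""

import numpy as np
import pandas as pd

import vesipinch as vp
from vesipinch.observables import (exact_sweep, fission_energy_step,
                                   rescale_constraint, two_sphere_limit)

state = vp.state_from_groups(0.0, 0.0, 0.0)
df = exact_sweep(state, np.arange(0.0, 0.91, 0.15))
traj = pd.concat([df, two_sphere_limit(state)], ignore_index=True)

const_A = rescale_constraint(traj, "constant_area")
red = 1.0 - const_A.iloc[-1]["V_rescaled"] / const_A.loc[0, "V"]
print(f"constant area:   volume reduction to divide = {100 * red:.1f} %")

const_V = rescale_constraint(traj, "constant_volume")
inc = const_V.iloc[-1]["A_rescaled"] / const_V.loc[0, "A"] - 1.0
print(f"constant volume: area increase to divide    = {100 * inc:.1f} %")

dEG = fission_energy_step(10.0, -0.8 * 10.0)
print(f"Gaussian fission step (kappa_G = -0.8 x 10 kBT): {dEG:.1f} kBT")
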
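"""Optimal polar-cap shapes: prolate, spherical and oblate vesicles.

The polar caps are spheroids with equatorial semi-axis R_m and polar
semi-axis L_p = R_m (1 + eps); minimizing the quadratic cap energy gives
eps = -5 (Lambda - 1) / (Gamma + 29).  At Gamma = -24, Lambda = 0.5 / 1 /
1.5 produce the three canonical initial shapes.
"""

import vesipinch as vp


def state_for(Lambda, Gamma):
    # realize the pair with zero spontaneous curvature
    return vp.state_from_groups(0.0, (Gamma - 3.0) / 2.0, Lambda - Gamma + 2.0)


for Lambda, label in [(0.5, "prolate"), (1.0, "sphere "), (1.5, "oblate ")]:
    cap = vp.cap_solution(state_for(Lambda, -24.0))
    print(f"Lambda={Lambda:.1f} ({label}): eps = {cap.epsilon:+.3f}, "
          f"L_p = {cap.L_p:.2f} R_m, "
          f"A_caps/A_sphere = {cap.A_caps / (4 * 3.14159265):.3f}, "
          f"V_caps/V_sphere = {cap.V_caps / 4.1887902:.3f}")

# eps < 0 flattens the vesicle along the symmetry axis (oblate), eps > 0
# elongates it (prolate); the cap shape is set once by (Lambda, Gamma) and
# does not change as the equator is constricted at fixed R_m.
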
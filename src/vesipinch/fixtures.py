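"""Canonical parameter sets for the published figure families.

These are the study conditions the rest of the package is exercised
against: the three cap-shape exemplars (prolate/sphere/oblate at
Gamma = -24), the tension/pressure pathway family at zero spontaneous
curvature, the spontaneous-curvature family at zero tension/pressure, and
the phase-diagram panels.  The tension/pressure family spans
(sig, prs) in {-0.3, 0, +0.3}^2 except the doubly negative corner, whose
Lambda = 0.1 lies outside the validity domain of the perturbative method
(its smallest member is Lambda = 0.4).
"""

from __future__ import annotations

from .core_model import DimensionlessState, state_from_groups

__all__ = ["fixture_grids", "cap_exemplars", "pathway_states",
           "phase_panels"]

_VALS = (-0.3, 0.0, 0.3)


def cap_exemplars() -> list[dict]:
    """(Lambda, Gamma) triples of the prolate / spherical / oblate caps."""
    return [
        {"name": "prolate", "Lambda": 0.5, "Gamma": -24.0, "L_p": 1.5},
        {"name": "sphere", "Lambda": 1.0, "Gamma": -24.0, "L_p": 1.0},
        {"name": "oblate", "Lambda": 1.5, "Gamma": -24.0, "L_p": 0.5},
    ]


def pathway_states(include_reference_once: bool = True) -> list[DimensionlessState]:
    """States of the two pathway families (tension/pressure and curvature).

    Tension/pressure family: c0r = 0, (sig, prs) in {-0.3, 0, 0.3}^2 minus
    the doubly negative corner.  Curvature family: sig = prs = 0,
    c0r in {-0.3, 0, 0.3}.  The bare vesicle appears in both; it is
    deduplicated unless ``include_reference_once`` is False.
    """
    states = []
    for sg in _VALS:
        for pr in _VALS:
            if sg == -0.3 and pr == -0.3:
                continue
            states.append(state_from_groups(0.0, sg, pr))
    for c0 in _VALS:
        if c0 == 0.0 and include_reference_once:
            continue  # already present as (0, 0, 0)
        states.append(state_from_groups(c0, 0.0, 0.0))
    return states


def phase_panels() -> list[dict]:
    """Phase-diagram panels: grid limits and the c0r of each panel."""
    panels = []
    for c0 in (-0.3, 0.0, 0.3, 0.8, 1.5):
        panels.append({
            "c0r": c0,
            "sig_min": -0.6, "sig_max": 0.6,
            "prs_min": -0.3, "prs_max": 0.3,
            "n_sig": 61, "n_prs": 61,
            "s_eval": 0.2,
        })
    return panels


def fixture_grids() -> dict:
    """Deterministic enumeration of all canonical parameter sets."""
    return {
        "cap_exemplars": cap_exemplars(),
        "pathways": [
            {"c0r": st.c0r, "sig": st.sig, "prs": st.prs,
             "Lambda": st.Lambda, "Gamma": st.Gamma}
            for st in pathway_states()
        ],
        "phase_panels": phase_panels(),
    }
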
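import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import vesipinch as vp
from vesipinch.shape_ansatz import build_profile, profile_obj_mesh, profile_table


def spheroid_area_closed_form(L_p):
    """Prolate/oblate spheroid area with equatorial semi-axis 1.

    A = 2 pi [1 + (L_p/e) arcsin(e)] with e^2 = 1 - 1/L_p^2 (prolate); the
    analytic continuation arcsin(i|e|)/i = arcsinh(|e|) covers the oblate
    branch.
    """
    if L_p == 1.0:
        return 4.0 * math.pi
    e2 = 1.0 - 1.0 / L_p**2
    if e2 > 0:
        e = math.sqrt(e2)
        return 2.0 * math.pi * (1.0 + L_p / e * math.asin(e))
    e = math.sqrt(-e2)
    return 2.0 * math.pi * (1.0 + L_p / e * math.asinh(e))


class TestSphere:
    prof = build_profile(0.0, 0.0, 1.0)

    def test_bending_energy(self):
        assert vp.bending_energy(self.prof, 0.0) == pytest.approx(8 * math.pi, rel=1e-10)

    def test_bending_energy_with_spontaneous_curvature(self):
        # 8 pi (1 - c0/2)^2 at c0r = 1
        assert vp.bending_energy(self.prof, 1.0) == pytest.approx(2 * math.pi, rel=1e-9)

    def test_area_volume(self):
        A, V = vp.area_volume(self.prof)
        assert A == pytest.approx(4 * math.pi, rel=1e-10)
        assert V == pytest.approx(4 * math.pi / 3, rel=1e-12)


@pytest.mark.parametrize("L_p", [0.5, 0.9, 1.1, 1.5])
def test_spheroid_area_matches_closed_form(L_p):
    A, V = vp.area_volume(build_profile(0.0, 0.0, L_p))
    assert A == pytest.approx(spheroid_area_closed_form(L_p), rel=1e-10)
    assert V == pytest.approx(4 * math.pi / 3 * L_p, rel=1e-12)


def test_cap_bending_against_x_quadrature_oracle():
    """The angle-parameterized cap quadrature equals an independent
    x-parameterized quadrature of the raw kernel (spheroid, eps = 0.1)."""
    L_p, c0r = 1.1, 0.0
    prof = build_profile(0.0, 0.0, L_p)
    e_theta = vp.bending_energy(prof, c0r)

    def kernel_x(x):
        w = x / L_p
        R = math.sqrt(1.0 - w * w)
        Rx = -w / (L_p * R)
        Rxx = -1.0 / (L_p**2 * R**3)
        op = 1.0 + Rx * Rx
        N = op - Rxx * R - R * c0r * op**1.5
        return N * N / (R * op**2.5)

    # integrable endpoint singularity at the pole: stop just short and
    # bound the remainder by the analytic tail ~ 2 L_p^2 (1 - w^2)
    val, _ = quad(kernel_x, 0.0, L_p * (1 - 1e-12), limit=400)
    e_x = 2.0 * math.pi * val          # pi * (two caps)
    assert e_x == pytest.approx(e_theta, rel=1e-8)


class TestProfileInvariants:
    @given(s=st.floats(0.01, 0.95), L_m=st.floats(0.1, 2.0),
           L_p=st.floats(0.5, 1.5), x=st.floats(-3.5, 3.5))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_positivity_bounds(self, s, L_m, L_p, x):
        prof = build_profile(s, L_m, L_p)
        x = min(max(x, -prof.half_length), prof.half_length)
        r1, r2 = prof.R(np.array([x])), prof.R(np.array([-x]))
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 >= 0.0
        assert r1 <= 1.0 + 1e-12

    @pytest.mark.parametrize("s", [0.0, 0.25, 0.5, 0.9])
    def test_waist_and_junction(self, s):
        L_m = 0.8 if s > 0 else 0.0
        prof = build_profile(s, L_m, 1.0)
        assert prof.R(np.array([0.0])) == pytest.approx(1.0 - s, abs=1e-14)
        if s > 0:
            below, above = L_m - 1e-15, L_m + 1e-15
            assert prof.R(np.array([below])) == pytest.approx(
                prof.R(np.array([above])), abs=1e-9)
            assert prof.R(np.array([L_m])) == pytest.approx(1.0, abs=1e-14)

    def test_degenerate_neck_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_profile(0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            build_profile(0.5, 0.8, -1.0)
        with pytest.raises(ValueError):
            build_profile(1.5, 0.8, 1.0)


def test_neck_contributions_vanish_as_s_to_zero(ref_state):
    base = vp.total_energy(build_profile(0.0, 0.0, 1.0), ref_state)
    prev = None
    for s in [0.1, 0.03, 0.01]:
        lm = 0.5 * math.pi * 6**0.25 * math.sqrt(s)
        obs = vp.total_energy(build_profile(s, lm, 1.0), ref_state)
        dE = obs.E_total - base.E_total
        dA = obs.A - base.A
        dV = obs.V - base.V
        assert dE > 0 and dA > 0 and dV > 0
        if prev is not None:
            assert dE < prev[0] and dA < prev[1] and dV < prev[2]
        prev = (dE, dA, dV)
    assert prev[0] < 3.0 * math.sqrt(0.01) * 8  # consistent with sqrt(s) scaling


def test_total_energy_identity():
    state = vp.state_from_groups(0.1, 0.2, -0.1)
    obs = vp.total_energy(build_profile(0.3, 0.7, 1.05), state)
    assert obs.E_total == pytest.approx(
        obs.E_bend + state.sig * obs.A + state.prs * obs.V, rel=1e-14)
    assert obs.E_bend == pytest.approx(obs.E_bend_caps + obs.E_bend_neck, rel=1e-14)
    # field-free case reduces to pure bending
    obs0 = vp.total_energy(build_profile(0.3, 0.7, 1.05),
                           vp.state_from_groups(0.0, 0.0, 0.0))
    assert obs0.E_total == pytest.approx(obs0.E_bend, rel=1e-14)


def test_exports():
    prof = build_profile(0.4, 0.8, 1.0)
    tab = profile_table(prof, n=101)
    assert tab.shape == (101, 2)
    assert np.all(np.isfinite(tab))
    obj = profile_obj_mesh(prof, n_axial=10, n_azimuthal=8)
    assert obj.count("\nv ") + obj.startswith("v ") == 80
    assert "f " in obj
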
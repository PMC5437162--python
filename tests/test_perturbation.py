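import json
import math

import numpy as np
import pytest
import sympy as sp

import vesipinch as vp
from vesipinch.perturbation import (EPS_MAX, _derive_cap_symbolic, _LAM, _GAM,
                                    _C, cap_solution, derive_series,
                                    neck_series_eval, series_to_json)

from conftest import state_for


def printed_l2_bracket(lam, gam):
    """The first L_m correction: the regenerated coefficient shares the
    published numerator 72(Lambda-Gamma) + (Gamma-4) 6^(3/2) sqrt(Lambda)
    - 25 sqrt(6) Lambda^(3/2); the denominator is 576 Lambda (the symbolic
    engine arbitrates the garbled printed prefactor)."""
    return (72 * (lam - gam) + (gam - 4) * 6**1.5 * math.sqrt(lam)
            - 25 * math.sqrt(6) * lam**1.5) / (576 * lam)


def printed_energy_bracket(lam, gam):
    """s-coefficient of the energy brace: -3/(576 Lambda) [5 sqrt(6)
    Lambda^(3/2) + 168 Lambda - (Gamma-4) 6^(3/2) sqrt(Lambda) - 72 Gamma]."""
    return -3.0 / (576 * lam) * (5 * math.sqrt(6) * lam**1.5 + 168 * lam
                                 - (gam - 4) * 6**1.5 * math.sqrt(lam)
                                 - 72 * gam)


class TestSymbolicRegeneration:
    def test_leading_length(self, series4):
        """L_m/R_m -> (pi/2) (6/Lambda)^(1/4) sqrt(s)."""
        l1 = series4.L_m.coeffs[0]
        target = sp.pi / 2 * (6 / _LAM) ** sp.Rational(1, 4)
        assert sp.simplify(l1 - target) == 0

    @pytest.mark.parametrize("lam,gam", [(1, 3), (1.5, -24), (0.5, -24),
                                         (0.7, 2.4), (2.0, 5.0)])
    def test_length_correction(self, series4, lam, gam):
        l1 = series4.L_m.funcs[0](lam**0.25, gam, 0.0)
        l1l2 = series4.L_m.funcs[1](lam**0.25, gam, 0.0)
        assert l1l2 / l1 == pytest.approx(printed_l2_bracket(lam, gam), rel=1e-12)

    @pytest.mark.parametrize("lam,gam", [(1, 3), (1.5, -24), (0.5, -24)])
    def test_energy_series(self, series4, lam, gam):
        e0 = series4.dE.funcs[0](lam**0.25, gam, 0.0)
        e1 = series4.dE.funcs[1](lam**0.25, gam, 0.0)
        lead = 4.0 / 3.0 * math.pi**2 * 6**0.25 * lam**0.75
        assert e0 == pytest.approx(lead, rel=1e-12)
        assert e1 / e0 == pytest.approx(printed_energy_bracket(lam, gam), rel=1e-12)

    def test_leading_area_volume_are_cylinder_values(self, series4):
        """dA -> 2 pi R_m * 2 L_m and dV -> pi R_m^2 * 2 L_m at leading
        order: the nascent neck is a cylinder of radius R_m."""
        for lam in (0.5, 1.0, 1.7):
            a0 = series4.dA.funcs[0](lam**0.25, 3.0, 0.0)
            v0 = series4.dV.funcs[0](lam**0.25, 3.0, 0.0)
            l1 = series4.L_m.funcs[0](lam**0.25, 3.0, 0.0)
            assert a0 == pytest.approx(2 * math.pi * 2 * l1, rel=1e-12)
            assert v0 == pytest.approx(math.pi * 2 * l1, rel=1e-12)
            assert a0 == pytest.approx(2 * math.pi**2 * (6 / lam) ** 0.25, rel=1e-12)

    def test_order4_coefficients_are_lambda_gamma_only(self, series4):
        for sc in series4.as_dict().values():
            for f in sc.funcs:
                a = f(1.3**0.25, -2.0, 0.0)
                b = f(1.3**0.25, -2.0, 0.4)
                assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    def test_order6_has_explicit_curvature_dependence(self, series6):
        # verified against direct quadrature: the c0r terms at s^(5/2) are real
        f = series6.dE.funcs[2]
        assert abs(f(1.0, 3.0, 0.2) - f(1.0, 3.0, 0.0)) > 1e-3


class TestCapSolution:
    @pytest.mark.parametrize("lam,gam,eps", [
        (1.5, -24.0, -0.5),   # oblate exemplar
        (0.5, -24.0, +0.5),   # prolate exemplar
        (1.0, -24.0, 0.0),    # sphere regardless of Gamma
        (1.0, 3.0, 0.0),
    ])
    def test_optimal_epsilon(self, lam, gam, eps):
        cap = cap_solution(state_for(lam, gam))
        assert cap.epsilon == pytest.approx(eps, abs=1e-12)
        assert cap.L_p == pytest.approx(1.0 + eps, abs=1e-12)

    def test_cap_formulas(self):
        sym = _derive_cap_symbolic()
        assert sp.simplify(sym["eps_opt"] + 5 * (_LAM - 1) / (_GAM + 29)) == 0
        assert sp.simplify(sym["E1"] - sp.Rational(4, 3) * sp.pi * (_LAM - 1)) == 0
        assert sp.simplify(sym["E2"] - sp.Rational(2, 15) * sp.pi * (_GAM + 29)) == 0
        assert sym["A1"] == sp.Rational(2, 3)
        assert sym["A2"] == sp.Rational(1, 15)

    def test_sphere_energy_expression(self):
        # E_sph = pi (8 + 2 c^2 - 8 c + 4 sig + 4/3 prs)
        st = vp.state_from_groups(0.25, 0.1, -0.2)
        cap = cap_solution(st)
        target = math.pi * (8 + 2 * 0.25**2 - 8 * 0.25 + 4 * 0.1 + 4 / 3 * -0.2)
        assert cap.E_sph == pytest.approx(target, rel=1e-12)

    def test_volume_exact_and_flagging(self):
        cap = cap_solution(state_for(1.5, -24.0))
        assert cap.V_caps == pytest.approx(4 * math.pi / 3 * 0.5, rel=1e-12)
        assert cap.flagged  # |eps| = 0.5 = EPS_MAX boundary
        assert not cap_solution(state_for(1.1, 3.0)).flagged

    def test_singular_cap_refused(self):
        with pytest.raises(ValueError, match="-29"):
            cap_solution(state_for(1.2, -29.0))

    def test_cap_energy_matches_quadrature(self):
        """Quadratic cap series vs exact-quadrature spheroid energy."""
        st = vp.state_from_groups(0.0, 0.1, -0.05)
        cap = cap_solution(st)
        obs = vp.total_energy(vp.build_profile(0.0, 0.0, cap.L_p), st)
        assert cap.E_caps == pytest.approx(obs.E_total, rel=2e-4)
        assert cap.A_caps == pytest.approx(obs.A, rel=1e-5)


class TestNeckSeries:
    def test_small_s_limit(self, ref_state):
        out = neck_series_eval(1e-10, ref_state, order=6)
        for key in ("L_m", "dE", "dA", "dV"):
            assert abs(float(out[key])) < 1e-3

    def test_force_is_termwise_energy_derivative(self, ref_state):
        """F~ = d(dE)/ds: analytic series vs centered finite difference."""
        s, h = 0.2, 1e-5
        out = neck_series_eval([s - h, s, s + h], ref_state, order=6)
        fd = (out["dE"][2] - out["dE"][0]) / (2 * h)
        assert float(out["F"][1]) == pytest.approx(fd, rel=1e-6)

    def test_series_against_brute_force_minimum(self, ref_state):
        """Order-6 energy vs direct numeric minimization of the quadrature
        energy over L_m (independent oracle) at small s."""
        from scipy.optimize import minimize_scalar
        s = 0.02
        base = vp.total_energy(vp.build_profile(0.0, 0.0, 1.0), ref_state).E_total

        def neck(L):
            obs = vp.total_energy(vp.build_profile(s, L, 1.0), ref_state)
            return obs.E_total - base

        r = minimize_scalar(neck, bounds=(0.05, 1.5), method="bounded",
                            options={"xatol": 1e-10})
        out = neck_series_eval(s, ref_state, order=6)
        assert float(out["L_m"]) == pytest.approx(r.x, rel=2e-3)
        assert float(out["dE"]) == pytest.approx(r.fun, rel=2e-4)

    def test_impossible_state_refused(self):
        bad = vp.state_from_groups(0.0, -0.6, 0.0)   # Lambda = -0.2
        with pytest.raises(ValueError, match="impossible"):
            neck_series_eval(0.2, bad, order=6)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            derive_series(5)


def test_series_json_export(ref_state):
    text = series_to_json(4, ref_state)
    data = json.loads(text)
    assert data["order"] == 4
    assert set(data["quantities"]) == {"L_m", "dE", "dA", "dV", "F"}
    lm = data["quantities"]["L_m"]
    assert len(lm["coefficients"]) == len(lm["numeric"]) == 2
    assert lm["numeric"][0] == pytest.approx(0.5 * math.pi * 6**0.25, rel=1e-12)
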
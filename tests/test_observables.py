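import math

import numpy as np
import pandas as pd
import pytest

import vesipinch as vp
from vesipinch.core_model import BOLTZMANN_J_PER_K
from vesipinch.observables import (PhaseCategory, exact_sweep,
                                   fission_energy_step, force_from_energy,
                                   phase_map, rescale_constraint,
                                   series_sweep, two_sphere_limit,
                                   variational_sweep)


class TestForceFromEnergy:
    def test_sqrt_profile(self):
        """E = c sqrt(s) -> F = c / (2 sqrt(s)) away from the ends."""
        c = 3.7
        s = np.linspace(0.1, 0.9, 401)
        fc = force_from_energy(s, c * np.sqrt(s))
        inner = slice(5, -5)
        assert np.allclose(fc.F[inner], c / (2 * np.sqrt(s[inner])), rtol=1e-4)

    def test_richardson_convergence_to_series_force(self, ref_state):
        """Finite-difference force converges at O(h^2) to the analytic
        series force."""
        errs = []
        for n in (51, 101, 201):
            s = np.linspace(0.1, 0.3, n)
            dE = vp.neck_series_eval(s, ref_state, order=6)["dE"]
            fc = force_from_energy(s, dE)
            f_true = float(vp.neck_series_eval(0.2, ref_state, order=6)["F"])
            errs.append(abs(fc.at(0.2) - f_true))
        assert errs[2] < errs[0] / 8  # better than O(h^2) on this window

    def test_validation(self):
        with pytest.raises(ValueError):
            force_from_energy([0.1, 0.2], [1, 2])
        with pytest.raises(ValueError):
            force_from_energy([0.1, 0.3, 0.2], [1, 2, 3])


class TestFissionStep:
    def test_value_is_4pi_kappa_G(self):
        assert fission_energy_step(10.0, -8.0) == pytest.approx(-32 * math.pi)
        assert fission_energy_step(10.0, 0.0) == 0.0

    def test_flexible_membrane_magnitude(self):
        # kappa = 10 kBT, kappa_G = -0.8 kappa -> ~ -100 kBT
        dEG = fission_energy_step(10.0, -0.8 * 10.0)
        assert dEG == pytest.approx(-100.5, rel=0.01)


class TestRescaling:
    @pytest.fixture(scope="class")
    def traj(self, ref_state):
        df = series_sweep(ref_state, np.linspace(0.0, 0.6, 7))
        return pd.concat([df, two_sphere_limit(ref_state)], ignore_index=True)

    def test_identity_at_s0(self, traj):
        out = rescale_constraint(traj, "constant_area")
        assert out.loc[0, "lam"] == pytest.approx(1.0, rel=1e-12)

    def test_constant_area_holds(self, traj):
        out = rescale_constraint(traj, "constant_area")
        assert np.allclose(out["A_rescaled"], out.loc[0, "A"], rtol=1e-10)

    def test_constant_volume_holds(self, traj):
        out = rescale_constraint(traj, "constant_volume")
        assert np.allclose(out["V_rescaled"], out.loc[0, "V"], rtol=1e-10)

    def test_two_sphere_volume_reduction(self, traj):
        """Fixed total area, one sphere -> two spheres: volume falls by
        1 - 2^(-1/2) ~ 29.3%."""
        out = rescale_constraint(traj, "constant_area")
        final = out.iloc[-1]
        assert final["s"] == 1.0
        ratio = final["V_rescaled"] / out.loc[0, "V"]
        assert ratio == pytest.approx(2**-0.5, rel=1e-9)

    def test_two_sphere_area_increase(self, traj):
        """Fixed total volume: area grows by 2^(1/3) - 1 ~ 26%."""
        out = rescale_constraint(traj, "constant_volume")
        ratio = out.iloc[-1]["A_rescaled"] / out.loc[0, "A"]
        assert ratio == pytest.approx(2 ** (1 / 3), rel=1e-9)

    def test_invalid(self, traj):
        with pytest.raises(ValueError):
            rescale_constraint(traj, "constant_banana")
        broken = traj.copy()
        broken.loc[1, "A"] = -1.0
        with pytest.raises(ValueError):
            rescale_constraint(broken, "constant_area")


class TestPhaseMap:
    sig = np.linspace(-0.6, 0.6, 13)
    prs = np.linspace(-0.3, 0.3, 13)

    def test_impossible_cells_are_lambda_nonpositive(self):
        pm = phase_map(0.0, self.sig, self.prs, tier="series")
        for i, sg in enumerate(self.sig):
            for j, pr in enumerate(self.prs):
                lam = 1.0 + 2 * sg + pr
                if lam <= 0:
                    assert pm.category[i, j] == int(PhaseCategory.IMPOSSIBLE)

    def test_spontaneous_only_above_unit_curvature(self):
        for c0 in (0.0, 0.3, 0.8):
            pm = phase_map(c0, self.sig, self.prs, tier="series")
            assert pm.fraction(PhaseCategory.SPONTANEOUS) == 0.0
        pm = phase_map(1.5, self.sig, self.prs, tier="series")
        assert pm.fraction(PhaseCategory.SPONTANEOUS) > 0.0

    def test_force_monotone_in_curvature(self):
        for sg, pr in [(0.0, 0.0), (0.3, 0.1), (-0.1, -0.05)]:
            F = [float(vp.neck_series_eval(0.2, vp.state_from_groups(c, sg, pr),
                                           order=6)["F"])
                 for c in np.linspace(-0.3, 0.3, 7)]
            assert all(np.diff(F) < 0)

    def test_reference_force_and_classification(self):
        pm = phase_map(0.0, np.array([-0.1, 0.0, 0.1]), np.array([0.0]),
                       tier="series")
        # positive tension raises the force above the reference
        assert pm.category[2, 0] == int(PhaseCategory.ABOVE_REF)
        assert pm.category[0, 0] == int(PhaseCategory.BELOW_REF)
        assert pm.F[1, 0] == pytest.approx(pm.F_ref, rel=1e-12)


class TestSweepTables:
    def test_series_sweep_schema(self, ref_state):
        df = series_sweep(ref_state, [0.0, 0.1, 0.2])
        assert list(df["s"]) == [0.0, 0.1, 0.2]
        assert df.loc[0, "E_total"] == pytest.approx(8 * math.pi, rel=1e-12)
        assert (df["tier"] == "series").all()

    def test_exact_sweep_includes_unconstricted(self, ref_state):
        df = exact_sweep(ref_state, [0.0, 0.2, 0.4])
        assert df.loc[0, "s"] == 0.0
        assert df.loc[0, "E_total"] == pytest.approx(8 * math.pi, rel=1e-5)
        assert df["E_total"].is_monotonic_increasing
        assert np.isfinite(df["F"]).all()

    def test_variational_sweep_force_column(self, ref_state):
        df = variational_sweep(ref_state, [0.1, 0.2, 0.3])
        assert np.isfinite(df["F"]).all()
        assert (df["F"] > 0).all()
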
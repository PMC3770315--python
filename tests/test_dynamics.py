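"""Euler integration of the wall dynamics and its fixed points."""

import numpy as np
import pytest

from microflowreg.calibration import ReferenceState
from microflowreg.dynamics import SimulationSettings, step_euler
from microflowreg.wall import (WallParameters, activation_target,
                               equilibrium_diameter, stimulus_tone,
                               total_tension, wall_tension_from_pressure)


def _ref_for(p, D_c, T_c):
    return ReferenceState(
        seg_ids=["x"], D0=np.array([p.D0]), D_c=np.array([D_c]),
        A_ref=np.array([0.5]), S_tone_ref=np.array([0.0]),
        C_tone=np.array([p.C_tone_pp]), T_c=np.array([T_c]), wall=[p],
        hemo=None, la_length=0.0)


class TestStepEuler:
    def setup_method(self):
        self.p = WallParameters(D0=12.0)
        self.p.C_tone_pp = -0.5 * self.p.C_myo \
            * wall_tension_from_pressure(100.0, 12.0)
        self.P = 70.0
        self.D_eq = equilibrium_diameter(self.p, self.P)
        T = wall_tension_from_pressure(self.P, self.D_eq)
        self.A_eq = activation_target(stimulus_tone(T, 0.0, 0.0, self.p))
        self.ref = _ref_for(self.p, self.D_eq, T)
        self.settings = SimulationSettings()

    def _terms(self, D, A):
        T = wall_tension_from_pressure(self.P, D)
        T_tot = np.array([total_tension(float(D), float(A), self.p)])
        A_tot = activation_target(np.array(
            [stimulus_tone(T, 0.0, 0.0, self.p)]))
        return np.atleast_1d(T), T_tot, np.atleast_1d(A_tot)

    def test_fixed_point_unchanged(self):
        D = np.array([self.D_eq])
        A = np.array([self.A_eq])
        T, T_tot, A_tot = self._terms(D[0], A[0])
        Dn, An = step_euler(D, A, T, T_tot, A_tot, self.ref, self.settings)
        assert Dn[0] == pytest.approx(D[0], rel=1e-12)
        assert An[0] == pytest.approx(A[0], rel=1e-9)

    def test_excess_tension_dilates(self):
        D = np.array([self.D_eq])
        A = np.array([self.A_eq])
        T, T_tot, _ = self._terms(D[0], A[0])
        Dn, _ = step_euler(D, A, T + 5.0, T_tot, np.array([self.A_eq]),
                           self.ref, self.settings)
        assert Dn[0] > D[0]

    def test_activation_relaxes_geometrically(self):
        # frozen target: discrete relaxation with ratio (1 - dt/tau_a)
        A_target = 0.8
        A = np.array([0.2])
        D = np.array([self.D_eq])
        ratio = 1.0 - self.settings.dt / self.settings.tau_a
        for k in range(1, 6):
            T, T_tot, _ = self._terms(D[0], A[0])
            D, A = step_euler(D, A, T, T, np.array([A_target]),
                              self.ref, self.settings)
            expected = A_target - (A_target - 0.2) * ratio ** k
            assert A[0] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_state_raises(self):
        from microflowreg.dynamics import IntegrationError
        with pytest.raises(IntegrationError):
            step_euler(np.array([10.0]), np.array([0.5]),
                       np.array([np.nan]), np.array([1.0]),
                       np.array([0.5]), self.ref, self.settings)


class TestSingleVesselEquilibrium:
    def test_dynamic_endpoint_matches_root_finding(self):
        """Euler endpoint equals the static equilibrium; rate constants
        affect the path but not the destination."""
        p = WallParameters(D0=12.0)
        p.C_tone_pp = -0.5 * p.C_myo * wall_tension_from_pressure(100.0, 12.0)
        P = 80.0
        D_eq = equilibrium_diameter(p, P)
        for tau_d, tau_a in ((1.0, 20.0), (2.0, 5.0)):
            settings = SimulationSettings(tau_d=tau_d, tau_a=tau_a)
            ref = _ref_for(p, D_eq, wall_tension_from_pressure(P, D_eq))
            D = np.array([0.8 * D_eq])
            A = np.array([0.3])
            for _ in range(4000):
                T = wall_tension_from_pressure(P, D)
                T_tot = np.array([total_tension(float(D[0]), float(A[0]), p)])
                A_tot = activation_target(np.array(
                    [stimulus_tone(float(T[0]), 0.0, 0.0, p)]))
                D, A = step_euler(D, A, T, T_tot, A_tot, ref, settings)
            assert D[0] == pytest.approx(D_eq, rel=1e-3)

    def test_determinism(self):
        p = WallParameters(D0=10.0)
        p.C_tone_pp = -0.5 * p.C_myo * wall_tension_from_pressure(100.0, 10.0)
        settings = SimulationSettings()
        ref = _ref_for(p, 8.0, wall_tension_from_pressure(70.0, 8.0))

        def run():
            D, A = np.array([8.0]), np.array([0.4])
            out = []
            for _ in range(200):
                T = wall_tension_from_pressure(70.0, D)
                T_tot = np.array([total_tension(float(D[0]), float(A[0]), p)])
                A_tot = activation_target(np.array(
                    [stimulus_tone(float(T[0]), 0.0, 0.0, p)]))
                D, A = step_euler(D, A, T, T_tot, A_tot, ref, settings)
                out.append((float(D[0]), float(A[0])))
            return out

        assert run() == run()
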
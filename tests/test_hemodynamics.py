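"""Two-phase flow: rheology oracles, solver limits, conservation."""

import numpy as np
import pytest

from microflowreg.hemodynamics import (FlowSolverSettings, MMHG_TO_DYN_CM2,
                                       RheologyError, UM_TO_CM,
                                       CM3S_TO_NLMIN, apparent_viscosity,
                                       classify_flowing,
                                       phase_separation_split,
                                       rbc_flux_fraction, solve_flows)

from conftest import make_ladder, make_single_tube, make_y_network


# --- independent one-line transcriptions of the empirical laws ----------

def oracle_viscosity(D, H):
    """In vivo apparent viscosity law, transcribed independently."""
    mu45 = 6 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)
    C = (0.8 + np.exp(-0.075 * D)) * (-1 + 1 / (1 + 1e-11 * D ** 12)) \
        + 1 / (1 + 1e-11 * D ** 12)
    r = (D / (D - 1.1)) ** 2
    return (1 + (mu45 - 1) * ((1 - H) ** C - 1) / ((1 - 0.45) ** C - 1) * r) \
        * r


def oracle_rbc_fraction(H, fq, Dp, D1, D2):
    """Empirical bifurcation partition law, transcribed independently."""
    X0 = 0.964 * (1 - H) / Dp
    if fq <= X0:
        return 0.0
    if fq >= 1 - X0:
        return 1.0
    A = -13.29 * ((D1 ** 2 - D2 ** 2) / (D1 ** 2 + D2 ** 2)) * (1 - H) / Dp
    B = 1 + 6.98 * (1 - H) / Dp
    logit = A + B * np.log(((fq - X0) / (1 - 2 * X0))
                           / (1 - (fq - X0) / (1 - 2 * X0)))
    return 1 / (1 + np.exp(-logit))


class TestViscosity:
    @pytest.mark.parametrize("D,H", [(10, 0.0), (10, 0.45), (6, 0.45),
                                     (40, 0.45), (5, 0.2), (100, 0.6)])
    def test_matches_oracle(self, D, H):
        assert apparent_viscosity(D, H) == pytest.approx(
            oracle_viscosity(D, H), rel=1e-12)

    def test_plasma_limit(self):
        # H=0: only the surface-layer factor remains
        D = 10.0
        assert apparent_viscosity(D, 0.0) == pytest.approx(
            (D / (D - 1.1)) ** 2, rel=1e-12)

    def test_monotone_in_hematocrit(self):
        assert apparent_viscosity(10, 0.45) > apparent_viscosity(10, 0.20)

    def test_inverse_fahraeus_lindqvist_small_diameters(self):
        assert apparent_viscosity(6, 0.45) > apparent_viscosity(40, 0.45)

    def test_esl_cutoff_raises(self):
        with pytest.raises(RheologyError):
            apparent_viscosity(2.5, 0.4)


class TestPhaseSeparation:
    def test_symmetric_bifurcation(self):
        h1, h2 = phase_separation_split(0.4, 0.5, 10, 8, 8)
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert h1 == pytest.approx(0.4, rel=1e-9)

    def test_below_cutoff_no_rbcs(self):
        X0 = 0.964 * (1 - 0.4) / 10.0
        h1, _ = phase_separation_split(0.4, X0 * 0.9, 10, 8, 8)
        assert h1 == 0.0

    def test_matches_oracle_asymmetric(self):
        H, fq, Dp, D1, D2 = 0.4, 0.7, 10.0, 8.0, 8.0
        fqe = rbc_flux_fraction(H, fq, Dp, D1, D2)
        assert fqe == pytest.approx(oracle_rbc_fraction(H, fq, Dp, D1, D2),
                                    rel=1e-12)
        h1, h2 = phase_separation_split(H, fq, Dp, D1, D2)
        # conservation and higher hematocrit in the higher-flow daughter
        assert fq * h1 + (1 - fq) * h2 == pytest.approx(H, rel=1e-12)
        assert h1 > h2

    @pytest.mark.parametrize("H,fq,Dp,D1,D2", [
        (0.3, 0.35, 12, 10, 6), (0.55, 0.6, 8, 7, 5), (0.45, 0.81, 15, 9, 9),
    ])
    def test_rbc_conservation(self, H, fq, Dp, D1, D2):
        h1, h2 = phase_separation_split(H, fq, Dp, D1, D2)
        assert fq * h1 + (1 - fq) * h2 == pytest.approx(H, rel=1e-9)

    def test_fq_out_of_range(self):
        with pytest.raises(ValueError):
            phase_separation_split(0.4, 1.2, 10, 8, 8)


class TestFlowSolver:
    def test_single_tube_poiseuille(self, single_tube):
        settings = FlowSolverSettings()
        st = solve_flows(single_tube, np.array([10.0]), settings)
        D_cm, L_cm = 10 * UM_TO_CM, 500 * UM_TO_CM
        mu = apparent_viscosity(10.0, 0.45) * 0.01
        q = np.pi * D_cm ** 4 / (128 * mu * L_cm) * 10 * MMHG_TO_DYN_CM2
        assert st.flow[0] == pytest.approx(q * CM3S_TO_NLMIN, rel=1e-9)

    def test_symmetric_y_equal_split(self, y_net):
        st = solve_flows(y_net, np.array([10.0, 8.0, 8.0]),
                         FlowSolverSettings())
        assert st.flow[1] == pytest.approx(st.flow[2], rel=1e-9)
        assert st.hematocrit[1] == pytest.approx(st.hematocrit[2], abs=1e-12)

    def test_node_pressures_match_dense_solve(self, ladder_net):
        """Sparse node solve vs a dense direct solve at converged mu."""
        settings = FlowSolverSettings()
        D = np.array([s.diameter_current for s in ladder_net.segments])
        st = solve_flows(ladder_net, D, settings)
        nidx = ladder_net.node_index()
        nn = len(ladder_net.nodes)
        g = np.zeros(len(ladder_net.segments))
        for i, s in enumerate(ladder_net.segments):
            mu = apparent_viscosity(D[i], st.hematocrit[i]) * 0.01
            g[i] = np.pi * (D[i] * UM_TO_CM) ** 4 \
                / (128 * mu * s.length * UM_TO_CM)
        A = np.zeros((nn, nn))
        b = np.zeros(nn)
        bmask = np.array([n.boundary for n in ladder_net.nodes])
        for i, s in enumerate(ladder_net.segments):
            a_, b_ = nidx[s.from_node], nidx[s.to_node]
            A[a_, a_] += g[i]
            A[b_, b_] += g[i]
            A[a_, b_] -= g[i]
            A[b_, a_] -= g[i]
        for j, n in enumerate(ladder_net.nodes):
            if n.boundary:
                A[j, :] = 0.0
                A[j, j] = 1.0
                b[j] = n.boundary_pressure * MMHG_TO_DYN_CM2
        P = np.linalg.solve(A, b) / MMHG_TO_DYN_CM2
        assert np.max(np.abs(P - st.pressure_node)
                      / np.maximum(np.abs(P), 1e-12)) < 1e-10

    def test_mass_and_rbc_conservation(self, default_net):
        settings = FlowSolverSettings()
        D = np.array([s.diameter_control for s in default_net.segments])
        st = solve_flows(default_net, D, settings)
        _assert_conservation(default_net, st)

    def test_linearity_in_pressure_drop(self, ladder_net):
        settings = FlowSolverSettings(phase_separation_enabled=False)
        D = np.array([s.diameter_current for s in ladder_net.segments])
        st1 = solve_flows(ladder_net, D, settings)
        for n in ladder_net.boundary_nodes():
            n.boundary_pressure = 20.0 + 2.0 * (n.boundary_pressure - 20.0)
        st2 = solve_flows(ladder_net, D, settings)
        assert np.allclose(st2.flow, 2.0 * st1.flow, rtol=1e-9)

    def test_independent_of_initial_hematocrit(self, ladder_net):
        settings = FlowSolverSettings(tolerance=1e-10)
        D = np.array([s.diameter_current for s in ladder_net.segments])
        st1 = solve_flows(ladder_net, D, settings)
        warm = solve_flows(ladder_net, D * 1.2, settings)
        st2 = solve_flows(ladder_net, D, settings, warm_start=warm)
        assert np.allclose(st1.flow, st2.flow, rtol=1e-6)
        assert np.allclose(st1.hematocrit, st2.hematocrit, atol=1e-6)

    def test_phase_separation_aggregate_vs_local_effect(self, default_net):
        # unequal partition redistributes red cells: individual segment
        # flows shift substantially, while the aggregate inflow shifts
        # only modestly (local effects largely cancel in the total)
        D = np.array([s.diameter_control for s in default_net.segments])
        st_on = solve_flows(default_net, D,
                            FlowSolverSettings(phase_separation_enabled=True))
        st_off = solve_flows(default_net, D, FlowSolverSettings(
            phase_separation_enabled=False))
        qa, qb = st_on.total_inflow(default_net), \
            st_off.total_inflow(default_net)
        assert abs(qa - qb) / qb < 0.10
        rel = np.abs(st_on.flow - st_off.flow) \
            / np.maximum(np.abs(st_off.flow), 1e-9)
        assert np.percentile(rel, 90) > abs(qa - qb) / qb


class TestFlowingClassification:
    def test_strictly_above_threshold(self, single_tube):
        st = solve_flows(single_tube, np.array([10.0]), FlowSolverSettings())
        st.rbc_flux = np.array([12.6])
        assert classify_flowing(single_tube, st, 12.5)["flowing"][0]
        st.rbc_flux = np.array([12.5])
        assert not classify_flowing(single_tube, st, 12.5)["flowing"][0]

    def test_zero_flow_none_flowing(self, single_tube):
        for n in single_tube.boundary_nodes():
            n.boundary_pressure = 50.0
        st = solve_flows(single_tube, np.array([10.0]), FlowSolverSettings())
        out = classify_flowing(single_tube, st)
        assert not out["flowing"].any()


def _assert_conservation(net, st):
    nidx = net.node_index()
    imb = np.zeros(len(net.nodes))
    rbc = np.zeros(len(net.nodes))
    for i, s in enumerate(net.segments):
        imb[nidx[s.from_node]] -= st.flow[i]
        imb[nidx[s.to_node]] += st.flow[i]
        rbc[nidx[s.from_node]] -= st.flow[i] * st.hematocrit[i]
        rbc[nidx[s.to_node]] += st.flow[i] * st.hematocrit[i]
    inflow = abs(st.total_inflow(net))
    interior = [j for j, n in enumerate(net.nodes) if not n.boundary]
    assert np.abs(imb[interior]).max() <= 1e-9 * inflow
    assert np.abs(rbc[interior]).max() <= 1e-9 * inflow
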
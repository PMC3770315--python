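"""Green's-function oxygen transport: limits, balance, discretization."""

import numpy as np
import pytest

from microflowreg.hemodynamics import FlowSolverSettings, solve_flows
from microflowreg.network import NetworkGraph, Node, VesselSegment
from microflowreg.oxygen import (OxygenParameters, OxygenSolver,
                                 TissueDomain, consumption_rate,
                                 hill_saturation, tissue_statistics)


class TestHill:
    def test_half_saturation(self):
        assert hill_saturation(26.0) == pytest.approx(0.5, abs=1e-12)

    def test_zero(self):
        assert hill_saturation(0.0) == 0.0

    def test_arterial_value(self):
        expected = 1.0 / (1.0 + (26.0 / 100.0) ** 2.55)
        assert hill_saturation(100.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            hill_saturation(-1.0)


class TestConsumption:
    def test_michaelis_midpoint(self):
        assert consumption_rate(1.0, 2.0, 1.0) == pytest.approx(1.0)

    def test_zero_and_clamp(self):
        assert consumption_rate(0.0, 5.0) == 0.0
        assert consumption_rate(-3.0, 5.0) == 0.0

    def test_near_saturation(self):
        assert consumption_rate(99.0, 1.0, 1.0) == pytest.approx(0.99)


def _single_vessel(L=400.0, D=8.0):
    nodes = [Node("a", np.array([0.0, 0, 0]), True, 60.0, 0.45, 100.0),
             Node("b", np.array([L, 0, 0]), True, 40.0)]
    seg = VesselSegment("v", "a", "b", L, D, D, D, "capillary")
    return NetworkGraph([seg], nodes, {})


def _box_domain(L, half, h):
    xs = np.arange(h / 2, L, h)
    ys = np.arange(-half + h / 2, half, h)
    gx, gy, gz = np.meshgrid(xs, ys, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return TissueDomain(origin=np.array([0.0, -half, -half]),
                        shape=(len(xs), len(ys), len(ys)), spacing=h,
                        centers=centers, volume=h ** 3)


def test_zero_demand_tissue_equals_vessel_po2():
    net = _single_vessel()
    hemo = solve_flows(net, np.array([8.0]), FlowSolverSettings())
    solver = OxygenSolver(net, OxygenParameters(),
                          domain=_box_domain(400.0, 32.0, 16.0),
                          subsegment_um=25.0)
    sol = solver.solve(hemo, M0=0.0)
    # no consumption anywhere: the tissue sits at the (uniform) blood PO2
    assert np.allclose(sol.tissue_po2, sol.vessel_po2[0], atol=1e-6)
    assert sol.vessel_po2[0] == pytest.approx(100.0, abs=1e-6)


def test_two_parallel_vessels_mirror_symmetric_field():
    L, off = 400.0, 24.0
    nodes = [Node("a1", np.array([0.0, off, 0]), True, 60.0, 0.45, 100.0),
             Node("b1", np.array([L, off, 0]), True, 40.0),
             Node("a2", np.array([0.0, -off, 0]), True, 60.0, 0.45, 100.0),
             Node("b2", np.array([L, -off, 0]), True, 40.0)]
    segs = [VesselSegment("v1", "a1", "b1", L, 8.0, 8.0, 8.0, "capillary"),
            VesselSegment("v2", "a2", "b2", L, 8.0, 8.0, 8.0, "capillary")]
    net = NetworkGraph(segs, nodes, {})
    hemo = solve_flows(net, np.array([8.0, 8.0]), FlowSolverSettings())
    dom = _box_domain(L, 48.0, 12.0)
    solver = OxygenSolver(net, OxygenParameters(), domain=dom,
                          subsegment_um=25.0, max_outer=400)
    sol = solver.solve(hemo, M0=2.0)
    nx, ny, nz = dom.shape
    grid = sol.tissue_po2.reshape(nx, ny, nz)
    asym = np.abs(grid - grid[:, ::-1, :]).max()
    assert asym < 1e-6 * np.mean(sol.tissue_po2)


def test_krogh_cylinder_radial_shape():
    """Single vessel, near-zeroth-order consumption: the mid-plane tissue
    profile declines radially on the Krogh scale (the strict 5%
    comparison lives in the acceptance suite)."""
    L, D, half, h = 400.0, 8.0, 30.0, 8.0
    net = _single_vessel(L, D)
    hemo = solve_flows(net, np.array([D]), FlowSolverSettings())
    par = OxygenParameters(P0=0.05)
    solver = OxygenSolver(net, par, domain=_box_domain(L, half, h),
                          subsegment_um=20.0, max_outer=600)
    sol = solver.solve(hemo, M0=5.0)

    Dalpha = par.D_alpha
    M_cgs = 5.0 / 6000.0
    Req = (2 * half / np.sqrt(np.pi)) * 1e-4       # equivalent cylinder, cm
    rv = 0.5 * D * 1e-4
    x0 = L / 2
    iw = np.argmin(np.abs(solver.sub_mid[:, 0] - x0))
    p_wall = sol.vessel_po2[iw]
    angs = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    sims, kroghs = [], []
    for r_um in (8.0, 12.0, 15.0):
        r = r_um * 1e-4
        pts = np.column_stack([np.full(12, x0), r_um * np.cos(angs),
                               r_um * np.sin(angs)])
        sims.append(solver._field_at(pts, sol.source_strength,
                                     sol.sink_strength,
                                     solver._c_warm).mean())
        kroghs.append(p_wall - (M_cgs / (2 * Dalpha)) * (
            Req ** 2 * np.log(r / rv) - (r ** 2 - rv ** 2) / 2))
    sims, kroghs = np.array(sims), np.array(kroghs)
    assert np.all(np.diff(sims) < 0)            # declines radially
    assert np.allclose(sims, kroghs, rtol=0.5)  # on the Krogh scale


def test_global_oxygen_balance(default_net):
    net = default_net.copy()
    D = np.array([s.diameter_control for s in net.segments])
    for i, s in enumerate(net.segments):
        s.diameter_current = D[i]
    hemo = solve_flows(net, D, FlowSolverSettings())
    solver = OxygenSolver(net, OxygenParameters(), subsegment_um=50.0,
                          sink_spacing_um=60.0, padding_um=40.0,
                          max_outer=600)
    for M0 in (1.0, 4.0):
        sol = solver.solve(hemo, M0=M0)
        assert sol.balance_error() < 0.02


def test_median_po2_falls_with_demand(default_net):
    net = default_net.copy()
    D = np.array([s.diameter_control for s in net.segments])
    for i, s in enumerate(net.segments):
        s.diameter_current = D[i]
    hemo = solve_flows(net, D, FlowSolverSettings())
    solver = OxygenSolver(net, OxygenParameters(), subsegment_um=50.0,
                          sink_spacing_um=60.0, padding_um=40.0,
                          max_outer=600)
    medians = [tissue_statistics(solver.solve(hemo, M0=m))["median_po2"]
               for m in (1.0, 2.0, 4.0)]
    assert medians[0] > medians[1] > medians[2]


def test_mesh_refinement_stability(default_net):
    net = default_net.copy()
    D = np.array([s.diameter_control for s in net.segments])
    for i, s in enumerate(net.segments):
        s.diameter_current = D[i]
    hemo = solve_flows(net, D, FlowSolverSettings())
    med = {}
    for h in (50.0, 25.0):
        solver = OxygenSolver(net, OxygenParameters(), subsegment_um=50.0,
                              sink_spacing_um=h, padding_um=40.0,
                              max_outer=600)
        med[h] = tissue_statistics(solver.solve(hemo, M0=1.0))["median_po2"]
    assert abs(med[25.0] - med[50.0]) / med[50.0] < 0.03


def test_statistics_definitions():
    sol_like = type("S", (), {})()
    sol_like.tissue_po2 = np.array([0.5, 2.0, 3.0])
    st = tissue_statistics(sol_like)
    assert st["hypoxic_fraction"] == pytest.approx(1 / 3)
    assert st["median_po2"] == 2.0
    hist, edges = st["histogram"]
    assert hist.sum() == 3
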
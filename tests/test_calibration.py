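"""Reference-state construction: feed tuning and tone inversion."""

import numpy as np
import pytest

from microflowreg.calibration import (_arterial_side_node, calibrate,
                                      invert_reference_tone,
                                      tune_feed_segment)
from microflowreg.hemodynamics import FlowSolverSettings, solve_flows
from microflowreg.synth import GeneratorConfig, generate_network
from microflowreg.wall import stimulus_tone


@pytest.fixture(scope="module")
def tuned_net():
    net = generate_network(GeneratorConfig(seed=3))
    for s in net.segments:
        s.diameter_current = s.diameter_control
    fs = FlowSolverSettings()
    tune_feed_segment(net, fs, 66.0)
    return net, fs


def test_arterial_side_pressure_hits_target(tuned_net):
    net, fs = tuned_net
    st = solve_flows(net, np.array([s.diameter_current
                                    for s in net.segments]), fs)
    nidx = net.node_index()
    p = st.pressure_node[nidx[_arterial_side_node(net)]]
    assert p == pytest.approx(66.0, abs=0.05)


def test_feed_drain_drops_by_construction(tuned_net):
    net, fs = tuned_net
    st = solve_flows(net, np.array([s.diameter_current
                                    for s in net.segments]), fs)
    nidx = net.node_index()
    for s in net.segments:
        dp = abs(st.pressure_node[nidx[s.from_node]]
                 - st.pressure_node[nidx[s.to_node]])
        if s.vclass == "artery":
            assert dp == pytest.approx(10.0, rel=0.05)
        elif s.vclass == "large_venule":
            assert dp == pytest.approx(1.49, rel=0.05)
        elif s.vclass == "vein":
            assert dp == pytest.approx(1.0, rel=0.05)


def test_retuning_is_a_noop(tuned_net):
    net, fs = tuned_net
    la = next(s for s in net.segments if s.vclass == "large_arteriole")
    before = la.length
    tune_feed_segment(net, fs, 66.0)
    assert la.length == pytest.approx(before, rel=0.02)


def test_longer_la_lowers_arterial_pressure(tuned_net):
    net, fs = tuned_net
    net = net.copy()
    from microflowreg.calibration import _set_length
    la = next(s for s in net.segments if s.vclass == "large_arteriole")
    nidx = net.node_index()

    def p_art():
        st = solve_flows(net, np.array([s.diameter_current
                                        for s in net.segments]), fs)
        return st.pressure_node[nidx[_arterial_side_node(net)]]

    p1 = p_art()
    _set_length(net, la.id, la.length * 2.0)
    assert p_art() < p1


class TestToneInversion:
    @pytest.fixture(scope="class")
    def ref(self):
        net = generate_network(GeneratorConfig(seed=3))
        for s in net.segments:
            s.diameter_current = s.diameter_control
        fs = FlowSolverSettings()
        tune_feed_segment(net, fs, 66.0)
        ref = invert_reference_tone(net, fs, metabolic=False)
        return net, ref

    def test_stimulus_roundtrip(self, ref):
        """Re-evaluating the stimulus at the reference inputs returns
        S_tone_ref: the inversion is algebraically exact."""
        net, ref = ref
        sidx = net.segment_index()
        for k, sid in enumerate(ref.seg_ids):
            i = sidx[sid]
            S = stimulus_tone(ref.T_c[k], ref.hemo.wall_shear[i], 0.0,
                              ref.wall[k])
            assert S == pytest.approx(ref.S_tone_ref[k], abs=1e-10)

    def test_sigmoid_midpoint_inverse(self, ref):
        net, ref = ref
        mid = np.argmin(np.abs(ref.A_ref - 0.5))
        import math
        assert ref.S_tone_ref[mid] == pytest.approx(
            math.log(ref.A_ref[mid] / (1 - ref.A_ref[mid])), abs=1e-12)

    def test_passive_vessels_get_minimal_tone(self):
        net = generate_network(GeneratorConfig(seed=3))
        for s in net.segments:
            s.diameter_current = s.diameter_control
        # force one arteriole to the 'dilated not larger than control' case
        art = next(s for s in net.segments if s.vclass == "arteriole")
        art.diameter_dilated = art.diameter_control * 0.99
        fs = FlowSolverSettings()
        tune_feed_segment(net, fs, 66.0)
        ref = invert_reference_tone(net, fs, metabolic=False)
        k = ref.seg_ids.index(art.id)
        assert ref.S_tone_ref[k] == -1000.0
        assert ref.A_ref[k] == pytest.approx(0.0, abs=1e-12)

    def test_activation_in_unit_interval(self, ref):
        _, ref = ref
        assert np.all(ref.A_ref >= 0.0)
        assert np.all(ref.A_ref <= 1.0)


def test_capillary_adjustment_bounded():
    from microflowreg.calibration import adjust_capillary_diameters
    net = generate_network(GeneratorConfig(seed=3))
    for s in net.segments:
        s.diameter_current = s.diameter_control
    fs = FlowSolverSettings()
    tune_feed_segment(net, fs, 66.0)
    before = {s.id: s.diameter_control for s in net.segments
              if s.vclass == "capillary"}
    rep = adjust_capillary_diameters(net, fs)
    assert rep["mislabeled_after"] <= rep["mislabeled_before"]
    for s in net.segments:
        if s.vclass == "capillary":
            assert abs(s.diameter_control - before[s.id]) <= 1.2 + 1e-9
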
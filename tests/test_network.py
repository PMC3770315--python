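"""Network model, file I/O, validation, and vessel classification."""

import numpy as np
import pytest

from microflowreg.network import (NetworkFormatError, TopologyError,
                                  classify_vessels, load_network,
                                  save_network, validate_topology)
from microflowreg.synth import GeneratorConfig, generate_network

from conftest import make_y_network


def test_roundtrip_preserves_fields(tmp_path, default_net):
    path = tmp_path / "net.tsv"
    save_network(default_net, path)
    back = load_network(path)
    assert len(back.segments) == len(default_net.segments)
    for a, b in zip(default_net.segments, back.segments):
        assert a.id == b.id and a.vclass == b.vclass
        assert a.from_node == b.from_node and a.to_node == b.to_node
        assert a.length == pytest.approx(b.length, rel=1e-9)
        assert a.diameter_control == pytest.approx(b.diameter_control)
        assert a.diameter_dilated == pytest.approx(b.diameter_dilated)
    # boundary conditions survive
    bc_a = {n.id: (n.boundary_pressure, n.boundary_hematocrit, n.boundary_po2)
            for n in default_net.boundary_nodes()}
    bc_b = {n.id: (n.boundary_pressure, n.boundary_hematocrit, n.boundary_po2)
            for n in back.boundary_nodes()}
    assert bc_a == bc_b


def test_roundtrip_preserves_extra_columns(tmp_path, default_net):
    path = tmp_path / "net.tsv"
    save_network(default_net, path)
    back = load_network(path)
    key = "intended_flowing_control"
    assert back.metadata["extra_columns"][key] == \
        default_net.metadata["extra_columns"][key]


def test_load_y_fixture(tmp_path, y_net):
    path = tmp_path / "y.tsv"
    save_network(y_net, path)
    net = load_network(path)
    assert len(net.segments) == 3
    assert len(net.nodes) == 4


def test_missing_column_named_in_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("#format=microflowreg-net-1\n"
                    "segid\tfrom\tto\tlength_um\n"
                    "s1\tn1\tn2\t100\n")
    with pytest.raises(NetworkFormatError, match="diam_control_um"):
        load_network(path)


def test_dangling_node_reported(y_net):
    y_net.segments[1].to_node = "n99"
    with pytest.raises(TopologyError, match="n99"):
        y_net.validate()


def test_refuse_empty_network(tmp_path):
    from microflowreg.network import NetworkGraph
    with pytest.raises(NetworkFormatError):
        save_network(NetworkGraph([], [], {}), tmp_path / "e.tsv")


def test_centerline_arc_consistency_enforced(y_net):
    y_net.segments[0].centerline = np.array([[0.0, 0, 0], [500.0, 0, 0]])
    with pytest.raises(NetworkFormatError, match="arc length"):
        y_net.validate()


def test_topology_report_y(y_net):
    rep = validate_topology(y_net)
    assert rep.connected
    assert len(rep.inflow_nodes) == 0 or len(rep.inflow_nodes) == 1
    assert "connected: yes" in rep.summary()


def test_topology_report_disconnected():
    net = make_y_network()
    extra = make_y_network()
    for n in extra.nodes:
        n.id = "x" + n.id
    for s in extra.segments:
        s.id = "x" + s.id
        s.from_node = "x" + s.from_node
        s.to_node = "x" + s.to_node
    net.segments += extra.segments
    net.nodes += extra.nodes
    rep = validate_topology(net)
    assert not rep.connected
    assert rep.n_components == 2


def test_duplicate_segment_ids_flagged(y_net):
    y_net.segments[2].id = y_net.segments[1].id
    rep = validate_topology(y_net)
    assert rep.duplicate_segment_ids
    sid, idxs = rep.duplicate_segment_ids[0]
    assert len(idxs) == 2


class TestClassification:
    def test_diverging_parent_at_threshold_is_arteriole(self):
        net = make_y_network(d_parent=8.0)
        cls = classify_vessels(net, apply=False)
        assert cls.vclass["par"] == "arteriole"

    def test_below_threshold_is_capillary(self):
        net = make_y_network(d_parent=7.9)
        cls = classify_vessels(net, apply=False)
        assert cls.vclass["par"] == "capillary"

    def test_passthrough_segment_is_capillary(self):
        # a wide but unbranched segment: not a diverging-bifurcation parent
        from conftest import _seg
        from microflowreg.network import NetworkGraph, Node
        nodes = [
            Node("a", np.array([0.0, 0, 0]), True, 60.0, 0.4, 100.0),
            Node("m", np.array([200.0, 0, 0])),
            Node("b", np.array([400.0, 0, 0]), True, 20.0),
        ]
        segs = [_seg("s1", "a", "m", 200.0, 12.0),
                _seg("s2", "m", "b", 200.0, 12.0)]
        net = NetworkGraph(segs, nodes, {})
        cls = classify_vessels(net, apply=False)
        assert cls.vclass["s1"] == "capillary"
        assert cls.vclass["s2"] == "capillary"

    def test_idempotent_and_order_independent(self, default_cfg):
        net = generate_network(default_cfg)
        first = classify_vessels(net, apply=True)
        second = classify_vessels(net, apply=False)
        assert first.vclass == second.vclass
        shuffled = net.copy()
        order = np.random.default_rng(3).permutation(len(shuffled.segments))
        shuffled.segments = [shuffled.segments[i] for i in order]
        third = classify_vessels(shuffled, apply=False)
        assert third.vclass == first.vclass

    def test_matches_generator_labels(self, default_net):
        cls = classify_vessels(default_net.copy(), apply=False)
        gen_art = {s.id for s in default_net.segments
                   if s.vclass == "arteriole"}
        cls_art = {k for k, v in cls.vclass.items() if v == "arteriole"}
        assert gen_art == cls_art
        assert len(cls.terminal_arterioles) == \
            GeneratorConfig().n_terminal_arterioles
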
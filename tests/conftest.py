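"""Shared fixtures: small analytic networks and a default synthetic net."""

import numpy as np
import pytest

from microflowreg.network import NetworkGraph, Node, VesselSegment
from microflowreg.synth import GeneratorConfig, generate_network


def _seg(sid, a, b, L, d, vclass="capillary"):
    return VesselSegment(id=sid, from_node=a, to_node=b, length=L,
                         diameter_control=d, diameter_dilated=d,
                         diameter_current=d, vclass=vclass)


def make_y_network(d_parent=10.0, d1=8.0, d2=8.0, L=200.0,
                   p_in=60.0, p_out=20.0):
    """Diverging Y: one parent, two daughters, three boundary nodes."""
    nodes = [
        Node("in", np.array([0.0, 0.0, 0.0]), True, p_in, 0.45, 100.0),
        Node("j", np.array([L, 0.0, 0.0])),
        Node("o1", np.array([2 * L, L, 0.0]), True, p_out),
        Node("o2", np.array([2 * L, -L, 0.0]), True, p_out),
    ]
    segs = [
        _seg("par", "in", "j", L, d_parent),
        _seg("d1", "j", "o1", np.hypot(L, L) * 1.02, d1),
        _seg("d2", "j", "o2", np.hypot(L, L) * 1.02, d2),
    ]
    return NetworkGraph(segs, nodes, {})


def make_single_tube(D=10.0, L=500.0, p_in=60.0, p_out=50.0, H=0.45):
    nodes = [
        Node("a", np.array([0.0, 0.0, 0.0]), True, p_in, H, 100.0),
        Node("b", np.array([L, 0.0, 0.0]), True, p_out),
    ]
    return NetworkGraph([_seg("t", "a", "b", L, D)], nodes, {})


def make_ladder(n=4, D=8.0, L=150.0, p_in=60.0, p_out=20.0):
    """Two parallel rails with rungs: a small meshy fixture (3n segments)."""
    nodes = [Node("in", np.array([0.0, 0.0, 0.0]), True, p_in, 0.45, 100.0)]
    segs = []
    prev_a, prev_b = "in", "in"
    for k in range(n):
        a, b = f"a{k}", f"b{k}"
        nodes.append(Node(a, np.array([(k + 1) * L, 50.0, 0.0])))
        nodes.append(Node(b, np.array([(k + 1) * L, -50.0, 0.0])))
        La = L * 1.15 if prev_a == "in" else L
        segs.append(_seg(f"ra{k}", prev_a, a, La, D))
        segs.append(_seg(f"rb{k}", prev_b, b, La, D * 0.9))
        segs.append(_seg(f"rung{k}", a, b, 101.0, D * 0.7))
        prev_a, prev_b = a, b
    nodes.append(Node("out", np.array([(n + 1) * L, 0.0, 0.0]),
                      True, p_out))
    segs.append(_seg("oa", prev_a, "out", L * 1.15, D))
    segs.append(_seg("ob", prev_b, "out", L * 1.15, D))
    return NetworkGraph(segs, nodes, {})


@pytest.fixture
def y_net():
    return make_y_network()


@pytest.fixture
def single_tube():
    return make_single_tube()


@pytest.fixture
def ladder_net():
    return make_ladder()


@pytest.fixture(scope="session")
def default_net():
    """The default cremaster-like synthetic network, seed 1."""
    return generate_network(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig(seed=1)
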
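"""Network data model, file I/O, topology validation, and vessel classification.

A microvessel network is a collection of cylindrical segments joined at
nodes.  Each segment carries two anatomical diameters: the diameter
observed in a control (toned) state and the diameter in a maximally
dilated (passive) state.  The current diameter is the dynamic variable
modulated by vascular smooth muscle in regulating segments (arterioles
and the large feeding arteriole).

File format (tab separated, UTF-8, first line ``#format=microflowreg-net-1``)::

    segid  from  to  length_um  diam_control_um  diam_dilated_um  vclass  x0 y0 z0 x1 y1 z1

Boundary conditions live in a companion ``<name>.bc.tsv`` with columns
``node kind value_mmHg hematocrit po2_mmHg``; multi-point centerlines in
an optional ``<name>.path.tsv`` (``segid point_index x y z``).
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORMAT_TAG = "#format=microflowreg-net-1"

VESSEL_CLASSES = (
    "artery",
    "large_arteriole",
    "arteriole",
    "capillary",
    "venule",
    "large_venule",
    "vein",
    "virtual",
)

#: classes whose diameter is actively controlled by VSM tone
REGULATING_CLASSES = ("arteriole", "large_arteriole")

#: classes that exchange oxygen with the discretized tissue domain
EXCHANGING_CLASSES = ("arteriole", "capillary", "venule")

SEGMENT_COLUMNS = [
    "segid", "from", "to", "length_um", "diam_control_um", "diam_dilated_um",
    "vclass", "x0", "y0", "z0", "x1", "y1", "z1",
]


class NetworkFormatError(ValueError):
    """Raised for malformed network files."""


class TopologyError(ValueError):
    """Raised when segment/node references are inconsistent."""


@dataclass
class VesselSegment:
    id: str
    from_node: str
    to_node: str
    length: float                  # um
    diameter_control: float        # um
    diameter_dilated: float        # um
    diameter_current: float        # um
    vclass: str = "capillary"
    centerline: np.ndarray | None = None   # (k, 3) um, endpoints included
    sleeve_width: float | None = None      # um; fixed-consumption sleeve (A/LA)

    @property
    def regulating(self) -> bool:
        return self.vclass in REGULATING_CLASSES

    @property
    def exchanges_oxygen(self) -> bool:
        return self.vclass in EXCHANGING_CLASSES

    def arc_length(self) -> float:
        if self.centerline is None or len(self.centerline) < 2:
            return self.length
        d = np.diff(np.asarray(self.centerline, dtype=float), axis=0)
        return float(np.sqrt((d ** 2).sum(axis=1)).sum())


@dataclass
class Node:
    id: str
    position: np.ndarray           # (3,) um
    boundary: bool = False
    boundary_pressure: float | None = None    # mmHg
    boundary_hematocrit: float | None = None  # dimensionless
    boundary_po2: float | None = None         # mmHg


@dataclass
class NetworkGraph:
    segments: list[VesselSegment] = field(default_factory=list)
    nodes: list[Node] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # ---- lookup helpers -------------------------------------------------
    def node_index(self) -> dict[str, int]:
        return {n.id: i for i, n in enumerate(self.nodes)}

    def segment_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.segments)}

    def segment(self, segid: str) -> VesselSegment:
        return self.segments[self.segment_index()[segid]]

    def node(self, nid: str) -> Node:
        return self.nodes[self.node_index()[nid]]

    def boundary_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.boundary]

    def adjacency(self) -> dict[str, list[int]]:
        """node id -> list of indices of incident segments."""
        adj: dict[str, list[int]] = {n.id: [] for n in self.nodes}
        for i, s in enumerate(self.segments):
            adj[s.from_node].append(i)
            adj[s.to_node].append(i)
        return adj

    def copy(self) -> "NetworkGraph":
        segs = [VesselSegment(s.id, s.from_node, s.to_node, s.length,
                              s.diameter_control, s.diameter_dilated,
                              s.diameter_current, s.vclass,
                              None if s.centerline is None else np.array(s.centerline),
                              s.sleeve_width)
                for s in self.segments]
        nodes = [Node(n.id, np.array(n.position), n.boundary, n.boundary_pressure,
                      n.boundary_hematocrit, n.boundary_po2)
                 for n in self.nodes]
        return NetworkGraph(segs, nodes, dict(self.metadata))

    def validate(self) -> None:
        """Raise on violated structural invariants."""
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TopologyError(f"duplicate segment ids: {dup}")
        known = {n.id for n in self.nodes}
        dangling = [s.id for s in self.segments
                    if s.from_node not in known or s.to_node not in known]
        if dangling:
            missing = sorted({e for s in self.segments
                              for e in (s.from_node, s.to_node) if e not in known})
            raise TopologyError(
                f"segments {dangling} reference undeclared nodes {missing}")
        for s in self.segments:
            if s.length <= 0:
                raise NetworkFormatError(f"segment {s.id}: non-positive length")
            if s.vclass != "virtual":
                if s.diameter_control <= 0 or s.diameter_dilated <= 0:
                    raise NetworkFormatError(f"segment {s.id}: non-positive diameter")
            if s.centerline is not None and len(s.centerline) >= 2:
                arc = s.arc_length()
                if abs(arc - s.length) > 0.01 * s.length + 1e-9:
                    raise NetworkFormatError(
                        f"segment {s.id}: centerline arc length {arc:.3f} "
                        f"inconsistent with length {s.length:.3f}")
        for n in self.nodes:
            if n.boundary and n.boundary_pressure is None:
                raise NetworkFormatError(f"boundary node {n.id} lacks a pressure")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_network(net: NetworkGraph, path: str | os.PathLike) -> None:
    """Write a network (and its boundary/centerline companions) to TSV."""
    if not net.segments:
        raise NetworkFormatError("refusing to write a network with no segments")
    net.validate()
    path = os.fspath(path)
    nidx = net.node_index()
    rows = []
    for s in net.segments:
        p0 = net.nodes[nidx[s.from_node]].position
        p1 = net.nodes[nidx[s.to_node]].position
        rows.append([s.id, s.from_node, s.to_node, s.length,
                     s.diameter_control, s.diameter_dilated, s.vclass,
                     *np.asarray(p0, float), *np.asarray(p1, float)])
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS[:7] + SEGMENT_COLUMNS[7:])
    extra = net.metadata.get("extra_columns", {})
    for col, per_seg in extra.items():
        df[col] = [per_seg.get(s.id, "") for s in net.segments]
    buf = io.StringIO()
    buf.write(FORMAT_TAG + "\n")
    for k, v in net.metadata.items():
        if k == "extra_columns":
            continue
        buf.write(f"#meta {k}={v}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())

    bc_rows = []
    for n in net.boundary_nodes():
        bc_rows.append([n.id, "pressure", n.boundary_pressure,
                        "" if n.boundary_hematocrit is None else n.boundary_hematocrit,
                        "" if n.boundary_po2 is None else n.boundary_po2])
    if bc_rows:
        bc = pd.DataFrame(bc_rows,
                          columns=["node", "kind", "value_mmHg", "hematocrit", "po2_mmHg"])
        with open(_companion(path, ".bc.tsv"), "w", encoding="utf-8") as fh:
            fh.write(FORMAT_TAG + "\n")
            bc.to_csv(fh, sep="\t", index=False)

    path_rows = []
    for s in net.segments:
        if s.centerline is not None and len(s.centerline) > 2:
            for j, pt in enumerate(np.asarray(s.centerline, float)):
                path_rows.append([s.id, j, *pt])
    if path_rows:
        pf = pd.DataFrame(path_rows, columns=["segid", "point_index", "x", "y", "z"])
        with open(_companion(path, ".path.tsv"), "w", encoding="utf-8") as fh:
            fh.write(FORMAT_TAG + "\n")
            pf.to_csv(fh, sep="\t", index=False)


def load_network(path: str | os.PathLike) -> NetworkGraph:
    """Read a network file written by :func:`save_network`."""
    path = os.fspath(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != FORMAT_TAG:
            raise NetworkFormatError(
                f"{path}: missing format tag {FORMAT_TAG!r} on first line")
        meta: dict = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#meta "):
                fh.seek(pos)
                break
            key, _, val = line[len("#meta "):].strip().partition("=")
            meta[key] = _coerce(val)
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", dtype={"segid": str, "from": str, "to": str})
    required = set(SEGMENT_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise NetworkFormatError(
            f"{path}: missing required column(s) {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in required]

    node_pos: dict[str, np.ndarray] = {}
    segments = []
    for _, r in df.iterrows():
        node_pos.setdefault(str(r["from"]), np.array([r.x0, r.y0, r.z0], float))
        node_pos.setdefault(str(r["to"]), np.array([r.x1, r.y1, r.z1], float))
        segments.append(VesselSegment(
            id=str(r["segid"]), from_node=str(r["from"]), to_node=str(r["to"]),
            length=float(r["length_um"]),
            diameter_control=float(r["diam_control_um"]),
            diameter_dilated=float(r["diam_dilated_um"]),
            diameter_current=float(r["diam_control_um"]),
            vclass=str(r["vclass"])))
    nodes = [Node(nid, p) for nid, p in node_pos.items()]
    net = NetworkGraph(segments, nodes, meta)
    if extra_cols:
        net.metadata["extra_columns"] = {
            c: {str(r["segid"]): _coerce(str(r[c]))
                for _, r in df.iterrows()
                if str(r[c]) not in ("", "nan")}
            for c in extra_cols}

    bc_path = _companion(path, ".bc.tsv")
    if os.path.exists(bc_path):
        bc = pd.read_csv(bc_path, sep="\t", comment="#", dtype={"node": str})
        nidx = net.node_index()
        for _, r in bc.iterrows():
            nid = str(r["node"])
            if nid not in nidx:
                raise TopologyError(f"{bc_path}: boundary node {nid} not in network")
            n = net.nodes[nidx[nid]]
            n.boundary = True
            n.boundary_pressure = float(r["value_mmHg"])
            if not pd.isna(r.get("hematocrit")):
                n.boundary_hematocrit = float(r["hematocrit"])
            if not pd.isna(r.get("po2_mmHg")):
                n.boundary_po2 = float(r["po2_mmHg"])

    pp = _companion(path, ".path.tsv")
    if os.path.exists(pp):
        pf = pd.read_csv(pp, sep="\t", comment="#", dtype={"segid": str})
        sidx = net.segment_index()
        for segid, grp in pf.groupby("segid"):
            grp = grp.sort_values("point_index")
            net.segments[sidx[str(segid)]].centerline = grp[["x", "y", "z"]].to_numpy(float)

    net.validate()
    return net


def _companion(path: str, suffix: str) -> str:
    base = path[:-4] if path.endswith(".tsv") else path
    return base + suffix


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


# ---------------------------------------------------------------------------
# topology diagnostics
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    connected: bool
    n_components: int
    components: list[set[str]]
    inflow_nodes: list[str]
    outflow_nodes: list[str]
    high_degree_nodes: list[str]       # degree > 3
    zero_length_segments: list[str]
    duplicate_segment_ids: list[tuple[str, list[int]]]

    def summary(self) -> str:
        return (f"connected: {'yes' if self.connected else 'no'}; "
                f"inflows: {len(self.inflow_nodes)}; "
                f"outflows: {len(self.outflow_nodes)}")


def validate_topology(net: NetworkGraph) -> TopologyReport:
    """Report-only structural diagnostics (never raises)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(n.id for n in net.nodes)
    for s in net.segments:
        g.add_edge(s.from_node, s.to_node)
    comps = [set(c) for c in nx.connected_components(g)] if len(g) else []

    inflow, outflow = [], []
    for n in net.boundary_nodes():
        # highest-pressure boundary node(s) feed the network
        if n.boundary_pressure is not None and n.boundary_pressure >= 90:
            inflow.append(n.id)
        else:
            outflow.append(n.id)
    adj = net.adjacency()
    high = [nid for nid, inc in adj.items() if len(inc) > 3]
    zero = [s.id for s in net.segments if s.length <= 0]
    ids = [s.id for s in net.segments]
    dups = [(sid, [i for i, x in enumerate(ids) if x == sid])
            for sid in sorted({i for i in ids if ids.count(i) > 1})]
    return TopologyReport(
        connected=len(comps) == 1, n_components=len(comps), components=comps,
        inflow_nodes=inflow, outflow_nodes=outflow, high_degree_nodes=high,
        zero_length_segments=zero, duplicate_segment_ids=dups)


# ---------------------------------------------------------------------------
# vessel classification
# ---------------------------------------------------------------------------

ARTERIOLE_DILATED_MIN_UM = 8.0


@dataclass
class Classification:
    vclass: dict[str, str]            # segid -> label
    terminal_arterioles: list[str]    # arterioles feeding no further arterioles


def classify_vessels(net: NetworkGraph, *, apply: bool = True) -> Classification:
    """Label microvessels as arteriole or capillary from the branching pattern.

    A microvessel is an arteriole iff it is the parent vessel at a
    diverging bifurcation (flow-oriented from the arterial inflow on the
    all-dilated passive flow solution) and its dilated diameter is at
    least 8 um.  Everything else that is not a pre-assigned venule or
    feed/drain vessel is a capillary.  Terminal arterioles are arterioles
    whose downstream tree contains no further arterioles.
    """
    from .hemodynamics import FlowSolverSettings, solve_flows

    for s in net.segments:
        if s.vclass in ("arteriole", "capillary") and s.diameter_dilated <= 0:
            raise NetworkFormatError(
                f"segment {s.id}: dilated diameter required for classification")

    dilated = np.array([s.diameter_dilated for s in net.segments])
    settings = FlowSolverSettings(phase_separation_enabled=False)
    state = solve_flows(net, dilated, settings)

    # orient each segment by flow sign; build downstream maps
    sidx = net.segment_index()
    up_node, down_node = {}, {}
    for i, s in enumerate(net.segments):
        if state.flow[i] >= 0:
            up_node[s.id], down_node[s.id] = s.from_node, s.to_node
        else:
            up_node[s.id], down_node[s.id] = s.to_node, s.from_node

    # outgoing segments at each node (in flow orientation)
    out_at: dict[str, list[str]] = {n.id: [] for n in net.nodes}
    for s in net.segments:
        out_at[up_node[s.id]].append(s.id)

    labels: dict[str, str] = {}
    micro = [s for s in net.segments if s.vclass in ("arteriole", "capillary")]
    for s in micro:
        kids = out_at[down_node[s.id]]
        n_flowing_kids = sum(1 for k in kids if abs(state.flow[sidx[k]]) > 0)
        diverging_parent = n_flowing_kids >= 2
        if diverging_parent and s.diameter_dilated >= ARTERIOLE_DILATED_MIN_UM:
            labels[s.id] = "arteriole"
        else:
            labels[s.id] = "capillary"

    # terminal arterioles: downstream tree (following flow) holds no arteriole
    arterioles = {sid for sid, lab in labels.items() if lab == "arteriole"}
    terminal = []
    for sid in sorted(arterioles):
        stack = list(out_at[down_node[sid]])
        seen = set()
        found = False
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            if k in arterioles:
                found = True
                break
            stack.extend(out_at[down_node[k]])
        if not found:
            terminal.append(sid)

    if apply:
        for s in micro:
            s.vclass = labels[s.id]
        net.metadata["terminal_arterioles"] = ",".join(terminal)
    return Classification(vclass=labels, terminal_arterioles=terminal)
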
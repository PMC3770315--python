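"""Wall-derived metabolic signal and its upstream conduction.

Each oxygen-exchanging vessel generates a local signal proportional to
the oxygen deficit 1 - M(P_wall)/M0 = P0/(P_wall + P0), expressed as a
density (uM per unit length).  The signal is conducted upstream against
the blood flow with exponential decay over a characteristic length L0;
where one downstream vessel feeds several upstream parents (a converging
blood-flow node) the conducted signal is partitioned in proportion to
parent diameters, and where several downstream daughters meet one parent
(a diverging blood-flow node) their signals are summed.  Virtual
segments appended beyond the network outflows supply a boundary signal
derived from venular PO2.  The total metabolic signal per segment,
S_meta (uM*cm), is the conducted input plus the locally generated
contribution and is what enters the vascular tone stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hemodynamics import HemodynamicState
from .network import NetworkGraph
from .oxygen import OxygenSolution

UM_CM = 1e-4


@dataclass
class SignalSettings:
    length_constant: float = 1.0       # L0, cm
    #: k_sig, uM per (cm^3 O2/100cm^3/min) of oxygen deficit.  The
    #: absolute scale of the conducted signal is a model convention; this
    #: value keeps the calibrated per-vessel tone constants C''_tone
    #: within the range reported for the antecedent vasoregulation models
    #: and the reference state dynamically stable, while the demand
    #: response is carried mostly by the deficit's proportionality to M0
    signal_scale: float = 0.02
    P0: float = 1.0                    # mmHg, half-maximal signal PO2
    virtual_length: float = 0.1        # cm, distal virtual segments
    virtual_po2: float | None = None   # default: venular inflow PO2 (20)
    #: anatomical conduction length for the lumped feed vessels (A, LA),
    #: whose hydraulic lengths are tuned resistances, not real distances
    feed_conduction_length: float = 0.15   # cm


@dataclass
class SignalField:
    S_loc: np.ndarray      # per segment, uM*cm (integrated local signal)
    S_meta: np.ndarray     # per segment, uM*cm (conducted + local)
    length_constant: float


def local_signal(net: NetworkGraph, oxygen: OxygenSolution,
                 M0: float = 1.0,
                 settings: SignalSettings | None = None) -> np.ndarray:
    """Local signal density per segment, uM (before length integration).

    The density is proportional to the local oxygen deficit, the
    difference between demand and consumption at the wall PO2:
    k_sig * (M0 - M(P_wall)) = k_sig * M0 * P0 / (P_wall + P0), with M0
    in cm^3 O2/100cm^3/min.  It grows with demand, vanishes for
    well-oxygenated walls at low demand, and saturates at k_sig*M0 as
    the wall PO2 approaches zero.  Non-exchanging segments generate
    nothing.
    """
    settings = settings or SignalSettings()
    dens = np.zeros(len(net.segments))
    for i, s in enumerate(net.segments):
        if not s.exchanges_oxygen:
            continue
        pw = oxygen.segment_wall_po2[i]
        if np.isnan(pw):
            continue
        dens[i] = (settings.signal_scale * M0 * settings.P0
                   / (max(pw, 0.0) + settings.P0))
    return dens


def propagate_signals(net: NetworkGraph, hemo: HemodynamicState,
                      S_loc_density: np.ndarray,
                      settings: SignalSettings | None = None,
                      M0: float = 1.0) -> SignalField:
    """Conduct wall-derived signals upstream through the flow-ordered net.

    The per-segment output is the signal arriving at the segment's
    upstream end: the downstream input attenuated over the segment
    length plus the within-segment generation integrated with decay,
    S_own = rho * L0 * (1 - exp(-L/L0)).
    """
    settings = settings or SignalSettings()
    L0 = settings.length_constant
    ns = len(net.segments)
    nidx = net.node_index()
    nn = len(net.nodes)

    # flow orientation; stagnant segments treated as oriented from->to
    up = np.empty(ns, dtype=int)
    down = np.empty(ns, dtype=int)
    for i, s in enumerate(net.segments):
        if hemo.flow[i] >= 0:
            up[i], down[i] = nidx[s.from_node], nidx[s.to_node]
        else:
            up[i], down[i] = nidx[s.to_node], nidx[s.from_node]
    down_segs = [[] for _ in range(nn)]   # segments leaving node downstream
    up_segs = [[] for _ in range(nn)]     # segments arriving at node
    for i in range(ns):
        down_segs[up[i]].append(i)
        up_segs[down[i]].append(i)

    L_cm = np.array([s.length for s in net.segments]) * UM_CM
    # feed vessels: conduction over their anatomical extent only
    lumped = np.array([s.sleeve_width is not None for s in net.segments])
    L_eff = np.where(lumped,
                     np.minimum(L_cm, settings.feed_conduction_length), L_cm)
    att = np.exp(-L_eff / L0)
    S_own = S_loc_density * L0 * (1.0 - att)

    vp = settings.virtual_po2 if settings.virtual_po2 is not None else 20.0
    dens_virtual = (settings.signal_scale * M0 * settings.P0
                    / (vp + settings.P0))
    S_virtual = dens_virtual * L0 * (1.0 - np.exp(-settings.virtual_length
                                                  / L0))

    # sweep nodes in ascending pressure (most distal first); the signal
    # at a node is the sum over its downstream segments' upstream-end
    # outputs, then split among the upstream parents by diameter
    D = np.array([s.diameter_current for s in net.segments])
    S_at_upstream_end = np.zeros(ns)
    node_signal = np.zeros(nn)
    order = np.argsort(hemo.pressure_node)
    for j in order:
        outs = down_segs[j]               # downstream continuations
        if outs:
            node_signal[j] = sum(S_at_upstream_end[i] for i in outs)
        else:
            node_signal[j] = S_virtual    # network outflow
        parents = up_segs[j]
        if not parents:
            continue
        if len(parents) == 1:
            shares = [1.0]
        else:
            dtot = sum(D[i] for i in parents)
            shares = [D[i] / dtot for i in parents]
        for i, w in zip(parents, shares):
            S_at_upstream_end[i] = node_signal[j] * w * att[i] + S_own[i]

    return SignalField(S_loc=S_own, S_meta=S_at_upstream_end,
                       length_constant=L0)


def compute_signals(net: NetworkGraph, hemo: HemodynamicState,
                    oxygen: OxygenSolution,
                    settings: SignalSettings | None = None,
                    M0: float = 1.0) -> SignalField:
    """Local generation followed by upstream conduction."""
    settings = settings or SignalSettings()
    dens = local_signal(net, oxygen, M0, settings)
    return propagate_signals(net, hemo, dens, settings, M0)
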
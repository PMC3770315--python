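"""Seeded generator of cremaster-like microvessel networks.

The experimental hamster cremaster map the analysis assumes is not
publicly available, so this module generates networks with the same
statistical structure: an arteriolar tree (default 32 segments, 6 of them
terminal arterioles), capillary chains (default 93 segments, about 15 per
terminal arteriole) that merge pairwise and drain into two venular
collecting chains (default 12 venule segments), completed by feed and
drain vessels A, LA, LV1, LV2, V1, V2 forming a single pathway through
the circulation.  A configurable fraction of vessels is intended to be
nonflowing in the control (toned) state and flowing only when arterioles
are dilated, which is what gives the network its capacity for capillary
recruitment.

Topology is built so that no node has degree above 3: arteriolar
bifurcations and side branches are binary, capillary ends merge pairwise,
and each venule junction accepts a single capillary trunk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkGraph, Node, VesselSegment


class GenerationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_arterioles: int = 32
    n_terminal_arterioles: int = 6
    n_capillaries: int = 93
    n_venules: int = 12
    arteriole_dilated_diam_range: tuple[float, float] = (8.0, 20.0)
    capillary_diam_range: tuple[float, float] = (4.0, 7.0)
    tone_fraction_range: tuple[float, float] = (0.55, 1.0)
    frac_dilated_only: float = 0.2
    slab: tuple[float, float, float] = (1000.0, 800.0, 50.0)
    arteriole_length_range: tuple[float, float] = (50.0, 300.0)
    capillary_length_range: tuple[float, float] = (100.0, 400.0)
    venule_length_range: tuple[float, float] = (50.0, 200.0)
    venule_diam_range: tuple[float, float] = (8.0, 15.0)
    crosslink_probability: float = 0.1
    seed: int = 1

    def validate(self) -> None:
        if min(self.n_arterioles, self.n_terminal_arterioles,
               self.n_capillaries, self.n_venules) <= 0:
            raise GenerationError("all vessel counts must be positive")
        if self.n_terminal_arterioles > self.n_arterioles:
            raise GenerationError("more terminal arterioles than arterioles")
        if self.n_arterioles < 2 * self.n_terminal_arterioles - 1:
            raise GenerationError(
                "arteriole count cannot host the requested number of terminals")
        if self.n_venules % 2:
            raise GenerationError("venule count must be even (two collecting chains)")
        for r in (self.arteriole_dilated_diam_range, self.capillary_diam_range,
                  self.tone_fraction_range):
            if r[0] > r[1]:
                raise GenerationError(f"range {r} not ordered")


def generate_network(cfg: GeneratorConfig) -> NetworkGraph:
    """Build one network; deterministic for a fixed config and seed.

    Rebuilds with a derived sub-seed in the rare case where capillary
    arcades reverse flow at an arteriolar side branch, which would make
    the branching-pattern classification disagree with the generated
    labels.
    """
    from .network import classify_vessels

    cfg.validate()
    last_err = None
    for attempt in range(20):
        rng = np.random.default_rng([cfg.seed, attempt])
        b = _Builder(cfg, rng)
        try:
            b.build()
            b.wire_side_chains()
            net = b.finish()
            net.validate()
            cls = classify_vessels(net.copy(), apply=False)
            gen_art = {s.id for s in net.segments if s.vclass == "arteriole"}
            cls_art = {k for k, v in cls.vclass.items() if v == "arteriole"}
            if gen_art != cls_art:
                raise GenerationError(
                    f"classification disagreed on {sorted(gen_art ^ cls_art)}")
        except GenerationError as err:
            last_err = err
            continue
        net.metadata["generator_attempt"] = attempt
        return net
    raise GenerationError(
        f"no self-consistent network after 20 attempts (seed {cfg.seed}): {last_err}")


def generate_ensemble(cfg: GeneratorConfig, n: int, base_seed: int
                      ) -> list[NetworkGraph]:
    if n < 1:
        raise GenerationError("ensemble size must be >= 1")
    nets = []
    for k in range(n):
        c = GeneratorConfig(**{**cfg.__dict__, "seed": base_seed + k})
        nets.append(generate_network(c))
    return nets


# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.nodes: dict[str, np.ndarray] = {}
        self.segs: list[dict] = []
        self._nid = 0
        self._sid = 0

    # -- low-level helpers -------------------------------------------------
    def new_node(self, pos) -> str:
        nid = f"n{self._nid:03d}"
        self._nid += 1
        self.nodes[nid] = np.asarray(pos, dtype=float)
        return nid

    def add_seg(self, a: str, b: str, length: float, d_ctl: float,
                d_dil: float, vclass: str, prefix: str, **extra) -> str:
        dist = float(np.linalg.norm(self.nodes[a] - self.nodes[b]))
        length = max(length, dist * 1.02, 5.0)
        sid = f"{prefix}{self._sid:03d}"
        self._sid += 1
        self.segs.append(dict(id=sid, a=a, b=b, length=length, d_ctl=d_ctl,
                              d_dil=d_dil, vclass=vclass, extra=extra))
        return sid

    def jitter_z(self) -> float:
        # thin vascular sheet: keep vessels within the middle 40% of the slab
        return self.cfg.slab[2] / 2 \
            + self.rng.uniform(-0.2, 0.2) * self.cfg.slab[2]

    # -- main construction -------------------------------------------------
    def build(self):
        cfg, rng = self.cfg, self.rng
        Lx, Ly, Lz = cfg.slab

        # ---- arteriolar tree topology: binary bifurcation skeleton with
        # chain links; exactly n_terminal leaves, n_arterioles segments.
        n_bif = cfg.n_terminal_arterioles - 1
        n_chain = cfg.n_arterioles - cfg.n_terminal_arterioles - n_bif
        # skeleton: full binary tree edge list over leaves
        # each edge of the skeleton becomes a chain of >=1 arteriole segments
        skeleton_edges = 2 * cfg.n_terminal_arterioles - 1  # incl. root edge
        chain_extra = np.zeros(skeleton_edges, dtype=int)
        for _ in range(n_chain):
            chain_extra[rng.integers(0, skeleton_edges)] += 1

        # recursive layout: leaves get y slots
        leaf_y = np.linspace(60.0, Ly - 60.0, cfg.n_terminal_arterioles)
        self.root_node = self.new_node((30.0, Ly / 2, Lz / 2))

        # grow tree: queue of (parent_node, leaf_lo, leaf_hi, depth, parent_D)
        self.cap_origins: list[dict] = []    # node, diam, link-count, leaf span
        self.sibling_pairs: list[tuple[int, int]] = []   # chains of one terminal
        self.terminal_nodes: list[str] = []
        d_lo, d_hi = cfg.arteriole_dilated_diam_range
        edge_i = [0]

        def grow(parent, lo, hi, depth, D_par, links_before=0):
            # one skeleton edge: chain of 1+extra arteriole segments
            k = edge_i[0]
            edge_i[0] += 1
            n_links = 1 + int(chain_extra[k % skeleton_edges])
            yc = leaf_y[lo:hi].mean()
            x_par = self.nodes[parent][0]
            x_target = 60.0 + (min(depth + 1, 8) / 9.0) * (0.55 * Lx - 60.0)
            node = parent
            D = D_par
            for j in range(n_links):
                frac = (j + 1) / n_links
                x = x_par + (x_target - x_par) * frac
                y = self.nodes[parent][1] + (yc - self.nodes[parent][1]) * frac
                nxt = self.new_node((x + rng.uniform(-10, 10),
                                     y + rng.uniform(-10, 10), self.jitter_z()))
                taper = 0.96 if j == 0 else 1.0   # taper at branch points only
                D = float(np.clip(D * taper * rng.lognormal(0.0, 0.05),
                                  d_lo, d_hi))
                L = rng.uniform(*cfg.arteriole_length_range)
                tone = rng.uniform(*cfg.tone_fraction_range)
                self.add_seg(node, nxt, L, D * tone, D, "arteriole", "ar",
                             depth=depth)
                if j < n_links - 1:
                    # chain link: must be a diverging parent -> capillary side branch
                    self.cap_origins.append(
                        dict(node=nxt, D=D, proxy=links_before + j + 1,
                             lo=lo, hi=hi, terminal=False))
                node = nxt
            if hi - lo == 1:
                self.terminal_nodes.append(node)
                # terminal arteriole feeds two capillary daughters
                self.sibling_pairs.append((len(self.cap_origins),
                                           len(self.cap_origins) + 1))
                for _ in range(2):
                    self.cap_origins.append(
                        dict(node=node, D=D, proxy=links_before + n_links,
                             lo=lo, hi=hi, terminal=True))
            else:
                mid = lo + max(1, int(round((hi - lo) * rng.uniform(0.35, 0.65))))
                mid = min(mid, hi - 1)
                Dk = D * 2.0 ** (-1.0 / 3.0)    # Murray-like daughter taper
                grow(node, lo, mid, depth + 1, Dk / 0.96, links_before + n_links)
                grow(node, mid, hi, depth + 1, Dk / 0.96, links_before + n_links)

        D_root = d_hi
        grow(self.root_node, 0, cfg.n_terminal_arterioles, 0,
             D_root / 0.96)

        n_art = sum(1 for s in self.segs if s["vclass"] == "arteriole")
        if n_art != cfg.n_arterioles:
            raise GenerationError(
                f"internal: built {n_art} arterioles, wanted {cfg.n_arterioles}")

        # ---- capillary budget: chains plus cross-links
        E = len(self.cap_origins)
        n_cross = int(round(cfg.crosslink_probability * E))
        chain_budget = cfg.n_capillaries - n_cross
        if chain_budget < E:
            raise GenerationError(
                f"n_capillaries={cfg.n_capillaries} too small for "
                f"{E} capillary origins")
        if chain_budget > 4 * E:
            raise GenerationError(
                f"n_capillaries={cfg.n_capillaries} too large for {E} chains")
        base = 2 if chain_budget >= 2 * E else 1
        chain_len = np.full(E, base, dtype=int)
        extras = chain_budget - base * E
        # terminal chains first: they host tributaries and need interior nodes
        for k, o in enumerate(self.cap_origins):
            if extras > 0 and o["terminal"] and chain_len[k] < 4:
                chain_len[k] += 1
                extras -= 1
        while extras > 0:
            k = int(rng.integers(0, E))
            if chain_len[k] < 4:
                chain_len[k] += 1
                extras -= 1

        # ---- venule attachment slots (two collecting chains)
        half = cfg.n_venules // 2
        x_v = 0.86 * Lx
        slots_a = [self.new_node((x_v + rng.uniform(-8, 8), y, self.jitter_z()))
                   for y in np.linspace(60.0, Ly / 2 - 40.0, half + 1)]
        slots_b = [self.new_node((x_v + rng.uniform(-8, 8), y, self.jitter_z()))
                   for y in np.linspace(Ly / 2 + 40.0, Ly - 60.0, half + 1)]
        attach_nodes = slots_a[:half] + slots_b[:half]

        # ---- grow capillary chains, marking dilated-only vessels
        c_lo, c_hi = cfg.capillary_diam_range
        chain_end: list[str] = []
        self.chain_interiors: list[list[str]] = []
        self.chain_segids: list[list[str]] = []
        n_term_chains = sum(1 for o in self.cap_origins if o["terminal"])
        term_rank = 0
        for k, (o, ln) in enumerate(zip(self.cap_origins, chain_len)):
            origin = o["node"]
            p0 = self.nodes[origin]
            if o["terminal"]:
                o["slot"] = (term_rank if term_rank < len(attach_nodes) else None)
                term_rank += 1
                slot_for_target = o["slot"]
            else:
                o["slot"] = None
                leaves = list(range(o["lo"], o["hi"]))
                slot_for_target = min(2 * leaves[int(rng.integers(0, len(leaves)))],
                                      len(attach_nodes) - 1)
            target = self.nodes[attach_nodes[slot_for_target]] \
                if slot_for_target is not None else self.nodes[attach_nodes[-1]]
            Dc = rng.uniform(c_lo, c_hi)
            interiors: list[str] = []
            segids: list[str] = []
            node = origin
            for j in range(ln):
                frac = (j + 1) / (ln + 1)
                pos = p0 + (target - p0) * frac * 0.8
                nxt = self.new_node((pos[0] + rng.uniform(-25, 25),
                                     pos[1] + rng.uniform(-25, 25),
                                     self.jitter_z()))
                L = rng.uniform(*cfg.capillary_length_range)
                dil_only = rng.random() < cfg.frac_dilated_only
                d_dil = Dc * rng.uniform(0.9, 1.1)
                d_dil = float(np.clip(d_dil, c_lo, c_hi))
                d_ctl = max(3.5, d_dil - 1.2) if dil_only else d_dil
                sid = self.add_seg(node, nxt, L, d_ctl, d_dil, "capillary",
                                   "ca", intended_flowing_control=(not dil_only))
                segids.append(sid)
                if j < ln - 1:
                    interiors.append(nxt)
                node = nxt
            chain_end.append(node)
            self.chain_interiors.append(interiors)
            self.chain_segids.append(segids)

        # ---- drainage: terminal chains end on venule slots; side chains are
        # tributaries joining an interior node of a chain strictly further
        # down their own arteriolar path, so every junction they create sits
        # at lower pressure than their origin and flow stays forward.
        used: set[str] = set()

        # sibling cross-links first, so they still find free interior nodes
        for _ in range(n_cross):
            candidates = [(a, b) for i, j in self.sibling_pairs
                          for a in self.chain_interiors[i]
                          for b in self.chain_interiors[j]
                          if a not in used and b not in used]
            if not candidates:
                raise GenerationError("could not place the requested cross-links")
            a, b = candidates[int(rng.integers(0, len(candidates)))]
            Dx = rng.uniform(c_lo, c_hi)
            Lx_ = rng.uniform(*cfg.capillary_length_range)
            self.add_seg(a, b, Lx_, Dx, Dx, "capillary", "cx",
                         intended_flowing_control=True)
            used.update((a, b))

        # terminal chains end on the venule slots; side chains stay dangling
        # here and are wired to low-pressure interior nodes afterwards, using
        # a solved pressure field (wire_side_chains)
        for k, o in enumerate(self.cap_origins):
            if o["terminal"] and o["slot"] is not None:
                self._reattach_end(chain_end[k], attach_nodes[o["slot"]])
            elif o["terminal"]:
                # more terminal chains than venule slots: join the sibling
                sib = next(j for i, j in self.sibling_pairs + [
                    (j, i) for i, j in self.sibling_pairs] if i == k)
                if not any(n not in used for n in self.chain_interiors[sib]):
                    raise GenerationError("sibling chain has no free interior")
                tgt = next(n for n in self.chain_interiors[sib] if n not in used)
                self._reattach_end(chain_end[k], tgt)
                used.add(tgt)
        self.used = used
        self.chain_end = chain_end

        # ---- dilated-only arterioles (small control diameters, 2.9-3.8 um)
        # distal arterioles only, so a closed arteriole starves a small group
        art = [s for s in self.segs if s["vclass"] == "arteriole"
               and s["extra"].get("depth", 0) >= 3]
        n_dil_only = int(round(cfg.frac_dilated_only * 0.5 * len(art)))
        for k in rng.choice(len(art), size=min(n_dil_only, len(art)),
                            replace=False):
            art[k]["d_ctl"] = float(rng.uniform(2.9, 3.8))
            art[k]["extra"]["intended_flowing_control"] = False
        for s in self.segs:
            if s["vclass"] == "arteriole":
                s["extra"].setdefault("intended_flowing_control", True)

        # ---- venule collecting chains
        v_lo, v_hi = cfg.venule_diam_range
        for slots in (slots_a, slots_b):
            dv = np.sort(rng.uniform(v_lo, v_hi, size=half))
            for k in range(half):
                L = rng.uniform(*cfg.venule_length_range)
                self.add_seg(slots[k], slots[k + 1], L, dv[k], dv[k],
                             "venule", "ve")
        self.lv_start = (slots_a[half], slots_b[half])

        # ---- feed and drain vessels (outside the oxygen-coupled slab)
        yc, zc = Ly / 2, Lz / 2
        a_in = self.new_node((-2600.0, yc, zc))
        a_out = self.new_node((-1400.0, yc, zc))
        self.add_seg(a_in, a_out, 1200.0, 80.0, 80.0, "artery", "A")
        # LA control tone 0.6: the 0.70-0.80 band is a locally unstable
        # operating range of the wall model at feed-vessel pressures
        self.add_seg(a_out, self.root_node, 1460.0, 24.0, 40.0,
                     "large_arteriole", "LA")
        v_mid = []
        for i, lv in enumerate(self.lv_start):
            lv_end = self.new_node((Lx + 600.0, yc + (-150.0, 150.0)[i], zc))
            self.add_seg(lv, lv_end, 700.0, 60.0, 60.0, "large_venule", "LV")
            v_out = self.new_node((Lx + 1800.0, yc + (-150.0, 150.0)[i], zc))
            self.add_seg(lv_end, v_out, 1200.0, 120.0, 120.0, "vein", "V")
            v_mid.append(v_out)
        self.inflow_node = a_in
        self.outflow_nodes = v_mid

    def wire_side_chains(self, max_rounds: int = 8) -> None:
        """Attach dangling side chains to low-pressure interior nodes.

        Uses the passive dilated flow solution to pick junctions whose
        pressure lies well below the side chain's origin, then verifies
        that every generated arteriole is still a diverging parent,
        re-wiring offending tributaries toward the venous side until the
        orientation is stable.
        """
        from .hemodynamics import FlowSolverSettings, solve_flows

        side = [k for k, o in enumerate(self.cap_origins) if not o["terminal"]]
        if not side:
            return
        rng = self.rng
        node_chain = {n: k for k, ints in enumerate(self.chain_interiors)
                      for n in ints}
        self.trib_attach: dict[int, str] = {}
        settings = FlowSolverSettings(phase_separation_enabled=False)
        for rnd in range(max_rounds):
            net = self.finish()
            dd = np.array([sg.diameter_dilated for sg in net.segments])
            st = solve_flows(net, dd, settings)
            P = {n.id: p for n, p in zip(net.nodes, st.pressure_node)}
            if rnd == 0:
                for k in sorted(side,
                                key=lambda k: -self.cap_origins[k]["proxy"]):
                    o = self.cap_origins[k]
                    po = P[o["node"]]
                    lim = po - 0.3 * (po - 13.0)
                    cands = [n for k2, ints in enumerate(self.chain_interiors)
                             if k2 != k for n in ints
                             if n not in self.used and P.get(n, 1e9) < lim]
                    if not cands:
                        # fall back to the lowest-pressure free interior
                        # with at least a small forward-pressure margin
                        free = [n for k2, ints in
                                enumerate(self.chain_interiors)
                                if k2 != k for n in ints
                                if n not in self.used
                                and P.get(n, 1e9) < po - 2.0]
                        if not free:
                            raise GenerationError(
                                "no low-pressure interior for a side chain")
                        cands = [min(free, key=lambda n: P.get(n, 1e9))]
                    tgt = cands[int(rng.integers(0, len(cands)))]
                    self._move_endpoint(self.chain_segids[k][-1],
                                        self.chain_end[k], tgt)
                    self.used.add(tgt)
                    self.trib_attach[k] = tgt
                continue
            bad_hosts = self._misrouted_chains(net, st)
            if not bad_hosts:
                self._scale_collectors()
                return
            fixed = False
            for k_host in bad_hosts:
                tribs = [k for k, tgt in self.trib_attach.items()
                         if node_chain.get(tgt) == k_host]
                if not tribs:
                    continue
                k = max(tribs, key=lambda k: P.get(self.trib_attach[k], -1e9))
                cands = [n for k2, ints in enumerate(self.chain_interiors)
                         if k2 != k for n in ints if n not in self.used]
                if not cands:
                    continue
                tgt = min(cands, key=lambda n: P.get(n, 1e9))
                old_t = self.trib_attach[k]
                self._move_endpoint(self.chain_segids[k][-1], old_t, tgt)
                self.used.discard(old_t)
                self.used.add(tgt)
                self.trib_attach[k] = tgt
                fixed = True
            if not fixed:
                raise GenerationError(
                    "could not repair reversed capillary junctions")
        raise GenerationError("side-chain wiring did not stabilize")

    def _scale_collectors(self) -> None:
        """Widen collecting capillaries by a Murray-like flow-unit rule.

        A chain segment that drains n feeder chains (its own plus wired
        tributaries) gets its diameter scaled by n^(1/3), capped below
        the arteriole classification threshold, so the venular-side
        capillaries run wider than the feeders they collect.
        """
        E = len(self.cap_origins)
        node_pos: dict[str, tuple[int, int]] = {}
        for k, ints in enumerate(self.chain_interiors):
            for j, n in enumerate(ints):
                node_pos[n] = (k, j + 1)   # tributary enters before seg j+1
        children: dict[int, list[tuple[int, int]]] = {}
        for k, tgt in getattr(self, "trib_attach", {}).items():
            k2, j = node_pos[tgt]
            children.setdefault(k2, []).append((k, j))
        out_units = np.ones(E)
        for _ in range(E):
            new = np.ones(E)
            for k in range(E):
                new[k] = 1.0 + sum(out_units[kk]
                                   for kk, _ in children.get(k, []))
            if np.array_equal(new, out_units):
                break
            out_units = np.minimum(new, E)
        seg_by_id = {s["id"]: s for s in self.segs}
        # nodes that host a cross-link can act as diverging bifurcations, so
        # the segment feeding them must stay below the arteriole threshold;
        # pure collectors (converging only) may widen further
        cx_nodes = {s[e] for s in self.segs if s["id"].startswith("cx")
                    for e in ("a", "b")}
        for k in range(E):
            sids = self.chain_segids[k]
            ints = self.chain_interiors[k]
            units = np.ones(len(sids))
            for kk, j in children.get(k, []):
                units[j:] += out_units[kk]
            for j, sid in enumerate(sids):
                if units[j] <= 1.0:
                    continue
                seg = seg_by_id[sid]
                down_node = ints[j] if j < len(ints) else None
                cap = 7.9 if (down_node in cx_nodes) else 11.0
                f = units[j] ** (1.0 / 3.0)
                d_dil = min(seg["d_dil"] * f, cap)
                seg["d_dil"] = d_dil
                if seg["extra"].get("intended_flowing_control", True):
                    seg["d_ctl"] = d_dil
                else:
                    seg["d_ctl"] = max(3.5, d_dil - 1.2)

    def _misrouted_chains(self, net: NetworkGraph, st) -> set[int]:
        """Chains whose head runs backward into an arteriolar junction."""
        sidx = net.segment_index()
        up_of, down_of = {}, {}
        for i, sg in enumerate(net.segments):
            if st.flow[i] >= 0:
                up_of[sg.id], down_of[sg.id] = sg.from_node, sg.to_node
            else:
                up_of[sg.id], down_of[sg.id] = sg.to_node, sg.from_node
        out_at: dict[str, list[str]] = {}
        for sg in net.segments:
            out_at.setdefault(up_of[sg.id], []).append(sg.id)
        head_of = {segids[0]: k for k, segids in enumerate(self.chain_segids)}
        bad: set[int] = set()
        for sg in net.segments:
            if sg.vclass != "arteriole":
                continue
            kids = out_at.get(down_of[sg.id], [])
            if len(kids) >= 2:
                continue
            # reversed capillary head(s) at this junction
            for s2 in net.segments:
                if s2.vclass != "capillary":
                    continue
                if down_of[s2.id] == down_of[sg.id] and s2.id in head_of:
                    bad.add(head_of[s2.id])
        return bad

    def _move_endpoint(self, segid: str, old: str, new: str):
        seg = next(s for s in self.segs if s["id"] == segid)
        if seg["a"] == old:
            seg["a"] = new
        elif seg["b"] == old:
            seg["b"] = new
        else:
            raise GenerationError(f"{segid} does not touch {old}")
        if not any(old in (s["a"], s["b"]) for s in self.segs):
            self.nodes.pop(old, None)

    def _reattach_end(self, old: str, new: str):
        """Redirect every reference to a chain's dangling end node."""
        for s in self.segs:
            if s["a"] == old:
                s["a"] = new
            if s["b"] == old:
                s["b"] = new
        self.nodes.pop(old, None)

    def _degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for s in self.segs:
            deg[s["a"]] = deg.get(s["a"], 0) + 1
            deg[s["b"]] = deg.get(s["b"], 0) + 1
        return deg

    # -- conversion --------------------------------------------------------
    def finish(self) -> NetworkGraph:
        cfg = self.cfg
        nodes = [Node(nid, pos) for nid, pos in self.nodes.items()]
        segments = []
        intended = {}
        for s in self.segs:
            p0, p1 = self.nodes[s["a"]], self.nodes[s["b"]]
            # merges may have moved endpoints after the length was drawn
            dist = float(np.linalg.norm(p1 - p0))
            s["length"] = max(s["length"], dist * 1.02)
            cl = _polyline(p0, p1, s["length"], self.rng)
            seg = VesselSegment(
                id=s["id"], from_node=s["a"], to_node=s["b"],
                length=s["length"], diameter_control=s["d_ctl"],
                diameter_dilated=s["d_dil"], diameter_current=s["d_ctl"],
                vclass=s["vclass"], centerline=cl,
                sleeve_width=18.8 if s["vclass"] in ("artery", "large_arteriole")
                else None)
            segments.append(seg)
            if "intended_flowing_control" in s["extra"]:
                intended[s["id"]] = int(s["extra"]["intended_flowing_control"])
        net = NetworkGraph(segments, nodes, {
            "generator_seed": cfg.seed,
            "slab": f"{cfg.slab[0]}x{cfg.slab[1]}x{cfg.slab[2]}",
            "extra_columns": {"intended_flowing_control": intended},
        })
        for nid, P, H, po2 in [
            (self.inflow_node, 100.0, 0.4, 100.0),
            (self.outflow_nodes[0], 12.91, None, None),
            (self.outflow_nodes[1], 12.91, None, None),
        ]:
            n = net.node(nid)
            n.boundary = True
            n.boundary_pressure = P
            n.boundary_hematocrit = H
            n.boundary_po2 = po2
        n_cap = sum(1 for s in segments if s.vclass == "capillary")
        if n_cap != cfg.n_capillaries:
            raise GenerationError(
                f"internal: built {n_cap} capillaries, wanted {cfg.n_capillaries}")
        return net


def _polyline(p0, p1, length: float, rng: np.random.Generator) -> np.ndarray:
    """Centerline from p0 to p1 whose arc length equals ``length``.

    Straight when the chord already matches; otherwise a zig-zag with an
    even number of equal legs, offset in the x-y plane, absorbing the
    tortuosity the chord cannot express.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = float(np.linalg.norm(p1 - p0))
    if length <= d * 1.0001:
        return np.vstack([p0, p1])
    h_max = 60.0
    delta_tot = math.sqrt(length ** 2 - d ** 2)
    m = max(2, 2 * math.ceil(delta_tot / (2 * h_max) / 2 + 0.5))
    delta = delta_tot / m
    chord = (p1 - p0) / m
    perp = np.array([-chord[1], chord[0], 0.0])
    nrm = np.linalg.norm(perp)
    perp = perp / nrm if nrm > 1e-12 else np.array([0.0, 1.0, 0.0])
    pts = [p0]
    for i in range(1, m):
        off = delta if i % 2 else 0.0
        pts.append(p0 + chord * i + perp * off)
    pts.append(p1)
    return np.vstack(pts)
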
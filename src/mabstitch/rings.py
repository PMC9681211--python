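"""Disulfide detection and minimal covalent rings through two chosen bonds.

The hinge of an IgG1 closes a covalent macrocycle: the paired CPPC motifs of
the two heavy chains plus their two inter-chain disulfides form a simple
cycle through both S-S bonds.  Finding the *smallest* such cycle is a
two-vertex-disjoint-paths problem, solved exactly here with a unit-capacity
min-cost flow (node splitting enforces vertex disjointness), rather than two
independent shortest paths which could illegally share atoms.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bondgraph import bond_graph  # re-export for callers
from .errors import TopologyError
from .model import AtomRef, Structure

__all__ = ["bond_graph", "detect_disulfides", "smallest_ring_through_edges", "RingResult"]

DISULFIDE_CUTOFF = 2.3  # Angstrom


def detect_disulfides(
    s: Structure, cutoff: float = DISULFIDE_CUTOFF
) -> list[tuple[AtomRef, AtomRef]]:
    """All Cys SG-SG pairs below `cutoff`, each SG used at most once
    (greedy nearest-first pairing); symmetric in chain order."""
    sgs: list[tuple[AtomRef, np.ndarray]] = []
    for c in s.chains:
        for r in c.residues:
            if r.name == "CYS" and r.has_atom("SG"):
                sgs.append((AtomRef(c.id, r.seq_num, r.icode, "SG"), r.atom("SG").coords))
    cand = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                cand.append((d, i, j))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = sorted((sgs[i][0], sgs[j][0]))
        pairs.append((a, b))
    pairs.sort()
    return pairs


@dataclass
class RingResult:
    size: int
    atoms: list[AtomRef]  # ordered cycle

    def name_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(r.atom_name for r in self.atoms))


def smallest_ring_through_edges(
    g: nx.Graph, e1: tuple, e2: tuple
) -> RingResult | None:
    """Minimum-length simple cycle containing both edges, or None.

    Hydrogens (degree-1 nodes) can never lie on a cycle and are ignored.
    The two arcs joining e1 to e2 are found as a min-cost unit flow of value
    2 with unit node capacities, which guarantees vertex disjointness and
    global optimality of the total length.
    """
    a1, b1 = e1
    a2, b2 = e2
    for u, v in (e1, e2):
        if not g.has_edge(u, v):
            raise TopologyError(f"edge {(u, v)} not in graph")
    if frozenset(e1) == frozenset(e2):
        raise TopologyError("the two edges must be distinct")

    h = g.copy()
    h.remove_edge(a1, b1)
    h.remove_edge(a2, b2)

    shared = frozenset(e1) & frozenset(e2)
    if shared:
        # adjacent edges: cycle = e1 + e2 + path between the far endpoints
        (sv,) = shared
        u = a1 if b1 == sv else b1
        v = a2 if b2 == sv else b2
        hh = h.copy()
        hh.remove_node(sv)
        try:
            path = nx.shortest_path(hh, u, v)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None
        cycle = [sv] + path
        return RingResult(size=len(cycle), atoms=cycle)

    # node-split flow network
    f = nx.DiGraph()
    for node in h.nodes:
        f.add_edge(("in", node), ("out", node), capacity=1, weight=0)
    for u, v in h.edges:
        f.add_edge(("out", u), ("in", v), capacity=1, weight=1)
        f.add_edge(("out", v), ("in", u), capacity=1, weight=1)
    S, T = ("S",), ("T",)
    for src in (a1, b1):
        f.add_edge(S, ("in", src), capacity=1, weight=0)
    for dst in (a2, b2):
        f.add_edge(("out", dst), T, capacity=1, weight=0)
    try:
        flow = nx.max_flow_min_cost(f, S, T)
    except nx.NetworkXUnfeasible:
        return None
    value = sum(flow[S][("in", src)] for src in (a1, b1))
    if value < 2:
        return None

    def walk(start):
        path = [start]
        node = start
        while True:
            nxt = None
            for _, v2 in f.out_edges(("out", node)):
                if v2 == T:
                    if flow[("out", node)][T] > 0:
                        return path
                    continue
                if flow[("out", node)].get(v2, 0) > 0:
                    nxt = v2[1]
                    break
            if nxt is None:
                raise TopologyError("flow decomposition failed")
            path.append(nxt)
            node = nxt

    p_a1 = walk(a1)
    p_b1 = walk(b1)
    # cycle: a1 ... (a2 or b2), cross e2, back along the other path, cross e1
    cycle = p_a1 + list(reversed(p_b1))
    return RingResult(size=len(cycle), atoms=cycle)


def smallest_ring_through_disulfides(s: Structure) -> RingResult | None:
    """Minimal covalent ring through the structure's two disulfide links
    (the hinge-core macrocycle); requires exactly two disulfides."""
    ss = [l for l in s.links if l.link_type == "disulfide"]
    if len(ss) != 2:
        raise TopologyError(f"need exactly 2 disulfides, found {len(ss)}")
    g = bond_graph(s, include_hydrogens=False)
    e1 = (ss[0].atom_a, ss[0].atom_b)
    e2 = (ss[1].atom_a, ss[1].atom_b)
    return smallest_ring_through_edges(g, e1, e2)
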
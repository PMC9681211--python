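"""Disulfide detection and minimal rings through two chosen bonds, checked
against a brute-force simple-cycle enumeration oracle."""
import itertools

import networkx as nx
import numpy as np
import pytest

from mabstitch.fixtures import make_ideal_peptide, make_paired_hinge
from mabstitch.rings import (
    bond_graph,
    detect_disulfides,
    smallest_ring_through_disulfides,
    smallest_ring_through_edges,
)


def brute_force_min_cycle(g, e1, e2):
    """Smallest simple cycle containing both edges, by full enumeration."""
    best = None
    for cycle in nx.simple_cycles(g):
        if len(cycle) < 3:
            continue
        edges = {
            frozenset((cycle[i], cycle[(i + 1) % len(cycle)]))
            for i in range(len(cycle))
        }
        if frozenset(e1) in edges and frozenset(e2) in edges:
            if best is None or len(cycle) < best:
                best = len(cycle)
    return best


class TestDetectDisulfides:
    def _two_cys(self, distance):
        s = make_ideal_peptide("CAC")
        res3 = s.chain("A").residue(3)
        res1 = s.chain("A").residue(1)
        res3.atom("SG").coords = res1.atom("SG").coords + np.array([distance, 0, 0])
        return s

    def test_bonded_pair_detected(self):
        pairs = detect_disulfides(self._two_cys(2.05))
        assert len(pairs) == 1

    def test_distant_pair_not_detected(self):
        assert detect_disulfides(self._two_cys(3.5)) == []

    def test_paired_hinge_has_exactly_two(self, paired_hinge):
        pairs = detect_disulfides(paired_hinge)
        assert len(pairs) == 2
        # symmetric in chain order: reversing chain list gives the same pairs
        flipped = paired_hinge.copy()
        flipped.chains.reverse()
        assert detect_disulfides(flipped) == pairs


class TestSmallestRing:
    def test_six_cycle_with_opposite_edges(self):
        g = nx.cycle_graph(6)
        ring = smallest_ring_through_edges(g, (0, 1), (3, 4))
        assert ring.size == 6

    def test_no_common_cycle_returns_none(self):
        g = nx.Graph()
        g.add_edges_from(nx.cycle_graph(4).edges)
        g.add_edges_from((f"x{a}", f"x{b}") for a, b in nx.cycle_graph(4).edges)
        assert smallest_ring_through_edges(g, (0, 1), ("x0", "x1")) is None

    def test_adjacent_edges(self):
        g = nx.cycle_graph(5)
        ring = smallest_ring_through_edges(g, (0, 1), (1, 2))
        assert ring.size == 5

    def test_chooses_smallest_of_several_cycles(self):
        # two cycles share the edges: a 6-ring and an 8-ring
        g = nx.cycle_graph(6)
        nx.add_path(g, [0, 10, 11, 12, 3])
        ring = smallest_ring_through_edges(g, (0, 1), (2, 3))
        assert ring.size == 6

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(500 + seed)
        n = int(rng.integers(6, 15))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        edges = list(g.edges)
        if len(edges) < 2:
            pytest.skip("degenerate random graph")
        e1, e2 = (edges[i] for i in rng.choice(len(edges), size=2, replace=False))
        expected = brute_force_min_cycle(g, e1, e2)
        got = smallest_ring_through_edges(g, e1, e2)
        assert (None if got is None else got.size) == expected

    def test_invariant_under_relabeling(self, paired_hinge):
        ring = smallest_ring_through_disulfides(paired_hinge)
        relabeled = paired_hinge.copy()
        relabeled.chains[0].id = "X"
        relabeled.chains[1].id = "Y"
        from mabstitch.model import AtomRef, CovalentLink

        relabeled.links = [
            CovalentLink(
                AtomRef({"A": "X", "B": "Y"}[l.atom_a.chain_id], l.atom_a.seq_num,
                         l.atom_a.icode, l.atom_a.atom_name),
                AtomRef({"A": "X", "B": "Y"}[l.atom_b.chain_id], l.atom_b.seq_num,
                         l.atom_b.icode, l.atom_b.atom_name),
                l.link_type,
            )
            for l in relabeled.links
        ]
        ring2 = smallest_ring_through_disulfides(relabeled)
        assert ring2.size == ring.size
        assert ring2.name_multiset() == ring.name_multiset()


class TestHingeRing:
    def test_paired_cppc_macrocycle_is_28_atoms(self, paired_hinge):
        ring = smallest_ring_through_disulfides(paired_hinge)
        assert ring.size == 28
        names = ring.name_multiset()
        assert names.count("SG") == 4
        assert names.count("CB") == 4
        assert names.count("CA") == 8

    def test_intrachain_loop_sizes_match_oracle(self):
        # Cys(i)...Cys(i+k) intramolecular loops at several spacings
        for k in (1, 2, 3):
            seq = "C" + "A" * (k - 1) + "C"
            s = make_ideal_peptide("G" + seq + "G")
            from mabstitch.model import AtomRef, CovalentLink

            s.links.append(
                CovalentLink(
                    AtomRef("A", 2, "", "SG"),
                    AtomRef("A", 2 + k, "", "SG"),
                    "disulfide",
                )
            )
            g = bond_graph(s, include_hydrogens=False)
            (ss,) = [l for l in s.links]
            e1 = (ss.atom_a, ss.atom_b)
            # ring through the disulfide and the Cys(i) CA-CB bond
            e2 = (AtomRef("A", 2, "", "CA"), AtomRef("A", 2, "", "CB"))
            got = smallest_ring_through_edges(g, e1, e2)
            expected = brute_force_min_cycle(g, e1, e2)
            assert got.size == expected == 8 + 3 * (k - 1)
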
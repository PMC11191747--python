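"""H-bond detection, donor/acceptor chemistry, and water-bridge search."""

import numpy as np
import pytest

from porenet.chemistry import assign_donors_acceptors, donor_acceptor_census
from porenet.errors import ParameterError
from porenet.hbonds import (
    DHA_SUPPLEMENT,
    HBondCriteria,
    detect_hbonds,
    water_bridges,
)
from porenet.trajectory import AtomRecord, Frame, Topology

from oracles import oracle_bridges, oracle_hbond_triples, random_small_system


def _pair_system(d_ax=2.8, box=50.0):
    """Two serine-like sites on separate chains, donor H on the x axis."""
    atoms = [
        AtomRecord(1, "CA", "C", 1, "PSC", "A", "peptide"),
        AtomRecord(2, "OG", "O", 1, "PSC", "A", "peptide"),
        AtomRecord(3, "HG", "H", 1, "PSC", "A", "peptide"),
        AtomRecord(4, "CA", "C", 1, "PSC", "B", "peptide"),
        AtomRecord(5, "OG", "O", 1, "PSC", "B", "peptide"),
        AtomRecord(6, "HG", "H", 1, "PSC", "B", "peptide"),
    ]
    top = Topology(atoms, [(2, 3), (5, 6)])
    assign_donors_acceptors(top)
    X = np.array([
        [0, 0, 1.5], [0, 0, 0], [0.96, 0, 0],  # donor site, H toward +x
        [d_ax, 0, 1.5], [d_ax, 0, 0], [d_ax + 0.96, 0, 0],
    ], dtype=float)
    return top, Frame(0, 0.0, np.array([box] * 3), X)


class TestChemistryAssignment:
    def test_serine_side_chain_is_both(self):
        top, _ = _pair_system()
        assert top.donor_atoms == [1, 4]  # OG indices
        assert 1 in top.acceptor_atoms and 4 in top.acceptor_atoms

    def test_alanine_has_no_sites(self):
        atoms = [
            AtomRecord(1, "CA", "C", 1, "ALA", "A", "peptide"),
            AtomRecord(2, "CB", "C", 1, "ALA", "A", "peptide"),
        ]
        top = assign_donors_acceptors(Topology(atoms, []))
        assert top.donor_atoms == [] and top.acceptor_atoms == []

    def test_lysine_nitrogen_donates_but_does_not_accept(self):
        atoms = [
            AtomRecord(1, "NZ", "N", 1, "LYS", "A", "peptide"),
            AtomRecord(2, "HZ1", "H", 1, "LYS", "A", "peptide"),
        ]
        top = assign_donors_acceptors(Topology(atoms, [(1, 2)]))
        assert top.donor_atoms == [0]
        assert top.acceptor_atoms == []

    def test_synthetic_census_matches_manifest(self, octamer):
        _, top, _, manifest = octamer
        census = donor_acceptor_census(top)
        n_waters = len([a for a in top.atoms
                        if a.molecule_class == "water" and a.element == "O"])
        assert census["peptide_donors"] == manifest.n_side_chain_sites
        assert census["peptide_acceptors"] == manifest.n_side_chain_sites
        assert census["lipid_acceptors"] == manifest.n_lipid_acceptor_oxygens
        assert census["water_donors"] == n_waters


class TestDetectHbonds:
    def test_ideal_geometry_gives_one_bond(self):
        top, frame = _pair_system(d_ax=2.8)
        events = detect_hbonds(frame, top)
        assert len(events) == 1
        ev = events[0]
        assert (ev.donor_atom, ev.acceptor_atom) == (2, 5)
        assert ev.angle == pytest.approx(0.0)
        assert ev.distance == pytest.approx(2.8)

    def test_beyond_distance_cutoff(self):
        top, frame = _pair_system(d_ax=3.6)
        assert detect_hbonds(frame, top) == []

    def test_both_angle_conventions_accept_linear_bond(self):
        top, frame = _pair_system(d_ax=2.8)
        for conv in ("H_D_A", DHA_SUPPLEMENT):
            assert len(detect_hbonds(frame, top,
                                     HBondCriteria(angle_convention=conv))) == 1

    def test_minimum_image_across_boundary(self):
        top, frame = _pair_system(d_ax=2.8, box=50.0)
        # translate the acceptor site by a box vector: same physics
        frame.coordinates[3:] += np.array([50.0, 0.0, 0.0])
        assert len(detect_hbonds(frame, top)) == 1

    def test_translation_and_permutation_invariance(self):
        rng = np.random.default_rng(42)
        top, frame = random_small_system(rng)
        ref = {(e.donor_atom, e.hydrogen, e.acceptor_atom)
               for e in detect_hbonds(frame, top)}
        shifted = Frame(0, 0.0, frame.box, frame.coordinates + rng.uniform(-30, 30, 3))
        assert {(e.donor_atom, e.hydrogen, e.acceptor_atom)
                for e in detect_hbonds(shifted, top)} == ref
        # permute atom order, keeping ids
        perm = rng.permutation(top.n_atoms)
        atoms = [top.atoms[i] for i in perm]
        top2 = Topology(atoms, top.bonds)
        assign_donors_acceptors(top2)
        frame2 = Frame(0, 0.0, frame.box, frame.coordinates[perm])
        assert {(e.donor_atom, e.hydrogen, e.acceptor_atom)
                for e in detect_hbonds(frame2, top2)} == ref

    @pytest.mark.parametrize("convention", ["H_D_A", DHA_SUPPLEMENT])
    def test_matches_exhaustive_oracle(self, convention):
        rng = np.random.default_rng(7)
        for _ in range(25):
            top, frame = random_small_system(rng)
            crit = HBondCriteria(angle_convention=convention)
            got = {(e.donor_atom, e.hydrogen, e.acceptor_atom)
                   for e in detect_hbonds(frame, top, crit)}
            want = oracle_hbond_triples(frame, top, convention=convention)
            assert got == want


def _bridge_fixture(water_chain_len, site_gap=None):
    """Two sites joined by a straight chain of waters, 2.8 Å spacing."""
    n = water_chain_len
    gap = site_gap if site_gap is not None else 2.8 * (n + 1)
    atoms = [
        AtomRecord(1, "CA", "C", 1, "PSC", "A", "peptide"),
        AtomRecord(2, "OG", "O", 1, "PSC", "A", "peptide"),
        AtomRecord(3, "HG", "H", 1, "PSC", "A", "peptide"),
        AtomRecord(4, "CA", "C", 1, "PSC", "B", "peptide"),
        AtomRecord(5, "OG", "O", 1, "PSC", "B", "peptide"),
        AtomRecord(6, "HG", "H", 1, "PSC", "B", "peptide"),
    ]
    bonds = [(2, 3), (5, 6)]
    coords = [
        [0, 0, 1.5], [0, 0, 0], [0, 0, -0.96],
        [gap, 0, 1.5], [gap, 0, 0], [gap, 0, -0.96],
    ]
    aid = 6
    for w in range(n):
        x = 2.8 * (w + 1) if site_gap is None else gap * (w + 1) / (n + 1)
        atoms += [
            AtomRecord(aid + 1, "O", "O", w + 1, "HOH", "W", "water"),
            AtomRecord(aid + 2, "H1", "H", w + 1, "HOH", "W", "water"),
            AtomRecord(aid + 3, "H2", "H", w + 1, "HOH", "W", "water"),
        ]
        bonds += [(aid + 1, aid + 2), (aid + 1, aid + 3)]
        coords += [[x, 0, 0], [x - 0.96, 0, 0], [x + 0.96, 0, 0]]
        aid += 3
    top = Topology(atoms, bonds)
    assign_donors_acceptors(top)
    frame = Frame(0, 0.0, np.array([200.0] * 3), np.array(coords, dtype=float))
    return top, frame


class TestWaterBridges:
    def test_single_shared_water(self):
        top, frame = _bridge_fixture(1)
        bridges = water_bridges(detect_hbonds(frame, top), top)
        assert len(bridges) == 1
        b = bridges[0]
        assert b.n_waters == 1
        assert b.endpoint_a == ("pep", 1, 1) and b.endpoint_b == ("pep", 2, 1)

    def test_four_water_chain_exceeds_limit(self):
        top, frame = _bridge_fixture(4)
        bridges = water_bridges(detect_hbonds(frame, top), top, max_waters=3)
        assert bridges == []

    def test_max_waters_zero_yields_direct_only(self):
        top, frame = _bridge_fixture(1)
        assert water_bridges(detect_hbonds(frame, top), top, max_waters=0) == []
        top2, frame2 = _pair_system(d_ax=2.8)
        direct = water_bridges(detect_hbonds(frame2, top2), top2, max_waters=0)
        assert [b.n_waters for b in direct] == [0]

    def test_negative_max_waters_rejected(self):
        top, frame = _bridge_fixture(1)
        with pytest.raises(ParameterError):
            water_bridges(detect_hbonds(frame, top), top, max_waters=-1)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            top, frame = random_small_system(rng)
            events = detect_hbonds(frame, top)
            got = {(b.endpoint_a, b.endpoint_b): (b.n_waters, b.water_ids)
                   for b in water_bridges(events, top, max_waters=3)}
            triples = {(e.donor_atom, e.hydrogen, e.acceptor_atom)
                       for e in events}
            assert got == oracle_bridges(triples, top, max_waters=3)

    def test_minimality_deleting_interior_water(self):
        """Removing any water of a reported bridge lengthens or breaks it."""
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(40):
            top, frame = random_small_system(rng)
            events = detect_hbonds(frame, top)
            triples = {(e.donor_atom, e.hydrogen, e.acceptor_atom)
                       for e in events}
            for b in water_bridges(events, top, max_waters=3):
                if b.n_waters == 0:
                    continue
                for wid in b.water_ids:
                    pruned = {
                        t for t in triples
                        if ("wat", wid) not in (
                            top.node_keys[top.index_of(t[0])],
                            top.node_keys[top.index_of(t[2])],
                        )
                    }
                    alt = oracle_bridges(pruned, top, max_waters=3).get(
                        (b.endpoint_a, b.endpoint_b))
                    assert alt is None or alt[0] >= b.n_waters
                    checked += 1
        assert checked > 0
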
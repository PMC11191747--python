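"""Independent brute-force oracles used to verify the detection code.

These deliberately share no code with porenet.hbonds: distances and angles
are recomputed pairwise, and bridge search is exhaustive simple-path
enumeration over the H-bond graph via networkx.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from porenet.trajectory import AtomRecord, Frame, Topology


def min_image(d, box):
    return d - box * np.round(d / box)


def oracle_hbond_triples(frame, topology, d_max=3.5, angle_max=60.0,
                         convention="H_D_A"):
    """All (donor_id, h_id, acceptor_id) triples by exhaustive pair scan."""
    X = frame.coordinates
    box = frame.box
    out = set()
    for d in topology.donor_atoms:
        for a in topology.acceptor_atoms:
            if d == a:
                continue
            if (topology.chains[d], topology.resids[d]) == \
               (topology.chains[a], topology.resids[a]):
                continue
            v_da = min_image(X[a] - X[d], box)
            if math.sqrt(float(np.dot(v_da, v_da))) > d_max:
                continue
            for h in topology.donor_hydrogens[d]:
                if convention == "H_D_A":
                    v_dh = min_image(X[h] - X[d], box)
                    ang = _deg(v_dh, v_da)
                else:
                    v_hd = min_image(X[d] - X[h], box)
                    v_ha = min_image(X[a] - X[h], box)
                    ang = 180.0 - _deg(v_hd, v_ha)
                if ang <= angle_max + 1e-12:
                    out.add((topology.atoms[d].atom_id,
                             topology.atoms[h].atom_id,
                             topology.atoms[a].atom_id))
    return out


def _deg(u, v):
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def oracle_bridges(triples, topology, max_waters=3):
    """{(node_a, node_b): (n_waters, water_ids)} by exhaustive simple-path
    enumeration; ties broken by the lexicographically smallest id sequence
    read from the smaller endpoint."""
    g = nx.Graph()
    for d_id, _h, a_id in triples:
        u = topology.node_keys[topology.index_of(d_id)]
        v = topology.node_keys[topology.index_of(a_id)]
        if u is None or v is None or u == v:
            continue
        g.add_edge(u, v)
    nonwater = sorted(n for n in g.nodes if n[0] != "wat")
    best = {}
    for u, v in itertools.combinations(nonwater, 2):
        candidates = []
        for path in nx.all_simple_paths(g, u, v, cutoff=max_waters + 1):
            interior = path[1:-1]
            if all(n[0] == "wat" for n in interior):
                candidates.append((len(interior), tuple(n[1] for n in interior)))
        if candidates:
            best[(u, v)] = min(candidates)
    return best


def random_small_system(rng, n_sites=None, n_waters=None, box_len=15.0):
    """A random fixture of surrogate side-chain sites and waters in a small
    periodic box (≤ 50 atoms), for oracle-equivalence testing."""
    if n_sites is None:
        n_sites = int(rng.integers(2, 6))
    if n_waters is None:
        n_waters = int(rng.integers(0, 12))
    atoms, bonds = [], []
    aid = 0

    def add(name, element, resid, resname, chain, cls):
        nonlocal aid
        aid += 1
        atoms.append(AtomRecord(aid, name, element, resid, resname, chain, cls))
        return aid

    coords = []
    for s in range(n_sites):
        chain = "A"
        resid = s + 1
        pos = rng.uniform(0, box_len, 3)
        ca = add("CA", "C", resid, "PSC", chain, "peptide")
        og = add("OG", "O", resid, "PSC", chain, "peptide")
        hg = add("HG", "H", resid, "PSC", chain, "peptide")
        bonds.append((og, hg))
        h_dir = rng.normal(size=3)
        h_dir /= np.linalg.norm(h_dir)
        coords += [pos + [0.0, 0.0, 1.2], pos, pos + 0.96 * h_dir]
    for w in range(n_waters):
        o = add("O", "O", w + 1, "HOH", "W", "water")
        h1 = add("H1", "H", w + 1, "HOH", "W", "water")
        h2 = add("H2", "H", w + 1, "HOH", "W", "water")
        bonds += [(o, h1), (o, h2)]
        pos = rng.uniform(0, box_len, 3)
        d1 = rng.normal(size=3)
        d1 /= np.linalg.norm(d1)
        d2 = rng.normal(size=3)
        d2 /= np.linalg.norm(d2)
        coords += [pos, pos + 0.96 * d1, pos + 0.96 * d2]

    from porenet.chemistry import assign_donors_acceptors

    top = assign_donors_acceptors(Topology(atoms, bonds))
    frame = Frame(0, 0.0, np.array([box_len] * 3), np.array(coords))
    return top, frame
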
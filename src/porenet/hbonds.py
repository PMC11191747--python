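"""Geometric hydrogen-bond and water-bridge detection.

An H-bond is declared between a donor heavy atom D (carrying hydrogen H) and
an acceptor heavy atom A when the D···A heteroatom distance is ≤ ``d_max``
(default 3.5 Å) and the H-bond angle is ≤ ``angle_max`` (default 60°).  Two
conventions for the angle are supported, selected by
``HBondCriteria.angle_convention``:

* ``"H_D_A"`` (default): the angle at the donor between the D→H and D→A
  vectors;
* ``"DHA_supplement"``: 180° minus the D–H···A angle at the hydrogen.

Both vanish for an ideally linear bond and the two are nearly equivalent at
this cutoff.  All distances use the minimum-image convention under an
orthorhombic box.

A *water bridge* connects two non-water nodes (peptide side chains or lipid
phosphates) through a chain of H-bonds whose interior members are exclusively
waters, at most ``max_waters`` (default 3) of them.  ``n_waters = 0`` encodes
a direct H-bond.  Bridges are undirected and reported at residue-node
granularity with the minimum achievable water count.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError, PorenetError
from .trajectory import Frame, Topology

H_D_A = "H_D_A"
DHA_SUPPLEMENT = "DHA_supplement"

NodeKey = tuple


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criteria (Å, degrees)."""

    d_max: float = 3.5
    angle_max: float = 60.0
    angle_convention: str = H_D_A

    def __post_init__(self):
        if self.d_max <= 0:
            raise ParameterError("d_max must be positive")
        if not 0 < self.angle_max <= 180:
            raise ParameterError("angle_max must be in (0, 180]")
        if self.angle_convention not in (H_D_A, DHA_SUPPLEMENT):
            raise ParameterError(
                f"unknown angle convention {self.angle_convention!r}"
            )


@dataclass(frozen=True)
class HBondEvent:
    """One donor–H–acceptor triple satisfying the criteria in one frame."""

    frame_index: int
    donor_atom: int  # atom_id
    hydrogen: int
    acceptor_atom: int
    distance: float
    angle: float


@dataclass(frozen=True)
class BridgePath:
    """A direct or water-mediated connection between two non-water nodes."""

    frame_index: int
    endpoint_a: NodeKey
    endpoint_b: NodeKey
    n_waters: int
    water_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_waters != len(self.water_ids):
            raise PorenetError("n_waters must equal len(water_ids)")


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)


def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: HBondCriteria = HBondCriteria()) -> list[HBondEvent]:
    """Detect all H-bond triples in one frame.

    Donors/acceptors must have been assigned
    (:func:`porenet.chemistry.assign_donors_acceptors`).  Pairs within the
    same residue are not evaluated: the analysis is residue-node based and
    intra-residue contacts are discarded downstream regardless.  The result
    is invariant to atom-order permutation and rigid translation.
    """
    if not topology.donor_atoms and not topology.acceptor_atoms:
        raise PorenetError("donors/acceptors not assigned on this topology")
    donors = np.array(topology.donor_atoms, dtype=int)
    acceptors = np.array(topology.acceptor_atoms, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []

    X = frame.coordinates
    box = frame.box
    d_xyz = X[donors]  # (nd, 3)
    a_xyz = X[acceptors]  # (na, 3)
    delta = minimum_image(d_xyz[:, None, :] - a_xyz[None, :, :], box)
    dist = np.linalg.norm(delta, axis=2)  # (nd, na)

    same_res = np.empty(dist.shape, dtype=bool)
    d_res = [(topology.chains[i], topology.resids[i]) for i in donors]
    a_res = [(topology.chains[i], topology.resids[i]) for i in acceptors]
    for r, dr in enumerate(d_res):
        same_res[r] = [dr == ar for ar in a_res]

    cand = np.argwhere((dist <= criteria.d_max) & ~same_res)
    events: list[HBondEvent] = []
    cos_max = np.cos(np.radians(criteria.angle_max))
    for di, ai in cand:
        d_idx = donors[di]
        a_idx = acceptors[ai]
        v_da = minimum_image(X[a_idx] - X[d_idx], box)
        for h_idx in topology.donor_hydrogens[d_idx]:
            v_dh = minimum_image(X[h_idx] - X[d_idx], box)
            if criteria.angle_convention == H_D_A:
                angle = _angle_deg(v_dh, v_da)
            else:
                v_hd = minimum_image(X[d_idx] - X[h_idx], box)
                v_ha = minimum_image(X[a_idx] - X[h_idx], box)
                angle = 180.0 - _angle_deg(v_hd, v_ha)
            if angle <= criteria.angle_max + 1e-12:
                events.append(
                    HBondEvent(
                        frame_index=frame.frame_index,
                        donor_atom=topology.atoms[d_idx].atom_id,
                        hydrogen=topology.atoms[h_idx].atom_id,
                        acceptor_atom=topology.atoms[a_idx].atom_id,
                        distance=float(dist[di, ai]),
                        angle=float(angle),
                    )
                )
    return events


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def hbond_node_graph(hbonds: Sequence[HBondEvent], topology: Topology) -> dict:
    """Residue-node adjacency implied by atom-level H-bond events.

    Multiple simultaneous atom contacts between the same two residues count
    once; intra-residue contacts are dropped; direction is ignored.
    """
    adj: dict[NodeKey, set[NodeKey]] = {}
    for ev in hbonds:
        u = topology.node_keys[topology.index_of(ev.donor_atom)]
        v = topology.node_keys[topology.index_of(ev.acceptor_atom)]
        if u is None or v is None or u == v:
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def water_bridges(hbonds: Sequence[HBondEvent], topology: Topology,
                  max_waters: int = 3, frame_index: int | None = None) -> list[BridgePath]:
    """Enumerate all direct and water-mediated bridges in one frame.

    For every pair of non-water nodes connected by an H-bond chain whose
    interior members are exclusively waters (at most ``max_waters``), emits a
    single :class:`BridgePath` with the minimum achievable water count.  When
    several minimal paths exist, ``water_ids`` records the lexicographically
    smallest water-id sequence (read from the smaller endpoint); only
    ``n_waters`` matters downstream.
    """
    if max_waters < 0:
        raise ParameterError("max_waters must be ≥ 0")
    if frame_index is None:
        frame_index = hbonds[0].frame_index if hbonds else 0
    adj = hbond_node_graph(hbonds, topology)
    nonwater = sorted(k for k in adj if k[0] != "wat")

    best: dict[tuple[NodeKey, NodeKey], tuple[int, tuple[int, ...]]] = {}

    def consider(u: NodeKey, v: NodeKey, n: int, path: tuple[int, ...]):
        key = (u, v) if u <= v else (v, u)
        if key[0] == u:
            cand = (n, path)
        else:
            cand = (n, tuple(reversed(path)))
        if key not in best or cand < best[key]:
            best[key] = cand

    for u in nonwater:
        # direct H-bonds
        for v in adj[u]:
            if v[0] != "wat" and u < v:
                consider(u, v, 0, ())
        if max_waters == 0:
            continue
        # Dijkstra over waters with (depth, path) as the order key, so the
        # first finalization of a water carries the lexicographically smallest
        # minimal-depth path from u.
        done: set[NodeKey] = set()
        heap: list[tuple[int, tuple[int, ...], NodeKey]] = []
        for w in adj[u]:
            if w[0] == "wat":
                heapq.heappush(heap, (1, (w[1],), w))
        while heap:
            depth, path, w = heapq.heappop(heap)
            if w in done:
                continue
            done.add(w)
            for v in adj[w]:
                if v[0] == "wat":
                    if depth < max_waters and v not in done:
                        heapq.heappush(heap, (depth + 1, path + (v[1],), v))
                elif v != u:
                    consider(u, v, depth, path)

    return [
        BridgePath(frame_index, a, b, n, path)
        for (a, b), (n, path) in sorted(best.items())
    ]
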
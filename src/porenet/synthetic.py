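"""Synthetic pore fixtures with fully known ground truth.

Builds desk-scale topology + trajectory fixtures of an idealized octameric
transmembrane peptide pore: rigid pseudo-helices on a ring, surrogate
side-chain donor/acceptor sites (a single O–H pair per polar residue, not a
rotamer), lipid molecules reduced to a phosphate group (P with two acceptor
oxygens), and waters.  Every H-bond edge of the eventual network is *planted*:
for each scheduled-present frame the endpoint sites and bridging waters are
placed so that the geometric criteria hold exactly, and for absent frames the
relevant distance is violated by at least 0.5 Å (waters are parked in a far
reservoir; direct-edge endpoints are pulled to 4.0 Å).  The accompanying
:class:`GroundTruthManifest` records the realized per-edge occupancies,
water counts, lipid shell membership, phosphate depths, and per-frame
water-column spanning flags, so that every analysis stage can be verified
against construction.

This is not a physical simulator: there are no forces and no dynamics, only
scheduled geometric constructions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .errors import GenerationError, InputError, ParameterError
from .hbonds import NodeKey
from .trajectory import AtomRecord, Frame, Topology, write_pdb, write_text_trajectory

OH = 0.96  # covalent O–H length, Å
HBOND_GAP = 2.8  # target O···O spacing inside bridges, Å
GAP_MIN, GAP_MAX = 2.4, 3.3  # admissible straight-chain spacing, Å
DIRECT_PRESENT = 2.9  # heavy-atom distance of a present direct H-bond, Å
DIRECT_ABSENT = 4.0  # ≥ 0.5 Å beyond the 3.5 Å cutoff
CONTINUOUS = "continuous"
GAPPED = "gapped"


@dataclass(frozen=True)
class PlantedEdge:
    """One ground-truth network edge.

    ``presence_prob`` draws a Bernoulli schedule from the spec seed unless an
    explicit per-frame ``presence`` pattern is given.
    """

    node_a: NodeKey
    node_b: NodeKey
    n_waters: int
    presence_prob: float = 1.0
    presence: tuple[bool, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.n_waters <= 3:
            raise ParameterError("n_waters must be in 0…3")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ParameterError("presence_prob must be in [0, 1]")
        for n in (self.node_a, self.node_b):
            if n[0] not in ("pep", "lip"):
                raise ParameterError(f"edge endpoint {n} must be pep or lip")
        if self.node_a == self.node_b:
            raise ParameterError("self-edges are not allowed")

    @property
    def pair(self) -> tuple[NodeKey, NodeKey]:
        return tuple(sorted((self.node_a, self.node_b)))


@dataclass
class SyntheticPoreSpec:
    """Plan of a synthetic pore system (all lengths Å, times ps)."""

    n_peptides: int = 8
    residues_per_peptide: int = 26
    ring_radius: float = 15.0
    phosphate_plane_z: float = 19.0
    planted_edges: tuple[PlantedEdge, ...] = ()
    planted_deep_phosphates: tuple[tuple[int, float], ...] = ()
    water_column: str = CONTINUOUS
    n_frames: int = 100
    frame_interval_ps: float = 10.0
    seed: int = 0
    # geometry knobs (defaults mirror a membrane-spanning 26-residue helix
    # bundle in a bilayer with phosphate planes at ±19 Å)
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    side_chain_length: float = 1.8
    wheel_phase_deg: float = 180.0  # residue 1 faces the pore axis
    box: tuple[float, float, float] = (110.0, 110.0, 90.0)
    n_bulk_lipids_per_leaflet: int = 16
    lipid_shell: float = 15.0
    deep_threshold: float = 5.0
    extra_polar_positions: tuple[int, ...] = ()
    #: rigid z displacement per peptide (Å, positive = outward through the
    #: upper leaflet); models peptides moving from inserted toward
    #: interfacial positions
    peptide_z_offsets: tuple[float, ...] = ()

    def __post_init__(self):
        if self.ring_radius <= 0:
            raise ParameterError("ring_radius must be positive")
        if self.n_peptides < 1 or self.n_peptides > 26:
            raise ParameterError("n_peptides must be in 1…26")
        if self.water_column not in (CONTINUOUS, GAPPED):
            raise ParameterError(f"unknown water_column mode {self.water_column!r}")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be ≥ 1")
        for e in self.planted_edges:
            for n in (e.node_a, e.node_b):
                if n[0] == "pep" and not (
                    1 <= n[1] <= self.n_peptides
                    and 1 <= n[2] <= self.residues_per_peptide
                ):
                    raise ParameterError(f"edge endpoint {n} outside the pore")
            if e.presence is not None and len(e.presence) != self.n_frames:
                raise ParameterError("explicit presence pattern length != n_frames")
        if self.peptide_z_offsets and len(self.peptide_z_offsets) != self.n_peptides:
            raise ParameterError("peptide_z_offsets must list one offset per peptide")


@dataclass
class GroundTruthManifest:
    """Everything the analysis should recover from a generated system."""

    edge_pairs: list[tuple[NodeKey, NodeKey]]
    edge_n_waters: dict[tuple[NodeKey, NodeKey], int]
    presence: np.ndarray  # (n_edges, n_frames) bool
    lipid_nodes: set[NodeKey]  # pore-shell lipids
    lipid_depths: dict[int, float]  # lipid_id → P depth toward bilayer center
    deep_threshold: float
    water_spanning: list[bool]
    n_frames: int
    n_side_chain_sites: int
    n_lipid_acceptor_oxygens: int

    def occupancy_pct(self, pair: tuple[NodeKey, NodeKey]) -> float:
        i = self.edge_pairs.index(pair)
        return 100.0 * float(np.mean(self.presence[i]))

    def expected_edges(self, min_occupancy_pct: float,
                       max_waters: int = 3,
                       include_lipid_lipid: bool = False) -> dict:
        """Edge → occupancy for edges surviving the given filters."""
        out = {}
        for i, pair in enumerate(self.edge_pairs):
            if self.edge_n_waters[pair] > max_waters:
                continue
            if not include_lipid_lipid and pair[0][0] == "lip" and pair[1][0] == "lip":
                continue
            occ = 100.0 * float(np.mean(self.presence[i]))
            if occ >= min_occupancy_pct and occ > 0:
                out[pair] = occ
        return out

    def expected_deep_count(self, threshold: float | None = None) -> int:
        t = self.deep_threshold if threshold is None else threshold
        return sum(1 for d in self.lipid_depths.values() if d >= t)

    def expected_bridge_counts(self, max_waters: int = 3) -> tuple[np.ndarray, np.ndarray]:
        """(direct, water-bridged) side-chain pair counts per frame."""
        direct = np.zeros(self.n_frames, dtype=int)
        watered = np.zeros(self.n_frames, dtype=int)
        for i, pair in enumerate(self.edge_pairs):
            if pair[0][0] != "pep" or pair[1][0] != "pep":
                continue
            w = self.edge_n_waters[pair]
            if w > max_waters:
                continue
            target = direct if w == 0 else watered
            target += self.presence[i].astype(int)
        return direct, watered

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "edges": [
                {
                    "node_a": _key_str(a), "node_b": _key_str(b),
                    "n_waters": self.edge_n_waters[(a, b)],
                    "presence": [int(x) for x in self.presence[i]],
                }
                for i, (a, b) in enumerate(self.edge_pairs)
            ],
            "lipid_nodes": sorted(_key_str(k) for k in self.lipid_nodes),
            "lipid_depths": {str(k): v for k, v in self.lipid_depths.items()},
            "deep_threshold": self.deep_threshold,
            "water_spanning": [bool(x) for x in self.water_spanning],
            "n_frames": self.n_frames,
            "n_side_chain_sites": self.n_side_chain_sites,
            "n_lipid_acceptor_oxygens": self.n_lipid_acceptor_oxygens,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _key_str(key: NodeKey) -> str:
    return ":".join(str(x) for x in key)


# ---------------------------------------------------------------------------
# Presence schedules
# ---------------------------------------------------------------------------

def schedule_presence(spec: SyntheticPoreSpec, seed: int | None = None) -> np.ndarray:
    """(n_edges, n_frames) boolean presence matrix, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for e in spec.planted_edges:
        if e.presence is not None:
            rows.append(np.array(e.presence, dtype=bool))
        elif e.presence_prob >= 1.0:
            rows.append(np.ones(spec.n_frames, dtype=bool))
        elif e.presence_prob <= 0.0:
            rows.append(np.zeros(spec.n_frames, dtype=bool))
        else:
            rows.append(rng.random(spec.n_frames) < e.presence_prob)
    return (np.array(rows) if rows
            else np.zeros((0, spec.n_frames), dtype=bool))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GenerationError("degenerate direction vector")
    return v / n


def _bridge_chain(a: np.ndarray, b: np.ndarray, n: int,
                  bow_hint: np.ndarray | None = None) -> np.ndarray:
    """Positions of ``n`` bridging waters between sites ``a`` and ``b``.

    Straight and equally spaced when the spacing lands in [2.4, 3.3] Å;
    otherwise bowed on a circular arc with 2.8 Å chords, displaced along
    ``bow_hint`` (outward from the pore axis when no hint is given).  Raises
    on geometry that would break the H-bond criteria or path minimality
    (direct shortcut, skip-a-water shortcut).
    """
    if n == 0:
        return np.zeros((0, 3))
    d = float(np.linalg.norm(b - a))
    if d <= DIRECT_ABSENT - 1e-9:
        raise GenerationError(
            f"bridge endpoints only {d:.2f} Å apart; a direct H-bond shortcut "
            "would break water-count minimality"
        )
    gap = d / (n + 1)
    if GAP_MIN <= gap <= GAP_MAX:
        return np.array([a + (j / (n + 1)) * (b - a) for j in range(1, n + 1)])
    if gap > GAP_MAX:
        raise GenerationError(
            f"bridge endpoints {d:.2f} Å apart cannot be spanned by {n} "
            "water(s)"
        )

    # Bowed arc: n+1 equal chords of HBOND_GAP each.  Cap the per-segment
    # half-angle at 45° so that skip-one chords stay above the 3.5 Å cutoff.
    ratio = d / HBOND_GAP  # in (1.43, n+1)

    def f(theta):
        return np.sin(theta / 2) / np.sin(theta / (2 * (n + 1))) - ratio

    theta_max = (n + 1) * (np.pi / 2) * 0.999
    try:
        theta = brentq(f, 1e-6, theta_max)
    except ValueError as exc:
        raise GenerationError(
            f"no feasible water arc for endpoints {d:.2f} Å apart with {n} "
            "water(s)"
        ) from exc
    r_c = d / (2 * np.sin(theta / 2))
    h = r_c * np.cos(theta / 2)

    u = _unit(b - a)
    m = 0.5 * (a + b)
    hint = (np.array([m[0], m[1], 0.0]) if bow_hint is None
            else np.asarray(bow_hint, float))
    w = hint - np.dot(hint, u) * u
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(u, np.array([1.0, 0.0, 0.0]))
    w = _unit(w)
    center = m - h * w

    a0 = np.arctan2(h, -d / 2)
    a1 = np.arctan2(h, d / 2)
    pts = []
    for j in range(1, n + 1):
        phi = a0 + (a1 - a0) * j / (n + 1)
        pts.append(center + r_c * (np.cos(phi) * u + np.sin(phi) * w))
    return np.array(pts)


# ---------------------------------------------------------------------------
# System builder
# ---------------------------------------------------------------------------

class _PoreBuilder:
    def __init__(self, spec: SyntheticPoreSpec):
        self.spec = spec
        self.plane = spec.phosphate_plane_z

    # ---- static geometry --------------------------------------------------
    def peptide_axis(self, pid: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        phi = 2 * np.pi * (pid - 1) / self.spec.n_peptides
        e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
        e_t = np.array([-np.sin(phi), np.cos(phi), 0.0])
        center = self.spec.ring_radius * e_r
        return center, e_r, e_t

    def residue_z(self, pos: int) -> float:
        mid = (self.spec.residues_per_peptide + 1) / 2
        return (pos - mid) * self.spec.helix_rise

    def wheel_direction(self, pid: int, pos: int) -> np.ndarray:
        _, e_r, e_t = self.peptide_axis(pid)
        theta = np.radians((pos - 1) * 100.0 + self.spec.wheel_phase_deg)
        return np.cos(theta) * e_r + np.sin(theta) * e_t

    def ca_position(self, pid: int, pos: int) -> np.ndarray:
        center, _, _ = self.peptide_axis(pid)
        u = self.wheel_direction(pid, pos)
        dz = 0.0
        if self.spec.peptide_z_offsets:
            dz = self.spec.peptide_z_offsets[pid - 1]
        return center + self.spec.helix_radius * u + \
            np.array([0, 0, self.residue_z(pos) + dz])

    def base_site(self, pid: int, pos: int) -> np.ndarray:
        return self.ca_position(pid, pos) + self.spec.side_chain_length * \
            self.wheel_direction(pid, pos)

    # ---- lipid placement --------------------------------------------------
    def place_lipids(self):
        """Decide lipid O1 anchor positions and record depths.

        Pore lipids are anchored either to the peptide endpoint of their
        planted edge (O1 placed a straight-chain length outward from the
        site) or, for lipids without a peptide partner, on a ring just
        outside the peptides at the upper phosphate plane.  Explicit deep
        phosphates sit near the pore axis at the requested depth.  Bulk
        lipids form outer rings at exactly ±plane z.
        """
        spec = self.spec
        self.lipid_o1: dict[int, np.ndarray] = {}
        self.pore_lipids: list[int] = []

        for e in spec.planted_edges:
            lips = [n for n in (e.node_a, e.node_b) if n[0] == "lip"]
            peps = [n for n in (e.node_a, e.node_b) if n[0] == "pep"]
            if not lips:
                continue
            if len(lips) == 2 and e.n_waters == 0:
                raise GenerationError(
                    "lipid–lipid direct edges are not constructible: surrogate "
                    "phosphates carry no hydrogen"
                )
            target = DIRECT_PRESENT if e.n_waters == 0 else HBOND_GAP * (e.n_waters + 1)
            for lip in lips:
                lid = lip[1]
                if lid in self.lipid_o1:
                    continue
                if peps:
                    site = self.base_site(peps[0][1], peps[0][2])
                    out = _unit(np.array([site[0], site[1], 0.0]))
                    self.lipid_o1[lid] = site + target * out
                else:
                    anchor = self._free_ring_position(lid)
                    if lips[0][1] in self.lipid_o1 and lid != lips[0][1]:
                        first = self.lipid_o1[lips[0][1]]
                        tang = _unit(np.cross(np.array([0, 0, 1.0]),
                                              np.array([first[0], first[1], 0.0])))
                        self.lipid_o1[lid] = first + target * tang
                    else:
                        self.lipid_o1[lid] = anchor
                self.pore_lipids.append(lid)

        self.deep_lipids: set[int] = set()
        for lid, depth in spec.planted_deep_phosphates:
            if lid in self.lipid_o1:
                raise GenerationError(f"lipid {lid} placed twice")
            phi = 2 * np.pi * ((lid * 0.381966) % 1.0)
            r = 5.0
            # vertically oriented: P exactly at plane − depth, O1 above it
            self.lipid_o1[lid] = np.array([
                r * np.cos(phi), r * np.sin(phi), self.plane - depth + 1.6
            ])
            self.deep_lipids.add(lid)
            self.pore_lipids.append(lid)

        # bulk lipids: outer rings at exactly ±plane
        self.bulk_lipids: list[int] = []
        nb = spec.n_bulk_lipids_per_leaflet
        lid = 500
        for leaflet in (+1, -1):
            for j in range(nb):
                ring = 40.0 if j % 2 == 0 else 47.0
                phi = 2 * np.pi * j / nb + (0.2 if leaflet < 0 else 0.0)
                self.lipid_o1[lid] = np.array([
                    ring * np.cos(phi), ring * np.sin(phi),
                    leaflet * self.plane - leaflet * 1.6,  # O1 sits inward of P
                ])
                self.bulk_lipids.append(lid)
                lid += 1

    def _free_ring_position(self, lid: int) -> np.ndarray:
        phi = 2 * np.pi * ((lid * 0.618034) % 1.0)
        r = self.spec.ring_radius + 7.0
        return np.array([r * np.cos(phi), r * np.sin(phi), self.plane])

    def lipid_atoms_xyz(self, lid: int) -> np.ndarray:
        """(P, O1, O2) coordinates: P outward of O1 along the radial (bulk:
        along z so the phosphorus sits exactly on the leaflet plane)."""
        o1 = self.lipid_o1[lid]
        if lid in self.bulk_lipids:
            sign = 1.0 if o1[2] > 0 else -1.0
            p = np.array([o1[0], o1[1], sign * self.plane])
            o2 = p + np.array([1.5, 0.0, 0.0])
        elif lid in self.deep_lipids:
            sign = 1.0 if o1[2] >= 0 else -1.0
            p = o1 - sign * np.array([0.0, 0.0, 1.6])
            o2 = p - sign * np.array([0.0, 0.0, 1.5])
        else:
            out = _unit(np.array([o1[0], o1[1], 0.0]))
            p = o1 + 1.6 * out
            o2 = p + 1.5 * out
        return np.array([p, o1, o2])

    # ---- water column -----------------------------------------------------
    def column_z(self) -> np.ndarray:
        top = self.plane + 2.8
        zs = np.arange(top, -(self.plane + 2.8) - 1e-9, -2.6)
        if self.spec.water_column == GAPPED:
            zs = zs[np.abs(zs) >= 2.6]
        return zs


def build_pore_system(spec: SyntheticPoreSpec, validate: bool = True
                      ) -> tuple[Topology, list[Frame], GroundTruthManifest]:
    """Construct topology, frames, and ground truth for a synthetic pore.

    Fully reproducible from ``spec.seed``.  With ``validate=True`` every frame
    is checked for unintended close contacts between polar heavy atoms (any
    pair ≤ 3.6 Å that is not a planted H-bond raises
    :class:`~porenet.errors.GenerationError`), so planted occupancies are
    guaranteed exact by construction.
    """
    b = _PoreBuilder(spec)
    presence = schedule_presence(spec)
    edges = list(spec.planted_edges)
    pairs = [e.pair for e in edges]
    if len(set(pairs)) != len(pairs):
        raise GenerationError("duplicate planted edges")

    # each node may take part in at most one direct edge (its site position
    # is repositioned to toggle that edge)
    direct_partner: dict[NodeKey, NodeKey] = {}
    for e in edges:
        if e.n_waters == 0:
            for n, m in ((e.node_a, e.node_b), (e.node_b, e.node_a)):
                if n in direct_partner:
                    raise GenerationError(
                        f"node {n} takes part in two direct edges; its site "
                        "cannot toggle both"
                    )
                direct_partner[n] = m

    b.place_lipids()

    polar_positions = sorted(
        {n[2] for e in edges for n in (e.node_a, e.node_b) if n[0] == "pep"}
        | set(spec.extra_polar_positions)
    )

    # ------------------------------------------------------------- topology
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    aid = 0

    def add(name, element, resid, resname, chain, cls):
        nonlocal aid
        aid += 1
        atoms.append(AtomRecord(aid, name, element, resid, resname, chain, cls))
        return aid

    site_o_index: dict[NodeKey, int] = {}  # node → atom list index of OG
    site_h_index: dict[NodeKey, int] = {}
    ca_index: dict[NodeKey, int] = {}
    for pid in range(1, spec.n_peptides + 1):
        chain = chr(ord("A") + pid - 1)
        for pos in range(1, spec.residues_per_peptide + 1):
            node = ("pep", pid, pos)
            if pos in polar_positions:
                ca = add("CA", "C", pos, "PSC", chain, "peptide")
                og = add("OG", "O", pos, "PSC", chain, "peptide")
                hg = add("HG", "H", pos, "PSC", chain, "peptide")
                bonds.append((og, hg))
                ca_index[node] = ca - 1
                site_o_index[node] = og - 1
                site_h_index[node] = hg - 1
            else:
                ca = add("CA", "C", pos, "APO", chain, "peptide")
                ca_index[node] = ca - 1

    lipid_atom_index: dict[int, tuple[int, int, int]] = {}
    for lid in sorted(b.lipid_o1):
        p = add("P", "P", lid, "PHO", "L", "lipid")
        o1 = add("O1", "O", lid, "PHO", "L", "lipid")
        o2 = add("O2", "O", lid, "PHO", "L", "lipid")
        bonds.extend([(p, o1), (p, o2)])
        lipid_atom_index[lid] = (p - 1, o1 - 1, o2 - 1)

    # waters: bridge waters per edge, then the column
    edge_water_index: list[list[tuple[int, int, int]]] = []
    wid = 0
    water_ids_per_edge: list[list[int]] = []
    for e in edges:
        trip, ids = [], []
        for _ in range(e.n_waters):
            wid += 1
            o = add("O", "O", wid, "HOH", "W", "water")
            h1 = add("H1", "H", wid, "HOH", "W", "water")
            h2 = add("H2", "H", wid, "HOH", "W", "water")
            bonds.extend([(o, h1), (o, h2)])
            trip.append((o - 1, h1 - 1, h2 - 1))
            ids.append(wid)
        edge_water_index.append(trip)
        water_ids_per_edge.append(ids)
    column_index: list[tuple[int, int, int]] = []
    for z in b.column_z():
        wid += 1
        o = add("O", "O", wid, "HOH", "W", "water")
        h1 = add("H1", "H", wid, "HOH", "W", "water")
        h2 = add("H2", "H", wid, "HOH", "W", "water")
        bonds.extend([(o, h1), (o, h2)])
        column_index.append((o - 1, h1 - 1, h2 - 1))

    topology = Topology(atoms, bonds)
    n_atoms = len(atoms)

    # ------------------------------------------------- per-frame coordinates
    box = np.array(spec.box, dtype=float)
    reservoir = _reservoir_positions(wid)

    base_sites = {n: b.base_site(n[1], n[2]) for n in site_o_index}

    def site_position(node: NodeKey, present_direct: dict[NodeKey, bool]) -> np.ndarray:
        """Current site O position, honoring direct-edge toggling."""
        if node not in direct_partner:
            return base_sites[node]
        partner = direct_partner[node]
        d = DIRECT_PRESENT if present_direct[node] else DIRECT_ABSENT
        if partner[0] == "lip":
            o1 = b.lipid_o1[partner[1]]
            u = _unit(base_sites[node] - o1)
            return o1 + d * u
        m = 0.5 * (base_sites[node] + base_sites[partner])
        u = _unit(base_sites[partner] - base_sites[node])
        return m - 0.5 * d * u

    def endpoint_position(node: NodeKey, present_direct) -> np.ndarray:
        if node[0] == "lip":
            return b.lipid_o1[node[1]]
        return site_position(node, present_direct)

    frames: list[Frame] = []
    spanning: list[bool] = []
    column_spans = spec.water_column == CONTINUOUS

    for f in range(spec.n_frames):
        X = np.zeros((n_atoms, 3))
        present_direct: dict[NodeKey, bool] = {}
        for i, e in enumerate(edges):
            if e.n_waters == 0:
                present_direct[e.node_a] = bool(presence[i, f])
                present_direct[e.node_b] = bool(presence[i, f])

        # peptide atoms
        for node, ci in ca_index.items():
            X[ci] = b.ca_position(node[1], node[2])
        site_pos: dict[NodeKey, np.ndarray] = {}
        for node, oi in site_o_index.items():
            pos = site_position(node, present_direct)
            site_pos[node] = pos
            X[oi] = pos
            # default H direction: along the side-chain vector
            h_dir = _unit(pos - X[ca_index[node]])
            if node in direct_partner and present_direct.get(node, False):
                partner = direct_partner[node]
                target = endpoint_position(partner, present_direct)
                # designate the lexicographically smaller peptide endpoint as
                # the donor; a peptide always donates to a lipid partner
                if partner[0] == "lip" or node < partner:
                    h_dir = _unit(target - pos)
                else:
                    h_dir = _unit(pos - target)
            X[site_h_index[node]] = pos + OH * h_dir

        # lipids (static)
        for lid, (pi, o1i, o2i) in lipid_atom_index.items():
            X[[pi, o1i, o2i]] = b.lipid_atoms_xyz(lid)

        # bridge waters
        for i, e in enumerate(edges):
            trip = edge_water_index[i]
            if not trip:
                continue
            if presence[i, f]:
                a = endpoint_position(e.node_a, present_direct)
                c = endpoint_position(e.node_b, present_direct)
                hint = None
                if (e.node_a[0] == "pep" and e.node_b[0] == "pep"
                        and e.node_a[1] == e.node_b[1]):
                    # intra-peptide bridge: bow away from the helix axis
                    axis_center, _, _ = b.peptide_axis(e.node_a[1])
                    m = 0.5 * (a + c)
                    hint = np.array([m[0] - axis_center[0],
                                     m[1] - axis_center[1], 0.0])
                chain_pts = _bridge_chain(a, c, e.n_waters, bow_hint=hint)
                nodes_chain = [a, *chain_pts, c]
                for j, (oi, h1i, h2i) in enumerate(trip):
                    o = nodes_chain[j + 1]
                    X[oi] = o
                    X[h1i] = o + OH * _unit(nodes_chain[j] - o)
                    X[h2i] = o + OH * _unit(nodes_chain[j + 2] - o)
            else:
                for j, (oi, h1i, h2i) in enumerate(trip):
                    o = reservoir[water_ids_per_edge[i][j] - 1]
                    X[oi] = o
                    X[h1i] = o + np.array([OH, 0, 0])
                    X[h2i] = o + OH * np.array([np.cos(1.82), np.sin(1.82), 0])

        # column waters
        zs = b.column_z()
        for j, (oi, h1i, h2i) in enumerate(column_index):
            o = np.array([0.0, 0.0, zs[j]])
            X[oi] = o
            nxt = np.array([0.0, 0.0, zs[j + 1]]) if j + 1 < len(zs) else o + np.array([0, 0, -2.6])
            X[h1i] = o + OH * _unit(nxt - o)
            X[h2i] = o + np.array([OH, 0.0, 0.0])

        frames.append(Frame(f, (f + 1) * spec.frame_interval_ps, box.copy(), X))
        spanning.append(column_spans)

    # ---------------------------------------------------------------- truth
    depths = {}
    for lid in b.lipid_o1:
        p_z = b.lipid_atoms_xyz(lid)[0][2]
        if p_z >= 0:
            depths[lid] = b.plane - p_z
        else:
            depths[lid] = p_z + b.plane
    manifest = GroundTruthManifest(
        edge_pairs=pairs,
        edge_n_waters={e.pair: e.n_waters for e in edges},
        presence=presence,
        lipid_nodes={("lip", lid) for lid in b.pore_lipids},
        lipid_depths=depths,
        deep_threshold=spec.deep_threshold,
        water_spanning=spanning,
        n_frames=spec.n_frames,
        n_side_chain_sites=len(site_o_index),
        n_lipid_acceptor_oxygens=2 * len(b.lipid_o1),
    )

    if validate:
        _validate_system(spec, b, topology, frames, edges, presence,
                         site_o_index, lipid_atom_index, edge_water_index,
                         column_index)
    return topology, frames, manifest


def _reservoir_positions(n_waters: int) -> np.ndarray:
    """Far-field parking grid for scheduled-absent bridge waters (5 Å pitch,
    well above the upper leaflet, nothing within H-bond range)."""
    pts = []
    for i in range(n_waters):
        pts.append([
            -45.0 + 5.0 * (i % 19),
            -45.0 + 5.0 * ((i // 19) % 19),
            34.0 + 5.0 * (i // 361),
        ])
    return np.array(pts) if pts else np.zeros((0, 3))


def _validate_system(spec, b, topology, frames, edges, presence,
                     site_o_index, lipid_atom_index, edge_water_index,
                     column_index):
    """Reject any geometry in which an unintended polar pair falls ≤ 3.6 Å."""
    polar = {}
    for node, oi in site_o_index.items():
        polar[oi] = ("site", node)
    for lid, (pi, o1i, o2i) in lipid_atom_index.items():
        polar[o1i] = ("lip", lid)
        polar[o2i] = ("lip", lid)
    for i, trip in enumerate(edge_water_index):
        for j, (oi, _, _) in enumerate(trip):
            polar[oi] = ("edgewat", i, j)
    for j, (oi, _, _) in enumerate(column_index):
        polar[oi] = ("colwat", j)
    idx = sorted(polar)
    tags = [polar[i] for i in idx]

    # shell distances checked once (lipids are static)
    pep_idx = topology.atom_indices("peptide")
    X0 = frames[-1].coordinates
    for lid, (pi, o1i, o2i) in lipid_atom_index.items():
        dmin = min(
            float(np.min(np.linalg.norm(X0[pep_idx] - X0[k], axis=1)))
            for k in (pi, o1i, o2i)
        )
        if lid in b.pore_lipids and dmin > spec.lipid_shell - 0.1:
            raise GenerationError(
                f"pore lipid {lid} lies {dmin:.1f} Å from the peptide, outside "
                f"the {spec.lipid_shell} Å shell"
            )
        if lid in b.bulk_lipids and dmin < spec.lipid_shell + 0.1:
            raise GenerationError(
                f"bulk lipid {lid} lies {dmin:.1f} Å from the peptide, inside "
                f"the {spec.lipid_shell} Å shell"
            )

    for f, frame in enumerate(frames):
        allowed: set[tuple[int, int]] = set()

        def allow(i, j):
            allowed.add((min(i, j), max(i, j)))

        for i, e in enumerate(edges):
            if not presence[i, f]:
                continue
            ep = []
            for n in (e.node_a, e.node_b):
                if n[0] == "pep":
                    ep.append(site_o_index[n])
                else:
                    ep.append(lipid_atom_index[n[1]][1])
            chain = [ep[0]] + [t[0] for t in edge_water_index[i]] + [ep[1]]
            for u, v in zip(chain, chain[1:]):
                allow(u, v)
        col = [t[0] for t in column_index]
        for u, v in zip(col, col[1:]):
            allow(u, v)

        X = frame.coordinates[idx]
        d = cdist(X, X)
        close = np.argwhere(np.triu(d <= 3.6, k=1))
        for r, c in close:
            i, j = idx[r], idx[c]
            if (min(i, j), max(i, j)) in allowed:
                continue
            # same residue (lipid O1/O2) pairs are harmless
            ti, tj = tags[r], tags[c]
            if ti[0] == "lip" and tj[0] == "lip" and ti[1] == tj[1]:
                continue
            raise GenerationError(
                f"frame {f}: unintended contact between {ti} and {tj} at "
                f"{d[r, c]:.2f} Å"
            )


# ---------------------------------------------------------------------------
# Fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(topology: Topology, frames: Sequence[Frame],
                  out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.pdb`` (topology, frame-0 coordinates, CONECT bonds)
    and ``<prefix>.traj`` (text trajectory).  Round-trips exactly through
    :func:`porenet.trajectory.load_topology` / ``read_text_trajectory``."""
    frames = list(frames)
    if not frames:
        raise InputError("refusing to write a fixture with no frames")
    out_prefix = Path(out_prefix)
    pdb = out_prefix.with_suffix(".pdb")
    traj = out_prefix.with_suffix(".traj")
    write_pdb(topology, frames[0].coordinates, pdb)
    write_text_trajectory(frames, traj)
    return pdb, traj


def default_pore_spec(n_frames: int = 100, seed: int = 0,
                      water_column: str = CONTINUOUS) -> SyntheticPoreSpec:
    """The stock octamer test system: 8 peptides × 26 residues.

    Plants, per peptide: one two-water inter-peptide bridge (residues 18–19
    of neighboring peptides), one two-water intra-peptide bridge (4–8, one
    helix turn), one direct side-chain pair (8–11), and one single-water
    peptide–lipid bridge at residue 7; plus one water-bridged lipid–lipid
    pair (exercises graph pruning) and three explicitly deep phosphates near
    the pore axis.  Presence probabilities span 0.6–0.9 so occupancies
    straddle the 30% display threshold companions (20%/50%) used in
    filtering tests.
    """
    edges = []
    n = 8
    for k in range(1, n + 1):
        nxt = k % n + 1
        edges.append(PlantedEdge(("pep", k, 18), ("pep", nxt, 19), 2, 0.9))
        edges.append(PlantedEdge(("pep", k, 4), ("pep", k, 8), 2, 0.6))
        edges.append(PlantedEdge(("pep", k, 8), ("pep", k, 11), 0, 0.7))
        edges.append(PlantedEdge(("pep", k, 7), ("lip", k), 1, 0.8))
    edges.append(PlantedEdge(("lip", 21), ("lip", 22), 1, 1.0))
    return SyntheticPoreSpec(
        planted_edges=tuple(edges),
        planted_deep_phosphates=((31, 8.0), (32, 6.5), (33, 9.5)),
        water_column=water_column,
        n_frames=n_frames,
        seed=seed,
    )
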
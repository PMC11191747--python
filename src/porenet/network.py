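"""Occupancy-filtered H-bond network graphs.

Aggregates per-frame bridges into a residue-level graph: nodes are peptide
side chains and lipid phosphate groups (one node per lipid molecule), edges
are direct or water-mediated H-bonds.  The *occupancy* of an edge is the
percentage of analyzed frames in which any qualifying bridge connects the two
nodes.  Graphs are displayed at a minimum occupancy (30% by default; 20% is
useful for more dynamic water-mediated connections), lipid–lipid edges are
excluded, and lipid nodes that lose all peptide connections are pruned.

Only lipid phosphates within a shell (15 Å by default) of any peptide atom in
the *final* analyzed frame enter the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .hbonds import BridgePath, HBondCriteria, NodeKey, detect_hbonds, minimum_image, water_bridges
from .trajectory import Frame, LIPID, PEPTIDE, Topology

logger = logging.getLogger(__name__)

SIDE_CHAIN = "side_chain"
LIPID_PHOSPHATE = "lipid_phosphate"


@dataclass(frozen=True)
class GraphNode:
    kind: str
    peptide_id: int | None = None
    residue_position: int | None = None
    lipid_id: int | None = None

    @property
    def key(self) -> NodeKey:
        if self.kind == SIDE_CHAIN:
            return ("pep", self.peptide_id, self.residue_position)
        return ("lip", self.lipid_id)

    @property
    def label(self) -> str:
        if self.kind == SIDE_CHAIN:
            return f"p{self.peptide_id}:r{self.residue_position}"
        return f"lipid{self.lipid_id}"

    @staticmethod
    def from_key(key: NodeKey) -> "GraphNode":
        if key[0] == "pep":
            return GraphNode(SIDE_CHAIN, peptide_id=key[1], residue_position=key[2])
        if key[0] == "lip":
            return GraphNode(LIPID_PHOSPHATE, lipid_id=key[1])
        raise InputError(f"not a graph node key: {key}")


@dataclass(frozen=True)
class GraphEdge:
    node_a: NodeKey
    node_b: NodeKey
    occupancy_pct: float
    mean_waters: float
    direct_pct: float

    @property
    def pair(self) -> tuple[NodeKey, NodeKey]:
        return (self.node_a, self.node_b)


@dataclass
class HBondNetwork:
    nodes: set[NodeKey]
    edges: dict[tuple[NodeKey, NodeKey], GraphEdge]
    n_frames_analyzed: int
    criteria: HBondCriteria
    max_waters: int
    min_occupancy_pct: float
    residues_per_peptide: int = 0
    n_peptides: int = 0

    def edge_list(self) -> list[GraphEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def lipid_nodes(self) -> set[NodeKey]:
        return {n for n in self.nodes if n[0] == "lip"}

    def side_chain_nodes(self) -> set[NodeKey]:
        return {n for n in self.nodes if n[0] == "pep"}


# ---------------------------------------------------------------------------
# Lipid shell selection
# ---------------------------------------------------------------------------

def select_lipid_nodes(final_frame: Frame, topology: Topology,
                       shell: float = 15.0) -> set[NodeKey]:
    """Lipid nodes whose phosphate group lies within ``shell`` Å of the pore.

    Membership is decided once, on the final analyzed frame: a lipid is
    included when the minimum-image distance from any of its phosphate-group
    heavy atoms (P and its oxygens; all heavy lipid atoms if no P is present)
    to any peptide atom is ≤ ``shell``.
    """
    lip_idx = topology.atom_indices(LIPID)
    pep_idx = topology.atom_indices(PEPTIDE)
    if lip_idx.size == 0:
        logger.warning("topology contains no lipid atoms; lipid node set is empty")
        return set()
    if pep_idx.size == 0:
        raise InputError("topology contains no peptide atoms")

    # phosphate-group atoms: P plus oxygens; fall back to all heavies
    probe = [
        i for i in lip_idx
        if topology.elements[i] in ("P", "O")
    ]
    if not probe:
        probe = [i for i in lip_idx if topology.elements[i] != "H"]

    X = final_frame.coordinates
    box = final_frame.box
    pep_xyz = X[pep_idx]
    selected: set[NodeKey] = set()
    for i in probe:
        key = topology.node_keys[i]
        if key in selected:
            continue
        d = np.linalg.norm(minimum_image(pep_xyz - X[i], box), axis=1)
        if float(d.min()) <= shell:
            selected.add(key)
    return selected


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def frame_bridges(frame: Frame, topology: Topology, criteria: HBondCriteria,
                  max_waters: int, lipid_nodes: set[NodeKey] | None = None
                  ) -> list[BridgePath]:
    """Per-frame bridge set restricted to side chains and shell lipids."""
    events = detect_hbonds(frame, topology, criteria)
    bridges = water_bridges(events, topology, max_waters, frame.frame_index)
    out = []
    for b in bridges:
        keep = True
        for ep in (b.endpoint_a, b.endpoint_b):
            if ep[0] == "lip" and (lipid_nodes is None or ep not in lipid_nodes):
                keep = False
        if keep:
            out.append(b)
    return out


def build_network(frames: Sequence[Frame], topology: Topology,
                  criteria: HBondCriteria = HBondCriteria(),
                  max_waters: int = 3,
                  lipid_nodes: set[NodeKey] | None = None,
                  min_occupancy_pct: float = 30.0) -> HBondNetwork:
    """Build the occupancy-filtered H-bond network over a frame subset.

    ``occupancy_pct`` of an edge is ``100 × (frames with a bridge) /
    n_frames_analyzed``; edges below ``min_occupancy_pct`` are dropped, then
    lipid–lipid edges and lipid nodes without a peptide connection are pruned.
    """
    frames = list(frames)
    if not frames:
        raise InputError("build_network requires a nonempty frame subset")
    if lipid_nodes is None:
        lipid_nodes = set()

    present: dict[tuple[NodeKey, NodeKey], list[int]] = {}
    for frame in frames:
        for b in frame_bridges(frame, topology, criteria, max_waters, lipid_nodes):
            present.setdefault((b.endpoint_a, b.endpoint_b), []).append(b.n_waters)

    n = len(frames)
    edges: dict[tuple[NodeKey, NodeKey], GraphEdge] = {}
    for pair, waters in present.items():
        occ = 100.0 * len(waters) / n
        if occ < min_occupancy_pct:
            continue
        direct = sum(1 for w in waters if w == 0)
        edges[pair] = GraphEdge(
            node_a=pair[0], node_b=pair[1],
            occupancy_pct=occ,
            mean_waters=float(np.mean(waters)),
            direct_pct=100.0 * direct / len(waters),
        )

    nodes: set[NodeKey] = {
        k for k in set(topology.node_keys) - {None} if k[0] == "pep"
    }
    net = HBondNetwork(
        nodes=nodes, edges=edges, n_frames_analyzed=n, criteria=criteria,
        max_waters=max_waters, min_occupancy_pct=min_occupancy_pct,
        residues_per_peptide=topology.residues_per_peptide,
        n_peptides=topology.n_peptides,
    )
    _prune(net)
    return net


def _prune(net: HBondNetwork) -> None:
    """Drop lipid–lipid edges and lipid nodes without a side-chain edge."""
    net.edges = {
        pair: e for pair, e in net.edges.items()
        if not (pair[0][0] == "lip" and pair[1][0] == "lip")
    }
    connected_lipids = set()
    for a, b in net.edges:
        for x in (a, b):
            if x[0] == "lip":
                connected_lipids.add(x)
    net.nodes = {n for n in net.nodes if n[0] != "lip"} | connected_lipids


def occupancy_filter(network: HBondNetwork, threshold_pct: float) -> HBondNetwork:
    """Retain edges with occupancy ≥ ``threshold_pct`` and re-prune lipids.

    Raising the threshold never adds edges, so edge sets are nested across
    thresholds (e.g. 20% ⊇ 30% ⊇ 50%).
    """
    if not 0 <= threshold_pct <= 100:
        raise ParameterError("threshold_pct must lie in [0, 100]")
    out = HBondNetwork(
        nodes=set(network.nodes),
        edges={p: e for p, e in network.edges.items()
               if e.occupancy_pct >= threshold_pct},
        n_frames_analyzed=network.n_frames_analyzed,
        criteria=network.criteria,
        max_waters=network.max_waters,
        min_occupancy_pct=max(network.min_occupancy_pct, threshold_pct),
        residues_per_peptide=network.residues_per_peptide,
        n_peptides=network.n_peptides,
    )
    _prune(out)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-residue interaction counts, summed over all peptides.

    ``counts[i]`` is the number of edge incidences at residue position
    ``i + 1``.  The sum equals ``2·E_pp + E_pl`` where ``E_pp`` is the number
    of side-chain–side-chain edges and ``E_pl`` the side-chain–lipid edges.
    """

    counts: np.ndarray
    weighted: bool = False

    def __getitem__(self, position: int) -> float:
        return self.counts[position - 1]

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.counts, index=np.arange(1, len(self.counts) + 1),
            name="interactions",
        )


def density_profile(network: HBondNetwork, weighted: bool = False) -> DensityProfile:
    """Interactions per residue position, aggregated across peptides.

    Each side-chain–side-chain edge increments both endpoint positions; each
    side-chain–lipid edge increments the side-chain position.  With
    ``weighted=True`` increments are occupancy fractions instead of unit
    counts.
    """
    r = network.residues_per_peptide
    if r == 0:
        positions = [n[2] for n in network.nodes if n[0] == "pep"]
        r = max(positions) if positions else 0
    counts = np.zeros(r, dtype=float)
    for e in network.edges.values():
        w = e.occupancy_pct / 100.0 if weighted else 1.0
        for ep in (e.node_a, e.node_b):
            if ep[0] == "pep":
                counts[ep[2] - 1] += w
    if not weighted:
        counts = counts.astype(int)
    return DensityProfile(counts=counts, weighted=weighted)


def count_peptide_lipid_edges(network: HBondNetwork) -> int:
    """Number of edges with exactly one lipid endpoint."""
    return sum(
        1 for a, b in network.edges
        if (a[0] == "lip") != (b[0] == "lip")
    )


def lipid_interaction_report(network: HBondNetwork,
                             thresholds: Sequence[float] = (20.0, 30.0)) -> dict[float, int]:
    """Peptide–lipid edge totals at several occupancy thresholds.

    On a simple residue-level graph, counting peptide–lipid *edges* and
    counting per-residue lipid *incidences* coincide (each edge touches
    exactly one side chain), so the remaining ambiguity in a printed
    lipid-interaction total is the occupancy threshold; this reports the
    count at each requested threshold.
    """
    return {
        t: count_peptide_lipid_edges(occupancy_filter(network, t))
        for t in thresholds
    }


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def to_networkx(network: HBondNetwork) -> nx.Graph:
    g = nx.Graph()
    for key in sorted(network.nodes):
        node = GraphNode.from_key(key)
        attrs = {"kind": node.kind, "label": node.label}
        if node.kind == SIDE_CHAIN:
            attrs.update(peptide_id=node.peptide_id,
                         residue_position=node.residue_position)
        else:
            attrs.update(lipid_id=node.lipid_id)
        g.add_node(node.label, **attrs)
    for e in network.edge_list():
        g.add_edge(
            GraphNode.from_key(e.node_a).label,
            GraphNode.from_key(e.node_b).label,
            occupancy_pct=round(e.occupancy_pct, 6),
            mean_waters=round(e.mean_waters, 6),
            direct_pct=round(e.direct_pct, 6),
        )
    return g


def export_network(network: HBondNetwork, path: str | Path,
                   format: str = "graph_markup") -> None:
    """Write the network as GraphML (``graph_markup``) or a TSV edge table."""
    path = Path(path)
    if format == "graph_markup":
        nx.write_graphml(to_networkx(network), path)
    elif format == "edge_table":
        edge_table(network).to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown export format {format!r}")


def edge_table(network: HBondNetwork) -> pd.DataFrame:
    rows = [
        {
            "node_a": GraphNode.from_key(e.node_a).label,
            "node_b": GraphNode.from_key(e.node_b).label,
            "occupancy_pct": round(e.occupancy_pct, 6),
            "mean_waters": round(e.mean_waters, 6),
            "direct_pct": round(e.direct_pct, 6),
        }
        for e in network.edge_list()
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "occupancy_pct",
                                       "mean_waters", "direct_pct"])


def _key_from_label(label: str) -> NodeKey:
    if label.startswith("lipid"):
        return ("lip", int(label[5:]))
    pep, res = label.split(":")
    return ("pep", int(pep[1:]), int(res[1:]))


def import_network(path: str | Path) -> HBondNetwork:
    """Re-import a GraphML export (attributes round-trip to 6 decimals)."""
    g = nx.read_graphml(str(path))
    nodes = {_key_from_label(n) for n in g.nodes}
    edges: dict[tuple[NodeKey, NodeKey], GraphEdge] = {}
    for a, b, data in g.edges(data=True):
        ka, kb = sorted((_key_from_label(a), _key_from_label(b)))
        edges[(ka, kb)] = GraphEdge(
            node_a=ka, node_b=kb,
            occupancy_pct=float(data["occupancy_pct"]),
            mean_waters=float(data["mean_waters"]),
            direct_pct=float(data["direct_pct"]),
        )
    return HBondNetwork(
        nodes=nodes, edges=edges, n_frames_analyzed=0,
        criteria=HBondCriteria(), max_waters=3, min_occupancy_pct=0.0,
    )
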
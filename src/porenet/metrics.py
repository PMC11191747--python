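"""Time-resolved and structural pore descriptors.

These quantify what a stable toroidal peptide nanopore looks like in a
simulation: how many side-chain bridges exist at each time point, how deep
lipid phosphates sit relative to their leaflet plane, how deep a chosen
tryptophan (position 19 by default) is inserted, and whether water is
connected across the bilayer through the pore.  The membrane normal is taken
to be the z axis throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .hbonds import HBondCriteria, minimum_image
from .network import frame_bridges, select_lipid_nodes
from .trajectory import Frame, LIPID, PEPTIDE, Topology, WATER

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bridge time series
# ---------------------------------------------------------------------------

@dataclass
class BridgeTimeSeries:
    """Per-frame counts of side-chain–side-chain bridges.

    ``direct_counts`` counts residue pairs connected with no intervening
    water, ``water_bridge_counts`` those with 1…max_waters waters; a pair is
    counted once per frame at its minimal water count, so
    ``total = direct + water_bridge`` at every frame.
    """

    times: np.ndarray
    direct_counts: np.ndarray
    water_bridge_counts: np.ndarray

    @property
    def total_counts(self) -> np.ndarray:
        return self.direct_counts + self.water_bridge_counts

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ps": self.times,
            "direct": self.direct_counts,
            "water_bridged": self.water_bridge_counts,
            "total": self.total_counts,
        })


def bridge_timeseries(frames: Sequence[Frame], topology: Topology,
                      criteria: HBondCriteria = HBondCriteria(),
                      max_waters: int = 3) -> BridgeTimeSeries:
    """Count side-chain bridges (direct and water-mediated) per frame."""
    frames = list(frames)
    if not frames:
        raise InputError("bridge_timeseries requires a nonempty frame subset")
    times, direct, watered = [], [], []
    for fr in frames:
        bridges = frame_bridges(fr, topology, criteria, max_waters, lipid_nodes=set())
        pep = [b for b in bridges
               if b.endpoint_a[0] == "pep" and b.endpoint_b[0] == "pep"]
        times.append(fr.time_ps)
        direct.append(sum(1 for b in pep if b.n_waters == 0))
        watered.append(sum(1 for b in pep if b.n_waters >= 1))
    return BridgeTimeSeries(
        times=np.array(times),
        direct_counts=np.array(direct, dtype=int),
        water_bridge_counts=np.array(watered, dtype=int),
    )


# ---------------------------------------------------------------------------
# Leaflet planes and depths
# ---------------------------------------------------------------------------

@dataclass
class DepthReport:
    """Signed depths relative to the leaflet phosphate planes.

    Depths are positive toward the bilayer center.  ``leaflet_planes`` is
    ``(upper_z, lower_z)`` computed from bulk (non-pore-shell) phosphates.
    """

    leaflet_planes: tuple[float, float]
    per_item_depths: dict
    deep_threshold: float

    @property
    def deep_count(self) -> int:
        return sum(1 for d in self.per_item_depths.values()
                   if d is not None and d >= self.deep_threshold)


def _phosphorus_indices(topology: Topology) -> np.ndarray:
    lip = topology.atom_indices(LIPID)
    p = [i for i in lip if topology.elements[i] == "P"]
    if not p:
        raise InputError("no lipid phosphorus atoms in topology")
    return np.array(p, dtype=int)


def leaflet_planes(frame: Frame, topology: Topology,
                   bulk_shell: float = 15.0) -> tuple[float, float]:
    """Mean phosphorus z per leaflet, from lipids outside the pore shell.

    Leaflets are assigned by phosphorus z-sign relative to the midplane (the
    mean phosphorus z).  Lipids within ``bulk_shell`` Å of the peptide are
    excluded so that pore-distorted phosphates do not bias the planes; if that
    leaves fewer than 10 lipids in a leaflet an unstable-plane warning is
    logged and all lipids are used instead.
    """
    p_idx = _phosphorus_indices(topology)
    z = frame.coordinates[p_idx, 2]
    shell = select_lipid_nodes(frame, topology, shell=bulk_shell)
    bulk_mask = np.array(
        [topology.node_keys[i] not in shell for i in p_idx]
    )
    z_bulk = z[bulk_mask]
    mid = float(np.mean(z if z_bulk.size == 0 else z_bulk))
    upper = z_bulk[z_bulk >= mid]
    lower = z_bulk[z_bulk < mid]
    if len(upper) < 10 or len(lower) < 10:
        logger.warning(
            "fewer than 10 bulk lipids per leaflet (%d upper, %d lower); "
            "leaflet planes may be unstable", len(upper), len(lower)
        )
        if len(upper) == 0 or len(lower) == 0:
            mid = float(np.mean(z))
            upper = z[z >= mid]
            lower = z[z < mid]
    return float(np.mean(upper)), float(np.mean(lower))


def _signed_depth(z: float, planes: tuple[float, float]) -> float:
    """Signed distance from the nearest leaflet plane, positive inward."""
    upper, lower = planes
    d_upper = upper - z
    d_lower = z - lower
    return d_upper if abs(d_upper) <= abs(d_lower) else d_lower


def phosphate_depth_profile(frame: Frame, topology: Topology,
                            deep_threshold: float = 5.0,
                            bulk_shell: float = 15.0) -> DepthReport:
    """Depth of every lipid phosphate relative to its leaflet plane.

    ``deep_count`` is the number of phosphates displaced at least
    ``deep_threshold`` Å toward the bilayer center — the signature of lipid
    headgroups lining a toroidal pore.
    """
    planes = leaflet_planes(frame, topology, bulk_shell)
    p_idx = _phosphorus_indices(topology)
    depths = {
        topology.node_keys[i]: _signed_depth(float(frame.coordinates[i, 2]), planes)
        for i in p_idx
    }
    return DepthReport(leaflet_planes=planes, per_item_depths=depths,
                       deep_threshold=deep_threshold)


def trp_insertion_depth(frame: Frame, topology: Topology,
                        residue_position: int = 19,
                        insertion_cutoff: float = 3.0,
                        bulk_shell: float = 15.0) -> pd.DataFrame:
    """Per-peptide side-chain depth at one residue position.

    Depth is the signed distance of the side-chain centroid from the nearest
    leaflet phosphate plane (positive toward the bilayer center).  Peptides
    are classified ``inserted`` when depth > ``insertion_cutoff`` (3 Å by
    default), else ``interfacial``.  Rows with missing side-chain atoms carry
    NaN depth and classification ``missing``.
    """
    planes = leaflet_planes(frame, topology, bulk_shell)
    rows = []
    found = False
    for pid, chain in enumerate(topology.peptide_chains, start=1):
        members = topology.residue_atoms.get((chain, residue_position), [])
        side = [i for i in members
                if topology.atoms[i].molecule_class == PEPTIDE
                and not topology.is_backbone(i)]
        if members:
            found = True
        if not side:
            rows.append({"peptide_id": pid, "depth": np.nan,
                         "classification": "missing"})
            continue
        z = float(np.mean(frame.coordinates[side, 2]))
        depth = _signed_depth(z, planes)
        rows.append({
            "peptide_id": pid,
            "depth": depth,
            "classification": "inserted" if depth > insertion_cutoff
            else "interfacial",
        })
    if not found:
        raise InputError(
            f"residue position {residue_position} not present in any peptide"
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transmembrane water connectivity
# ---------------------------------------------------------------------------

@dataclass
class WaterConnectivityReport:
    spans_bilayer: bool
    spanning_cluster_size: int
    cluster_count: int


def water_connectivity(frame: Frame, topology: Topology,
                       link_cutoff: float = 3.5,
                       bulk_shell: float = 15.0) -> WaterConnectivityReport:
    """Is bulk water connected across the bilayer through the pore?

    Builds a graph on water oxygens (O–O minimum-image distance ≤
    ``link_cutoff``) plus two virtual terminals collecting the waters above
    the upper and below the lower leaflet plane; the bilayer is spanned when
    both terminals fall in one connected component.  ``spanning_cluster_size``
    counts the waters in that component; ``cluster_count`` the number of
    water clusters overall.
    """
    wat = topology.atom_indices(WATER)
    o_idx = [i for i in wat if topology.elements[i] == "O"]
    if not o_idx:
        return WaterConnectivityReport(False, 0, 0)
    upper, lower = leaflet_planes(frame, topology, bulk_shell)

    X = frame.coordinates[np.array(o_idx)]
    box = frame.box
    g = nx.Graph()
    g.add_nodes_from(range(len(o_idx)))
    delta = minimum_image(X[:, None, :] - X[None, :, :], box)
    dist = np.linalg.norm(delta, axis=2)
    a, b = np.nonzero(np.triu(dist <= link_cutoff, k=1))
    g.add_edges_from(zip(a.tolist(), b.tolist()))

    n_clusters = nx.number_connected_components(g)
    g.add_node("upper")
    g.add_node("lower")
    for i in range(len(o_idx)):
        if X[i, 2] > upper:
            g.add_edge("upper", i)
        elif X[i, 2] < lower:
            g.add_edge("lower", i)

    spans = nx.has_path(g, "upper", "lower") if g.has_node("upper") else False
    size = 0
    if spans:
        comp = nx.node_connected_component(g, "upper")
        size = sum(1 for n in comp if isinstance(n, int))
    return WaterConnectivityReport(
        spans_bilayer=bool(spans),
        spanning_cluster_size=size,
        cluster_count=n_clusters,
    )
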
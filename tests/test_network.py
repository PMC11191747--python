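"""Occupancy aggregation, filtering, pruning, densities, export."""

import numpy as np
import pytest

from porenet.hbonds import HBondCriteria
from porenet.network import (
    GraphEdge,
    HBondNetwork,
    build_network,
    count_peptide_lipid_edges,
    density_profile,
    edge_table,
    export_network,
    import_network,
    occupancy_filter,
    select_lipid_nodes,
)
from porenet.chemistry import assign_donors_acceptors
from porenet.synthetic import (
    PlantedEdge,
    SyntheticPoreSpec,
    build_pore_system,
    default_pore_spec,
)


def _analyze(topology, frames, manifest, min_occ=0.0, max_waters=3):
    lipids = select_lipid_nodes(frames[-1], topology, 15.0)
    assert lipids == manifest.lipid_nodes
    return build_network(frames, topology, HBondCriteria(), max_waters,
                         lipids, min_occ)


def _mini_network(occupancies, lipid_pairs=()):
    """Hand-built network for pure-filtering tests."""
    edges = {}
    nodes = set()
    for i, occ in enumerate(occupancies):
        a, b = ("pep", 1, i + 1), ("pep", 2, i + 1)
        edges[(a, b)] = GraphEdge(a, b, occ, 1.0, 0.0)
        nodes |= {a, b}
    for lid, occ in lipid_pairs:
        a, b = ("lip", lid), ("pep", 1, lid)
        edges[(a, b)] = GraphEdge(a, b, occ, 1.0, 0.0)
        nodes |= {a, b}
    return HBondNetwork(nodes=nodes, edges=edges, n_frames_analyzed=10,
                        criteria=HBondCriteria(), max_waters=3,
                        min_occupancy_pct=0.0, residues_per_peptide=26,
                        n_peptides=2)


class TestLipidShell:
    def test_straddling_cutoff(self, octamer):
        """Planted pore lipids are selected; bulk ring lipids are not."""
        _, top, frames, manifest = octamer
        inside = select_lipid_nodes(frames[-1], top, shell=15.0)
        assert inside == manifest.lipid_nodes
        # a tiny shell excludes everything except lipids touching the sites
        tiny = select_lipid_nodes(frames[-1], top, shell=1.0)
        assert tiny == set()

    def test_no_lipids_warns_and_returns_empty(self, caplog):
        spec = SyntheticPoreSpec(n_peptides=2, planted_edges=(), n_frames=1,
                                 n_bulk_lipids_per_leaflet=0)
        top, frames, _ = build_pore_system(spec, validate=False)
        with caplog.at_level("WARNING"):
            assert select_lipid_nodes(frames[0], top) == set()


class TestBuildNetwork:
    def test_planted_occupancy_recovered_exactly(self):
        """An edge present in exactly 7 of 10 frames has occupancy 70%."""
        presence = (True,) * 7 + (False,) * 3
        spec = default_pore_spec(n_frames=10, seed=2)
        edges = tuple(
            PlantedEdge(e.node_a, e.node_b, e.n_waters, presence=presence)
            if e.pair == (("pep", 1, 4), ("pep", 1, 8)) else e
            for e in spec.planted_edges
        )
        spec = SyntheticPoreSpec(**{**spec.__dict__, "planted_edges": edges})
        top, frames, manifest = build_pore_system(spec)
        assign_donors_acceptors(top)
        net = _analyze(top, frames, manifest)
        assert net.edges[(("pep", 1, 4), ("pep", 1, 8))].occupancy_pct == 70.0

    def test_30pct_threshold_drops_2_of_10(self):
        presence = (True, True) + (False,) * 8
        spec = default_pore_spec(n_frames=10, seed=2)
        edges = tuple(
            PlantedEdge(e.node_a, e.node_b, e.n_waters, presence=presence)
            if e.pair == (("pep", 1, 4), ("pep", 1, 8)) else e
            for e in spec.planted_edges
        )
        spec = SyntheticPoreSpec(**{**spec.__dict__, "planted_edges": edges})
        top, frames, manifest = build_pore_system(spec)
        assign_donors_acceptors(top)
        net = _analyze(top, frames, manifest, min_occ=30.0)
        assert (("pep", 1, 4), ("pep", 1, 8)) not in net.edges

    def test_manifest_recovery(self, octamer):
        """Edge set, occupancies, and water counts all equal ground truth."""
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest)
        expected = manifest.expected_edges(min_occupancy_pct=0.0, max_waters=3)
        assert set(net.edges) == set(expected)
        for pair, e in net.edges.items():
            assert e.occupancy_pct == pytest.approx(expected[pair], abs=1e-9)
            assert e.mean_waters == manifest.edge_n_waters[pair]
            assert e.direct_pct == (100.0 if manifest.edge_n_waters[pair] == 0
                                    else 0.0)

    def test_no_lipid_lipid_edges_survive(self, octamer):
        """The planted water-bridged lipid pair is pruned from the graph."""
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest)
        assert all(not (a[0] == "lip" and b[0] == "lip") for a, b in net.edges)
        for lip in net.lipid_nodes():
            assert any(lip in pair and
                       (pair[0][0] == "pep" or pair[1][0] == "pep")
                       for pair in net.edges)

    def test_single_frame_network_equals_frame_bridges(self, octamer):
        _, top, frames, manifest = octamer
        net = _analyze(top, [frames[0]], manifest)
        i_present = manifest.presence[:, 0]
        expected_pairs = {
            pair for i, pair in enumerate(manifest.edge_pairs)
            if i_present[i] and not (pair[0][0] == "lip" and pair[1][0] == "lip")
        }
        assert set(net.edges) == expected_pairs
        assert all(e.occupancy_pct == 100.0 for e in net.edges.values())

    def test_empty_frames_rejected(self, octamer):
        _, top, _, _ = octamer
        from porenet.errors import InputError
        with pytest.raises(InputError):
            build_network([], top)


class TestOccupancyFilter:
    def test_zero_threshold_is_identity(self):
        net = _mini_network([10.0, 50.0, 99.9], [(3, 40.0)])
        assert occupancy_filter(net, 0.0).edges == net.edges

    def test_strict_boundary_at_100(self):
        net = _mini_network([99.9, 100.0])
        kept = occupancy_filter(net, 100.0)
        assert [e.occupancy_pct for e in kept.edges.values()] == [100.0]

    def test_thresholds_nest(self, octamer):
        _, top, frames, manifest = octamer
        base = _analyze(top, frames, manifest)
        e20 = set(occupancy_filter(base, 20.0).edges)
        e30 = set(occupancy_filter(base, 30.0).edges)
        e50 = set(occupancy_filter(base, 50.0).edges)
        assert e50 <= e30 <= e20 <= set(base.edges)

    def test_max_waters_monotonicity(self, octamer):
        _, top, frames, manifest = octamer
        nets = [set(_analyze(top, frames, manifest, max_waters=m).edges)
                for m in (0, 1, 2, 3)]
        for smaller, larger in zip(nets, nets[1:]):
            assert smaller <= larger

    def test_filter_reprunes_lipids(self):
        net = _mini_network([50.0], [(3, 25.0)])
        out = occupancy_filter(net, 30.0)
        assert ("lip", 3) not in out.nodes


class TestDensityProfile:
    def test_single_edge_counts(self):
        net = _mini_network([])
        a, b = ("pep", 1, 4), ("pep", 2, 8)
        net.edges = {(a, b): GraphEdge(a, b, 100.0, 0.0, 100.0)}
        prof = density_profile(net)
        assert prof[4] == 1 and prof[8] == 1
        assert prof.counts.sum() == 2

    def test_empty_network_all_zero(self):
        prof = density_profile(_mini_network([]))
        assert prof.counts.sum() == 0 and len(prof.counts) == 26

    def test_conservation_identity(self, octamer):
        """sum(counts) = 2·E_pp + E_pl on every generated network."""
        _, top, frames, manifest = octamer
        for thr in (0.0, 20.0, 30.0, 50.0):
            net = _analyze(top, frames, manifest, min_occ=thr)
            e_pl = count_peptide_lipid_edges(net)
            e_pp = sum(1 for a, b in net.edges
                       if a[0] == "pep" and b[0] == "pep")
            assert density_profile(net).counts.sum() == 2 * e_pp + e_pl

    def test_manifest_tally(self, octamer):
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest, min_occ=30.0)
        counts = np.zeros(26, dtype=int)
        for pair in manifest.expected_edges(30.0, 3):
            for ep in pair:
                if ep[0] == "pep":
                    counts[ep[2] - 1] += 1
        assert np.array_equal(density_profile(net).counts, counts)


class TestLipidEdgeCount:
    def test_no_lipids_gives_zero(self):
        assert count_peptide_lipid_edges(_mini_network([50.0])) == 0

    def test_matches_manifest(self, octamer):
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest, min_occ=30.0)
        expected = sum(
            1 for pair in manifest.expected_edges(30.0, 3)
            if (pair[0][0] == "lip") != (pair[1][0] == "lip")
        )
        assert count_peptide_lipid_edges(net) == expected

    def test_repruning_is_idempotent(self, octamer):
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest, min_occ=30.0)
        again = occupancy_filter(net, net.min_occupancy_pct)
        assert count_peptide_lipid_edges(again) == count_peptide_lipid_edges(net)
        assert again.edges == net.edges


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        net = _mini_network([72.5], [(5, 45.0)])
        p = tmp_path / "net.graphml"
        export_network(net, p, "graph_markup")
        back = import_network(p)
        assert set(back.edges) == set(net.edges)
        for pair in net.edges:
            for attr in ("occupancy_pct", "mean_waters", "direct_pct"):
                assert getattr(back.edges[pair], attr) == pytest.approx(
                    getattr(net.edges[pair], attr), abs=1e-6)

    def test_edge_table_row_count(self, octamer, tmp_path):
        _, top, frames, manifest = octamer
        net = _analyze(top, frames, manifest)
        t = edge_table(net)
        assert len(t) == len(net.edges)
        export_network(net, tmp_path / "edges.tsv", "edge_table")
        assert (tmp_path / "edges.tsv").read_text().count("\n") == len(t) + 1
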
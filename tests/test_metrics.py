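"""Pore descriptors: bridge counts, depths, water connectivity."""

import numpy as np
import pytest

from porenet.chemistry import assign_donors_acceptors
from porenet.hbonds import HBondCriteria
from porenet.metrics import (
    bridge_timeseries,
    leaflet_planes,
    phosphate_depth_profile,
    trp_insertion_depth,
    water_connectivity,
)
from porenet.synthetic import (
    PlantedEdge,
    SyntheticPoreSpec,
    build_pore_system,
    default_pore_spec,
)


def _bare_spec(**kw):
    base = dict(n_peptides=8, planted_edges=(), n_frames=1, seed=0)
    base.update(kw)
    return SyntheticPoreSpec(**base)


class TestBridgeTimeseries:
    def test_direct_only_frame(self):
        """Three direct side-chain pairs and no bridge waters → (3, 0, 3)."""
        edges = tuple(PlantedEdge(("pep", k, 8), ("pep", k, 11), 0, 1.0)
                      for k in (1, 2, 3))
        spec = _bare_spec(planted_edges=edges, n_frames=2)
        top, frames, _ = build_pore_system(spec)
        assign_donors_acceptors(top)
        ts = bridge_timeseries(frames, top)
        assert list(ts.direct_counts) == [3, 3]
        assert list(ts.water_bridge_counts) == [0, 0]
        assert list(ts.total_counts) == [3, 3]

    def test_matches_planted_schedule(self, octamer):
        _, top, frames, manifest = octamer
        ts = bridge_timeseries(frames, top, HBondCriteria(), 3)
        exp_direct, exp_water = manifest.expected_bridge_counts(3)
        assert np.array_equal(ts.direct_counts, exp_direct)
        assert np.array_equal(ts.water_bridge_counts, exp_water)
        assert np.array_equal(ts.total_counts, exp_direct + exp_water)

    def test_steady_state_per_peptide_mean(self):
        """~70 simultaneous bridges over 8 peptides ≈ 8.75 per peptide.

        Plants 70 always-present side-chain bridges (the scale of a stable
        pore's network) and checks the per-peptide arithmetic.
        """
        edges = []
        # three inter-peptide seams + an intra-peptide ladder, per peptide
        for k in range(1, 9):
            nxt = k % 8 + 1
            edges.append(PlantedEdge(("pep", k, 18), ("pep", nxt, 19), 2, 1.0))
            edges.append(PlantedEdge(("pep", k, 14), ("pep", nxt, 13), 3, 1.0))
            edges.append(PlantedEdge(("pep", k, 22), ("pep", nxt, 23), 1, 1.0))
            edges.append(PlantedEdge(("pep", k, 4), ("pep", k, 8), 2, 1.0))
            edges.append(PlantedEdge(("pep", k, 8), ("pep", k, 11), 0, 1.0))
            edges.append(PlantedEdge(("pep", k, 11), ("pep", k, 15), 2, 1.0))
            edges.append(PlantedEdge(("pep", k, 17), ("pep", k, 21), 2, 1.0))
            edges.append(PlantedEdge(("pep", k, 2), ("pep", k, 5), 1, 1.0))
        for k in range(1, 7):
            edges.append(PlantedEdge(("pep", k, 21), ("pep", k, 24), 1, 1.0))
        assert len(edges) == 70
        spec = _bare_spec(planted_edges=tuple(edges), n_frames=2)
        top, frames, manifest = build_pore_system(spec)
        assign_donors_acceptors(top)
        ts = bridge_timeseries(frames, top)
        assert ts.total_counts.mean() == 70
        assert ts.total_counts.mean() / 8 == pytest.approx(8.75)


class TestDepths:
    def test_flat_bilayer_all_depths_zero(self):
        spec = _bare_spec()
        top, frames, _ = build_pore_system(spec, validate=False)
        rep = phosphate_depth_profile(frames[0], top, deep_threshold=5.0)
        assert rep.leaflet_planes == pytest.approx((19.0, -19.0))
        assert all(abs(d) < 1e-9 for d in rep.per_item_depths.values())
        assert rep.deep_count == 0

    def test_single_displaced_phosphate(self):
        spec = _bare_spec(planted_deep_phosphates=((40, 8.0),))
        top, frames, _ = build_pore_system(spec)
        rep = phosphate_depth_profile(frames[0], top, deep_threshold=5.0)
        assert rep.deep_count == 1
        assert rep.per_item_depths[("lip", 40)] == pytest.approx(8.0)

    def test_planted_deep_count(self, octamer):
        _, top, frames, manifest = octamer
        rep = phosphate_depth_profile(frames[-1], top,
                                      deep_threshold=manifest.deep_threshold)
        assert rep.deep_count == manifest.expected_deep_count()

    def test_depth_invariant_to_xy_translation(self, octamer):
        _, top, frames, manifest = octamer
        f = frames[-1]
        shifted = type(f)(f.frame_index, f.time_ps, f.box,
                          f.coordinates + np.array([7.0, -4.0, 0.0]))
        a = phosphate_depth_profile(f, top)
        b = phosphate_depth_profile(shifted, top)
        assert a.per_item_depths == pytest.approx(b.per_item_depths)


class TestInsertionDepth:
    def test_inserted_octamer(self, octamer):
        _, top, frames, _ = octamer
        d = trp_insertion_depth(frames[0], top, residue_position=19)
        assert (d.classification == "inserted").all()
        # residue 19 sits 8.25 Å above the midplane of a ±19 Å slab
        assert d.depth.to_numpy() == pytest.approx(np.full(8, 19.0 - 8.25))

    def test_deinserting_peptides_flagged_interfacial(self):
        offsets = (0.0, 0.0, 9.0, 0.0, 0.0, 9.0, 0.0, 0.0)
        spec = _bare_spec(extra_polar_positions=(19,),
                          peptide_z_offsets=offsets)
        top, frames, _ = build_pore_system(spec, validate=False)
        d = trp_insertion_depth(frames[0], top, residue_position=19)
        interfacial = set(d[d.classification == "interfacial"].peptide_id)
        assert interfacial == {3, 6}

    def test_missing_position_raises(self, octamer):
        _, top, frames, _ = octamer
        from porenet.errors import InputError
        with pytest.raises(InputError):
            trp_insertion_depth(frames[0], top, residue_position=99)


class TestWaterConnectivity:
    def test_continuous_column_spans(self, octamer):
        _, top, frames, manifest = octamer
        rep = water_connectivity(frames[0], top)
        assert rep.spans_bilayer is manifest.water_spanning[0] is True
        assert rep.spanning_cluster_size >= 2

    def test_gapped_column_does_not_span(self):
        spec = default_pore_spec(n_frames=2, seed=4, water_column="gapped")
        top, frames, manifest = build_pore_system(spec)
        rep = water_connectivity(frames[0], top)
        assert rep.spans_bilayer is manifest.water_spanning[0] is False

    def test_monotone_in_link_cutoff(self):
        """Widening the O–O cutoff can only connect, never disconnect."""
        spec = default_pore_spec(n_frames=1, seed=4, water_column="gapped")
        top, frames, _ = build_pore_system(spec)
        spans = [water_connectivity(frames[0], top, link_cutoff=c).spans_bilayer
                 for c in (3.0, 3.5, 8.0, 10.0)]
        assert spans == sorted(spans)  # False ... True
        assert spans[-1] is True

    def test_dry_slab(self):
        spec = _bare_spec(water_column="gapped")
        top, frames, _ = build_pore_system(spec, validate=False)
        rep = water_connectivity(frames[0], top)
        assert rep.spans_bilayer is False
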
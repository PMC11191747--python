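# Methods

## The model

`porenet` treats a pore-forming peptide system as three interacting sets of
hydrogen-bonding groups: peptide *side-chain* heteroatoms (backbone amides
are deliberately excluded — the network of interest is the side-chain one),
lipid phosphate oxygens, and water. Analysis proceeds in four stages:

1. **Per-frame H-bond detection.** A donor heavy atom D carrying hydrogen H
   and an acceptor heavy atom A form an H-bond when the D···A heteroatom
   distance is ≤ `d_max` (default 3.5 Å) and the H-bond angle is ≤
   `angle_max` (default 60°). Distances use the minimum-image convention in
   an orthorhombic box. Because the literature does not always state which
   angle a "≤ 60°" criterion refers to, both common readings are
   implemented and selectable: the angle at the donor between D→H and D→A
   (`H_D_A`, default), and 180° minus the D–H···A angle (`DHA_supplement`).
   Both vanish for a linear bond and are nearly interchangeable at this
   cutoff; neither is asserted as ground truth. Donor/acceptor roles come
   from a per-residue chemistry table (standard amino-acid side chains,
   water both ways, phosphate oxygens acceptor-only) with a generic
   element-based fallback for nonstandard residues.

2. **Water-bridge search.** Atom-level H-bonds are collapsed to residue
   nodes (several simultaneous atomic contacts between the same two
   residues count once; intra-residue contacts are dropped; direction is
   ignored). For every pair of non-water nodes the search reports the
   minimum number of interior waters on an all-water H-bond chain between
   them, up to `max_waters` (default 3); 0 encodes a direct H-bond. The
   search is a per-source Dijkstra ordered by (depth, water-id sequence),
   which yields both minimality and a deterministic lexicographic
   tie-break; it is verified against exhaustive simple-path enumeration in
   the test suite.

3. **Occupancy aggregation.** Over an analysis window (by convention the
   trailing 200 ns sampled every 10 ps — 20 000 frames — selected as the
   half-open interval `(t_end − window, t_end]` so the frame count is exact),
   each node pair's *occupancy* is the percentage of analyzed frames in
   which any qualifying bridge connects it. Lipid nodes are restricted to
   phosphates within a shell (default 15 Å) of any peptide atom in the
   final frame — membership is decided once and fixed, since the pore-lining
   lipid set is an end-state property. Edges below the occupancy threshold
   (display default 30%; 20% is useful for more dynamic water-mediated
   connections) are dropped, lipid–lipid edges are excluded, and lipid
   nodes left without a peptide connection are pruned. Per-residue
   interaction densities count unweighted edge incidences summed over all
   peptides (an occupancy-weighted variant is available behind a flag);
   by construction `Σ counts = 2·E_pp + E_pl`.

4. **Pore descriptors.** The bridge time series counts residue pairs (not
   atomic contacts) per frame, split into direct and water-mediated.
   Depth quantities are measured along z (the membrane normal is fixed to
   z; no principal-axis fitting): leaflet phosphate planes are the mean
   phosphorus z per leaflet computed from *bulk* lipids (outside the pore
   shell) so pore-distorted headgroups do not bias the reference; fewer
   than 10 bulk lipids per leaflet triggers an unstable-plane warning.
   Phosphates displaced ≥ `deep_threshold` (default 5 Å) toward the
   bilayer center are counted as "deep" — the toroidal-pore signature. A
   chosen side chain (position 19, the tryptophan of melittin-family
   peptides, by default) is classified inserted/interfacial by a 3 Å depth
   cutoff. Water connectivity links water oxygens at O–O ≤ 3.5 Å plus two
   virtual bulk terminals (above/below the leaflet planes); the bilayer is
   "spanned" when both terminals share a connected component. The 3 Å
   insertion cutoff, 5 Å deep-phosphate threshold, and 3.5 Å O–O link are
   package choices for descriptors the source analyses use qualitatively;
   all are exposed as parameters.

## Counting conventions

Published "lipid interaction" totals for such networks can be read either
as graph edges or as per-residue incidences. On a simple residue-level
graph the two coincide for peptide–lipid edges (each edge touches exactly
one side chain), so the remaining ambiguity is the occupancy threshold;
`lipid_interaction_report` therefore returns the peptide–lipid edge count
at both 20% and 30%. Similarly, bridge time series count residue pairs,
not atom-level H-bonds; the difference is documented rather than hidden.

## The synthetic pore generator

Real nanopore H-bond networks come from ~0.5 µs all-atom trajectories that
cannot be regenerated at desk scale, so correctness is established on
synthetic systems whose answer is known by construction. The generator
builds an idealized octamer: eight rigid pseudo-helices (1.5 Å rise,
100°/residue, 2.3 Å helix radius) on a 15 Å ring spanning phosphate planes
at ±19 Å, with surrogate side chains — a single O–H site per polar residue,
not a rotamer, since ground-truth control matters more than chemical
realism — plus lipids reduced to a phosphate group (P + two acceptor
oxygens) and explicit waters.

Every network edge is *planted*: a Bernoulli schedule (or an explicit
per-frame pattern) decides presence per frame. Present water bridges place
exactly `n` waters along a straight or circularly bowed chain with ~2.8 Å
O···O links, with hydrogens aimed along the chain so both angle conventions
are satisfied exactly; skip-one chords stay ≥ ~4 Å so the minimal water
count is unambiguous. Absent bridges park their waters in a far reservoir
(5 Å pitch, nothing within H-bond range); absent direct edges pull the two
sites to 4.0 Å, violating the distance criterion by 0.5 Å regardless of
angle convention. Bulk lipids form outer rings at exactly ±19 Å (so leaflet
planes and depths are exact); pore lipids are anchored to their partner
sites inside the 15 Å shell; explicitly planted deep phosphates sit near
the axis at the requested depth. The water column along the pore axis is
continuous (spanning) or gapped (non-spanning) by construction. A
validation pass rejects any frame in which an unintended polar pair falls
within 3.6 Å, so planted occupancies are recovered *exactly* — the
generator's manifest (edge set, realized occupancies, water counts, lipid
shell membership, depths, spanning flags) is the oracle for the end-to-end
tests. Builds are bit-reproducible from the spec seed.

The generator emulates geometry and bookkeeping, not physics: there are no
forces, no thermal fluctuations of bond geometry, no competing near-miss
contacts, and surrogate chemistry is one site per residue. Passing tests
therefore demonstrate that the *analysis* is correct and exact on known
networks — not that any particular biological system behaves this way, and
not how the detectors respond to borderline geometries in thermal ensembles
(those are covered separately by the randomized-system oracle tests, which
place sites and waters uniformly at random so criteria are exercised at and
across their boundaries).

## Assay arithmetic

Fractional leakage is the affine-invariant normalization
`(F − F0)/(F100 − F0)` between a no-peptide negative control and a
detergent-lysed 100% control, clipped to [0, 1] with a logged clip flag; it
works for dequenching and donor-quenching readouts alike. Lipid exchange is
the baseline-subtracted NBD ratio as a percentage. The tryptophan titration
is fitted by least squares (scipy `curve_fit`, Kp ≥ 0, Imax ≥ 1) to the
mole-fraction partition model `I([L]) = 1 + (Imax − 1)·Kp[L]/([W] + Kp[L])`
with `[W] = 55.3 M`; an optional free-tryptophan scattering series is
subtracted as an excess-over-1 baseline. The equation bodies in the source
material are images, so these forms are the standard normalizations
consistent with the surrounding text, implemented as documented
interpretations. Replicates are summarized as mean ± standard error with n.

Sequence descriptors: net charge counts +1 per Lys/Arg, −1 per Asp/Glu,
+1 for the free N-terminal amine, and −1 only for a free C-terminus
(simulated constructs carry a neutral C-terminal amide); histidine is
neutral at pH 7 by default and configurable. Hydropathy scales
(Kyte–Doolittle, Hopp–Woods, Janin) are taken from Biopython; profiles are
centered moving averages with truncated ends; "protonated Glu" scores E
with the scale's Q value as a neutral-amide stand-in. No scale or
transmembrane threshold is asserted as canonical — both are parameters.

## Problem sizes and numerical notes

The test suite and the acceptance script run the full pipeline on synthetic
octamers of 100–200 frames (~600 atoms, 33 planted edges) and verify the
detectors on 100 randomized ≤ 50-atom systems against brute-force oracles —
sizes chosen so the whole verification runs in seconds while every code
path (bowed bridges, direct toggling, lipid pruning, gapped columns) is
exercised. Occupancy comparisons are exact (equality of realized schedule
fractions); angle comparisons carry a 1e-12 tolerance so boundary
constructions (exactly 60°, exactly 3.5 Å) are accepted deterministically.
Partition-fit initial guesses are derived from the data (half-saturation at
the median lipid concentration) and recovery on noise-free curves is better
than 0.1%.

## Known limitations

* The membrane normal is fixed to z and the box must be orthorhombic; no
  bonded-image handling beyond minimum image.
* Hydrogens must be present in the topology (no H placement); H→heavy
  attachment uses CONECT records or a 1.3 Å distance fallback.
* Occupancy is binary per frame (a pair is connected or not); bridge
  multiplicity within a frame is not tracked beyond the minimal water count.
* Leaflet assignment by z-sign is robust for planar fixtures but would need
  revisiting for strongly undulating membranes.
* No energetic H-bond definitions, pore-radius profiling, order parameters,
  or free energies — the scope is the H-bond network and its companion
  descriptors.
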
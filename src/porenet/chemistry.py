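"""Donor/acceptor assignment.

The graph analysis considers only H-bonding *side-chain* heteroatoms of the
peptides, lipid phosphate oxygens, and water.  Assignment combines a generic
rule (any side-chain N/O/S bearing a covalent hydrogen donates; any side-chain
N/O accepts; water oxygen does both; lipid oxygens bonded to phosphorus
accept) with an explicit per-residue chemistry table that encodes standard
amino-acid chemistry (e.g. the lysine ammonium nitrogen donates but does not
accept at neutral pH).  The table can be extended or overridden by the caller.
"""

from __future__ import annotations

from typing import Mapping

from .errors import TopologyError
from .trajectory import LIPID, PEPTIDE, WATER, Topology

DONOR = "donor"
ACCEPTOR = "acceptor"
BOTH = "both"

#: (residue_name, atom_name) → role for standard residues.  Entries override
#: the generic element rule.  Protonation: Asp/Glu deprotonated, Lys/Arg
#: protonated, His neutral (both ring nitrogens listed as both to cover the
#: two tautomers).
CHEMISTRY_TABLE: dict[tuple[str, str], str] = {
    ("SER", "OG"): BOTH,
    ("THR", "OG1"): BOTH,
    ("TYR", "OH"): BOTH,
    ("CYS", "SG"): BOTH,
    ("MET", "SD"): ACCEPTOR,
    ("ASN", "OD1"): ACCEPTOR,
    ("ASN", "ND2"): DONOR,
    ("GLN", "OE1"): ACCEPTOR,
    ("GLN", "NE2"): DONOR,
    ("ASP", "OD1"): ACCEPTOR,
    ("ASP", "OD2"): ACCEPTOR,
    ("GLU", "OE1"): ACCEPTOR,
    ("GLU", "OE2"): ACCEPTOR,
    ("LYS", "NZ"): DONOR,
    ("ARG", "NE"): DONOR,
    ("ARG", "NH1"): DONOR,
    ("ARG", "NH2"): DONOR,
    ("HIS", "ND1"): BOTH,
    ("HIS", "NE2"): BOTH,
    ("TRP", "NE1"): DONOR,
}


def assign_donors_acceptors(
    topology: Topology,
    chemistry_table: Mapping[tuple[str, str], str] | None = None,
) -> Topology:
    """Annotate a topology with donor/acceptor atoms (returns the same object).

    Rules, in order of precedence:

    1. an explicit ``(residue_name, atom_name)`` entry in the chemistry table;
    2. water oxygen → both donor and acceptor;
    3. lipid oxygen covalently bonded to a phosphorus (or named ``O*P*``) →
       acceptor;
    4. peptide side-chain N/O/S with ≥1 covalent hydrogen → donor, and
       side-chain N/O → acceptor.  Backbone atoms are excluded throughout.
    """
    table = dict(CHEMISTRY_TABLE)
    if chemistry_table:
        table.update(chemistry_table)

    for i, a in enumerate(topology.atoms):
        if a.element == "H" and i not in topology.h_parent:
            raise TopologyError(
                f"hydrogen atom {a.atom_id} is not attached to a heavy atom"
            )

    donors: list[int] = []
    acceptors: list[int] = []
    donor_h: dict[int, list[int]] = {}

    for i, a in enumerate(topology.atoms):
        if a.element == "H":
            continue
        role = None
        key = (a.residue_name, a.atom_name)
        if key in table:
            role = table[key]
        elif a.molecule_class == WATER and a.element == "O":
            role = BOTH
        elif a.molecule_class == LIPID and a.element == "O":
            if _bonded_to_phosphorus(topology, i) or "P" in a.atom_name[1:]:
                role = ACCEPTOR
        elif a.molecule_class == PEPTIDE and not topology.is_backbone(i):
            hs = topology.heavy_hydrogens.get(i, [])
            if a.element in ("N", "O", "S") and hs:
                role = BOTH if a.element in ("N", "O") else DONOR
            elif a.element in ("N", "O"):
                role = ACCEPTOR
            elif a.element == "S":
                role = ACCEPTOR
        if role is None:
            continue
        if role in (DONOR, BOTH):
            hs = topology.heavy_hydrogens.get(i, [])
            if hs:  # a donor with no H cannot actually donate
                donors.append(i)
                donor_h[i] = list(hs)
        if role in (ACCEPTOR, BOTH):
            acceptors.append(i)

    topology.donor_atoms = donors
    topology.acceptor_atoms = acceptors
    topology.donor_hydrogens = donor_h
    return topology


def _bonded_to_phosphorus(topology: Topology, i: int) -> bool:
    aid = topology.atoms[i].atom_id
    for a, b in topology.bonds:
        j = b if a == aid else (a if b == aid else None)
        if j is not None and topology.atoms[topology.index_of(j)].element == "P":
            return True
    return False


def donor_acceptor_census(topology: Topology) -> dict[str, int]:
    """Counts of donors/acceptors by molecule class (after assignment)."""
    out: dict[str, int] = {}
    for label, idxs in (("donor", topology.donor_atoms),
                        ("acceptor", topology.acceptor_atoms)):
        for i in idxs:
            cls = topology.atoms[i].molecule_class
            out[f"{cls}_{label}s"] = out.get(f"{cls}_{label}s", 0) + 1
    return out
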
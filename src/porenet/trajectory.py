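"""Topology and trajectory I/O.

The analysis operates on two in-memory objects:

* :class:`Topology` — per-atom identity (name, element, residue, chain) plus a
  molecule class (``peptide`` / ``water`` / ``lipid`` / ``ion``) and covalent
  bonds, which are needed to attach hydrogens to their donor heavy atoms.
* :class:`Frame` — one coordinate set (Å) with a time stamp (ps) and an
  orthorhombic box.

Topologies are read from PDB-style records via MDAnalysis.  Frames come either
from a self-describing structured-text trajectory format (used for all test
fixtures, see :func:`read_text_trajectory`) or, when the files are available,
from binary DCD/XTC trajectories through :func:`iter_binary_frames`.  Units are
fixed at Å and ps internally; conversions happen at the I/O boundary.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ClassificationError,
    InputError,
    RangeError,
    StrideError,
    TopologyError,
)

PEPTIDE = "peptide"
WATER = "water"
LIPID = "lipid"
ION = "ion"
MOLECULE_CLASSES = (PEPTIDE, WATER, LIPID, ION)

#: Default residue-name → molecule-class rules.  Users may extend or override
#: these via the ``class_rules`` argument of :func:`load_topology`.
DEFAULT_CLASS_RULES: dict[str, str] = {
    # waters
    "HOH": WATER, "TIP3": WATER, "TIP3P": WATER, "WAT": WATER, "SOL": WATER,
    "SPC": WATER,
    # common phospholipids
    "POPC": LIPID, "POPG": LIPID, "POPE": LIPID, "POPS": LIPID,
    "DOPC": LIPID, "DPPC": LIPID, "DMPC": LIPID, "CHL1": LIPID,
    # ions
    "NA": ION, "CL": ION, "SOD": ION, "CLA": ION, "POT": ION, "K": ION,
    "CA": ION, "MG": ION,
    # synthetic fixture residues (see porenet.synthetic)
    "PSC": PEPTIDE, "APO": PEPTIDE, "PHO": LIPID,
}
_AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL"
).split()
DEFAULT_CLASS_RULES.update({name: PEPTIDE for name in _AMINO3})

#: Atom names treated as backbone in peptide residues (excluded from
#: side-chain donor/acceptor assignment).
BACKBONE_NAMES = frozenset(
    "N CA C O OXT H HN H1 H2 H3 HA HA1 HA2 HA3 HT1 HT2 HT3".split()
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology."""

    atom_id: int
    atom_name: str
    element: str
    residue_index: int  # 1-based within its chain
    residue_name: str
    chain_id: str
    molecule_class: str


@dataclass
class Frame:
    """One coordinate set, aligned to the topology atom order."""

    frame_index: int
    time_ps: float
    box: np.ndarray  # (3,) orthorhombic box lengths, Å
    coordinates: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise InputError("frame box must be three positive lengths")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InputError("frame coordinates must be (n_atoms, 3)")


class Topology:
    """Atom table with covalent bonds and derived per-atom node identity.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    bonds:
        Covalent pairs of ``atom_id``.  Every hydrogen must have exactly one
        heavy-atom parent, either given here or inferred by
        :meth:`attach_hydrogens_by_distance`.
    """

    def __init__(self, atoms: Sequence[AtomRecord], bonds: Iterable[tuple[int, int]] = ()):
        self.atoms = list(atoms)
        if len({a.atom_id for a in self.atoms}) != len(self.atoms):
            raise TopologyError("atom_id values are not unique")
        self.bonds = [tuple(sorted(b)) for b in bonds]
        self._index_of = {a.atom_id: i for i, a in enumerate(self.atoms)}

        self.names = np.array([a.atom_name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.resids = np.array([a.residue_index for a in self.atoms])
        self.resnames = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.chains = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.classes = np.array([a.molecule_class for a in self.atoms], dtype=object)

        self._build_residues()
        self._build_h_parents()
        self._build_node_keys()
        self._validate_waters()

        # Filled by porenet.chemistry.assign_donors_acceptors
        self.donor_atoms: list[int] = []
        self.acceptor_atoms: list[int] = []
        self.donor_hydrogens: dict[int, list[int]] = {}

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        return self._index_of[atom_id]

    # --------------------------------------------------------------- residues
    def _build_residues(self):
        """Group atoms into residues keyed by (chain_id, residue_index)."""
        self.residue_atoms: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residue_atoms.setdefault((a.chain_id, a.residue_index), []).append(i)

        pep_chains: list[str] = []
        for a in self.atoms:
            if a.molecule_class == PEPTIDE and a.chain_id not in pep_chains:
                pep_chains.append(a.chain_id)
        self.peptide_chains = pep_chains
        self.n_peptides = len(pep_chains)
        counts = {
            c: len({a.residue_index for a in self.atoms
                    if a.chain_id == c and a.molecule_class == PEPTIDE})
            for c in pep_chains
        }
        if counts and len(set(counts.values())) != 1:
            raise TopologyError(f"peptide chains differ in residue count: {counts}")
        self.residues_per_peptide = next(iter(counts.values())) if counts else 0

    def _build_h_parents(self):
        adj: dict[int, list[int]] = {}
        for a, b in self.bonds:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        self.h_parent: dict[int, int] = {}
        self.heavy_hydrogens: dict[int, list[int]] = {}
        if not self.bonds:
            return
        for i, a in enumerate(self.atoms):
            if a.element != "H":
                continue
            heavies = [
                self._index_of[j] for j in adj.get(a.atom_id, [])
                if self.atoms[self._index_of[j]].element != "H"
            ]
            if len(heavies) != 1:
                raise TopologyError(
                    f"hydrogen atom {a.atom_id} has {len(heavies)} heavy-atom "
                    "parents; expected exactly one"
                )
            self.h_parent[i] = heavies[0]
            self.heavy_hydrogens.setdefault(heavies[0], []).append(i)

    def attach_hydrogens_by_distance(self, coordinates: np.ndarray, cutoff: float = 1.3):
        """Infer H→heavy attachments from geometry when bonds are absent.

        Each hydrogen is attached to the nearest heavy atom of its own residue
        within ``cutoff`` Å.  Used for PDB files without CONECT records.
        """
        coordinates = np.asarray(coordinates, dtype=float)
        self.h_parent = {}
        self.heavy_hydrogens = {}
        for key, members in self.residue_atoms.items():
            hs = [i for i in members if self.atoms[i].element == "H"]
            heavies = [i for i in members if self.atoms[i].element != "H"]
            if not hs:
                continue
            if not heavies:
                raise TopologyError(f"residue {key} contains only hydrogens")
            hv = coordinates[heavies]
            for h in hs:
                d = np.linalg.norm(hv - coordinates[h], axis=1)
                j = int(np.argmin(d))
                if d[j] > cutoff:
                    raise TopologyError(
                        f"hydrogen atom {self.atoms[h].atom_id} has no heavy "
                        f"atom within {cutoff} Å"
                    )
                parent = heavies[j]
                self.h_parent[h] = parent
                self.heavy_hydrogens.setdefault(parent, []).append(h)

    # -------------------------------------------------------------- node keys
    def _build_node_keys(self):
        """Assign each atom a residue-level node key.

        Peptide atoms map to ``("pep", peptide_id, residue_index)`` with
        peptide_id 1-based in chain order; lipid residues map to
        ``("lip", lipid_id)``; waters to ``("wat", water_id)``.  Lipid and
        water ids are the residue indices when those are globally unique
        within their class, otherwise a 1-based enumeration.
        """
        pep_rank = {c: k + 1 for k, c in enumerate(self.peptide_chains)}

        def class_ids(cls: str) -> dict[tuple[str, int], int]:
            keys: list[tuple[str, int]] = []
            for a in self.atoms:
                if a.molecule_class == cls and (a.chain_id, a.residue_index) not in keys:
                    keys.append((a.chain_id, a.residue_index))
            resids = [k[1] for k in keys]
            if len(set(resids)) == len(resids):
                return {k: k[1] for k in keys}
            return {k: n + 1 for n, k in enumerate(keys)}

        lip_ids = class_ids(LIPID)
        wat_ids = class_ids(WATER)
        self.lipid_ids = sorted(set(lip_ids.values()))
        self.node_keys: list[tuple | None] = []
        for a in self.atoms:
            if a.molecule_class == PEPTIDE:
                self.node_keys.append(("pep", pep_rank[a.chain_id], a.residue_index))
            elif a.molecule_class == LIPID:
                self.node_keys.append(("lip", lip_ids[(a.chain_id, a.residue_index)]))
            elif a.molecule_class == WATER:
                self.node_keys.append(("wat", wat_ids[(a.chain_id, a.residue_index)]))
            else:
                self.node_keys.append(None)

    def _validate_waters(self):
        for (chain, resid), members in self.residue_atoms.items():
            if self.atoms[members[0]].molecule_class != WATER:
                continue
            elems = sorted(self.atoms[i].element for i in members)
            if elems != ["H", "H", "O"]:
                raise TopologyError(
                    f"water residue {chain}:{resid} has atoms {elems}; "
                    "expected exactly one O and two H"
                )

    # ---------------------------------------------------------------- queries
    def atom_indices(self, molecule_class: str) -> np.ndarray:
        return np.flatnonzero(self.classes == molecule_class)

    def class_census(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in MOLECULE_CLASSES}

    def is_backbone(self, i: int) -> bool:
        a = self.atoms[i]
        if a.molecule_class != PEPTIDE:
            return False
        if a.element == "H" and i in self.h_parent:
            return self.names[self.h_parent[i]] in BACKBONE_NAMES
        return a.atom_name in BACKBONE_NAMES


# ---------------------------------------------------------------------------
# PDB topology reading
# ---------------------------------------------------------------------------

def load_topology(
    path: str | Path,
    class_rules: Mapping[str, str] | None = None,
    default_class: str | None = None,
) -> Topology:
    """Read a PDB-style topology and classify every atom.

    Parameters
    ----------
    path:
        PDB file.  CONECT records, when present, provide covalent bonds;
        otherwise hydrogens are attached to the nearest heavy atom of their
        residue using the file's own coordinates.
    class_rules:
        Extra ``residue_name → molecule_class`` rules merged over
        :data:`DEFAULT_CLASS_RULES`.
    default_class:
        Class used for residue names matched by no rule.  When ``None``,
        unknown names raise :class:`~porenet.errors.ClassificationError`.
    """
    import MDAnalysis as mda

    rules = dict(DEFAULT_CLASS_RULES)
    if class_rules:
        rules.update({k.upper(): v for k, v in class_rules.items()})
    for v in rules.values():
        if v not in MOLECULE_CLASSES:
            raise InputError(f"unknown molecule class {v!r}")

    path = Path(path)
    if not path.exists():
        raise InputError(f"topology file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="PDB")
    except Exception as exc:  # pragma: no cover - delegated parser detail
        raise InputError(f"failed to parse {path}: {exc}") from exc

    n = len(u.atoms)
    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.chainIDs
    except AttributeError:  # pragma: no cover
        chains = np.array([""] * n, dtype=object)
    try:
        elements = [e.capitalize() if e else "" for e in u.atoms.elements]
    except Exception:
        elements = ["" for _ in range(n)]
    elements = [
        e if e else _element_from_name(names[i]) for i, e in enumerate(elements)
    ]

    unknown = sorted(
        {r.upper() for r in resnames if r.upper() not in rules}
    )
    if unknown and default_class is None:
        raise ClassificationError(unknown)

    atoms = []
    for i in range(n):
        rn = str(resnames[i]).upper()
        atoms.append(
            AtomRecord(
                atom_id=int(u.atoms.ids[i]) if hasattr(u.atoms, "ids") else i + 1,
                atom_name=str(names[i]),
                element=str(elements[i]),
                residue_index=int(resids[i]),
                residue_name=rn,
                chain_id=str(chains[i]),
                molecule_class=rules.get(rn, default_class),
            )
        )

    bonds: list[tuple[int, int]] = []
    if hasattr(u, "bonds") and len(u.bonds):
        id_arr = u.atoms.ids if hasattr(u.atoms, "ids") else np.arange(1, n + 1)
        for b in u.bonds:
            bonds.append((int(id_arr[b.atoms[0].ix]), int(id_arr[b.atoms[1].ix])))

    top = Topology(atoms, bonds)
    if not top.h_parent and any(a.element == "H" for a in atoms):
        top.attach_hydrogens_by_distance(u.atoms.positions.astype(float))
    return top


def _element_from_name(name: str) -> str:
    name = name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    two = name[:2].capitalize()
    if two in ("Cl", "Na", "Mg", "Br", "Fe", "Zn"):
        return two
    return name[0].upper()


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str | Path) -> None:
    """Write a topology + one coordinate set as PDB with CONECT bonds."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (topology.n_atoms, 3):
        raise InputError("coordinate array does not match topology atom count")
    with open(path, "w") as fh:
        for i, a in enumerate(topology.atoms):
            x, y, z = coordinates[i]
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {a.atom_id:>5d} {name:<4s} {a.residue_name:<4s}"
                f"{a.chain_id:1s}{a.residue_index:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}\n"
            )
        for a, b in sorted(topology.bonds):
            fh.write(f"CONECT{a:>5d}{b:>5d}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Structured-text trajectory fixture format
# ---------------------------------------------------------------------------
#
# PORENET_TRAJ 1
# natoms <N>
# frame <index> <time_ps> <bx> <by> <bz>
# <x> <y> <z>          (N lines, %.6f)
# ...

_TRAJ_MAGIC = "PORENET_TRAJ 1"


def write_text_trajectory(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames in the self-describing text fixture format (exact round-trip)."""
    frames = list(frames)
    if not frames:
        raise InputError("refusing to write an empty trajectory")
    n = frames[0].coordinates.shape[0]
    with open(path, "w") as fh:
        fh.write(_TRAJ_MAGIC + "\n")
        fh.write(f"natoms {n}\n")
        for fr in frames:
            if fr.coordinates.shape[0] != n:
                raise InputError("frames differ in atom count")
            bx, by, bz = fr.box
            fh.write(f"frame {fr.frame_index} {fr.time_ps:.6f} {bx:.6f} {by:.6f} {bz:.6f}\n")
            np.savetxt(fh, fr.coordinates, fmt="%.6f", delimiter=" ")


def read_text_trajectory(path: str | Path) -> list[Frame]:
    """Read a text-format trajectory written by :func:`write_text_trajectory`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    frames: list[Frame] = []
    with open(path) as fh:
        line = fh.readline().rstrip("\n")
        if line != _TRAJ_MAGIC:
            raise InputError(f"{path}:1: not a porenet text trajectory")
        line = fh.readline()
        if not line.startswith("natoms "):
            raise InputError(f"{path}:2: expected 'natoms N'")
        n = int(line.split()[1])
        lineno = 2
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            parts = header.split()
            if parts[0] != "frame" or len(parts) != 6:
                raise InputError(f"{path}:{lineno}: malformed frame header")
            idx = int(parts[1])
            t = float(parts[2])
            box = np.array([float(x) for x in parts[3:6]])
            block = np.loadtxt(io.StringIO("".join(fh.readline() for _ in range(n))))
            lineno += n
            coords = np.atleast_2d(block)
            if coords.shape != (n, 3):
                raise InputError(f"{path}:{lineno}: truncated coordinate block")
            frames.append(Frame(idx, t, box, coords))
    if not frames:
        raise InputError(f"{path}: contains no frames")
    _check_times(frames)
    return frames


def _check_times(frames: Sequence[Frame]):
    times = np.array([f.time_ps for f in frames])
    if np.any(np.diff(times) < 0):
        raise InputError("frame times are not nondecreasing")


def iter_binary_frames(topology_path: str | Path, trajectory_path: str | Path,
                       dt_ps: float | None = None) -> Iterable[Frame]:
    """Stream frames from a binary trajectory (DCD/XTC) via MDAnalysis.

    Provides the same frame-stream contract as :func:`read_text_trajectory`
    for real-data use; ``dt_ps`` overrides the time step when the file stores
    no usable times.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(trajectory_path))
    for i, ts in enumerate(u.trajectory):
        t = float(ts.time) if dt_ps is None else i * dt_ps
        box = np.asarray(ts.dimensions[:3], dtype=float)
        yield Frame(i, t, box, ts.positions.astype(float))


# ---------------------------------------------------------------------------
# Window selection and metadata
# ---------------------------------------------------------------------------

def select_window(frames: Sequence[Frame], window_ns: float, stride_ps: float) -> list[Frame]:
    """Select equally spaced frames from the trailing analysis window.

    The window is the half-open time interval ``(t_end − window, t_end]``; the
    returned frames are those at times ``t_end − k·stride`` for
    ``k = 0 … window/stride − 1``, in chronological order.  With a 500 ns
    trajectory saved each 10 ps, a 200 ns window at 10 ps stride therefore
    yields exactly 20 000 frames.
    """
    frames = list(frames)
    if not frames:
        raise InputError("empty frame stream")
    if window_ns <= 0 or stride_ps <= 0:
        raise RangeError("window_ns and stride_ps must be positive")
    times = np.array([f.time_ps for f in frames])
    _check_times(frames)
    t_end = times[-1]
    t_first = times[0]
    interval = None
    if len(times) > 1:
        diffs = np.diff(times)
        interval = float(np.min(diffs[diffs > 0])) if np.any(diffs > 0) else None
    if interval is not None:
        ratio = stride_ps / interval
        if abs(ratio - round(ratio)) > 1e-6:
            raise StrideError(
                f"stride {stride_ps} ps is not a multiple of the saving "
                f"interval {interval} ps"
            )
    window_ps = window_ns * 1000.0
    n_req = window_ps / stride_ps
    if abs(n_req - round(n_req)) > 1e-9:
        raise StrideError("stride_ps must divide the window evenly")
    n_req = int(round(n_req))

    lookup = {round(t, 6): f for t, f in zip(times, frames)}
    picked: list[Frame] = []
    for k in range(n_req):
        t = round(t_end - k * stride_ps, 6)
        if t not in lookup:
            if t < round(t_first, 6):
                raise RangeError(
                    f"window of {window_ns} ns extends before the first saved "
                    f"frame (t = {t_first} ps)"
                )
            raise StrideError(f"no saved frame at t = {t} ps")
        picked.append(lookup[t])
    picked.reverse()
    return picked


def summarize_trajectories(durations_ns: Sequence[float],
                           labels: Sequence[str] | None = None) -> dict:
    """Summarize production-run durations.

    Returns a dict with ``total_us`` (total sampling in µs) and ``table``, a
    per-run :class:`pandas.DataFrame` with columns ``run`` and ``duration_ns``.
    """
    durations = [float(d) for d in durations_ns]
    if not durations:
        raise InputError("no trajectory durations given")
    if any(d <= 0 for d in durations):
        raise InputError("durations must be positive")
    labels = list(labels) if labels is not None else [
        f"run{i+1}" for i in range(len(durations))
    ]
    table = pd.DataFrame({"run": labels, "duration_ns": durations})
    return {"total_us": sum(durations) / 1000.0, "table": table}
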
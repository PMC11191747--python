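"""Sequence-level descriptors for melittin-family peptides.

Net charge, idealized helical-wheel coordinates (100° per residue), and
sliding-window hydropathy profiles.  Sequences are user-supplied one-letter
strings (e.g. from FASTA); nothing here assumes a particular variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import ProtParamData

from .errors import ConfigurationError, ParameterError, SequenceError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ACIDIC = set("DE")
BASIC = set("KR")
POLAR = set("STNQYHCW")

FREE = "free"
AMIDATED_C = "amidated_C"

#: Named hydropathy scales (per-residue values; higher = more hydrophobic for
#: kyte_doolittle/janin, higher = more hydrophilic for hopp_woods).
HYDROPATHY_SCALES: dict[str, Mapping[str, float]] = {
    "kyte_doolittle": ProtParamData.kd,
    "hopp_woods": ProtParamData.hw,
    "janin": ProtParamData.ja,
}


@dataclass(frozen=True)
class PeptideRecord:
    """A named peptide sequence with optional variant edits.

    ``variant_edits`` entries are ``(position, from_aa, to_aa)`` with 1-based
    positions; they are checked against the sequence, not applied to it.
    """

    name: str
    sequence: str
    variant_edits: tuple = ()

    def __post_init__(self):
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"{self.name}: nonstandard residue letter(s) {sorted(bad)}"
            )
        for pos, _from, to in self.variant_edits:
            if not 1 <= pos <= len(self.sequence):
                raise SequenceError(f"{self.name}: edit position {pos} out of range")
            if self.sequence[pos - 1].upper() != to.upper():
                raise SequenceError(
                    f"{self.name}: edit {pos}{_from}->{to} inconsistent with "
                    f"sequence residue {self.sequence[pos - 1]}"
                )

    def __len__(self):
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    return [
        PeptideRecord(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def net_charge(record: PeptideRecord, termini: str = FREE,
               histidine_charge: int = 0) -> int:
    """Formal net charge at neutral pH.

    +1 per Lys/Arg, −1 per Asp/Glu, plus the terminal contributions: the free
    N-terminal amine adds +1; the C-terminus adds −1 when free and 0 when
    amidated/neutral (simulated peptides carry a neutral C-terminal amide).
    Histidine is neutral by default.
    """
    if termini not in (FREE, AMIDATED_C):
        raise ParameterError(f"unknown termini mode {termini!r}")
    seq = record.sequence.upper()
    charge = sum(+1 for aa in seq if aa in BASIC)
    charge -= sum(1 for aa in seq if aa in ACIDIC)
    charge += histidine_charge * seq.count("H")
    charge += 1  # free N-terminal amine
    if termini == FREE:
        charge -= 1  # free C-terminal carboxylate
    return charge


def helical_wheel(record: PeptideRecord,
                  rotation_per_residue: float = 100.0) -> pd.DataFrame:
    """Idealized helical-wheel angles, one row per residue.

    ``angle_i = (i − 1)·rotation mod 360``; residues i and i+3 / i+4 land
    300° / 40° apart at the canonical 100° per residue, which is what places
    residues with those spacings on the same helix face.  Each residue is
    tagged ``acidic`` / ``basic`` / ``polar`` / ``nonpolar``.
    """
    if not record.sequence:
        raise SequenceError("empty sequence")
    rows = []
    for i, aa in enumerate(record.sequence.upper(), start=1):
        if aa in ACIDIC:
            tag = "acidic"
        elif aa in BASIC:
            tag = "basic"
        elif aa in POLAR:
            tag = "polar"
        else:
            tag = "nonpolar"
        rows.append({
            "position": i,
            "residue": aa,
            "angle_deg": ((i - 1) * rotation_per_residue) % 360.0,
            "polarity": tag,
        })
    return pd.DataFrame(rows)


def hydropathy_profile(record: PeptideRecord, scale: str | Mapping[str, float]
                       = "kyte_doolittle", window: int = 19,
                       protonated_glu: bool = False) -> pd.Series:
    """Centered sliding-window mean hydropathy.

    Ends are truncated (no padding): the profile is indexed by the center
    residue position, from ``(window+1)/2`` to ``L − (window−1)/2``.  With
    ``protonated_glu=True``, Glu is scored with the Gln value of the scale (a
    neutral-amide stand-in for the protonated carboxylic acid).
    """
    if isinstance(scale, str):
        try:
            table = dict(HYDROPATHY_SCALES[scale])
        except KeyError:
            raise ConfigurationError(
                f"unknown hydropathy scale {scale!r}; known: "
                f"{sorted(HYDROPATHY_SCALES)}"
            ) from None
    else:
        table = dict(scale)
    if protonated_glu:
        table["E"] = table["Q"]
    if window % 2 == 0 or window < 1:
        raise ParameterError("window must be a positive odd integer")
    seq = record.sequence.upper()
    if window > len(seq):
        raise ParameterError("window exceeds sequence length")
    try:
        values = np.array([table[aa] for aa in seq], dtype=float)
    except KeyError as exc:
        raise SequenceError(f"scale has no value for residue {exc}") from None
    kernel = np.ones(window) / window
    prof = np.convolve(values, kernel, mode="valid")
    half = (window - 1) // 2
    centers = np.arange(half + 1, len(seq) - half + 1)
    return pd.Series(prof, index=centers, name="hydropathy")


def max_window_hydropathy(record: PeptideRecord, scale="kyte_doolittle",
                          window: int = 19, protonated_glu: bool = False) -> float:
    """Maximum sliding-window score — compared against a transmembrane
    threshold (e.g. 1.6 on the Kyte–Doolittle scale) to ask whether any
    window looks like a classical hydrophobic TM segment."""
    return float(hydropathy_profile(record, scale, window, protonated_glu).max())
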
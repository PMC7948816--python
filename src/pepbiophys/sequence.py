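"""Peptide sequence handling and residue mass accounting.

The package centres on the C-terminal 27-mer of human cardiac troponin I
(residues 184-210, ``ENREVGDWRKNIDALSGMEGRKKKFES``) and its Arg192His
cardiomyopathic variant; sequences carry the numbering of the intact protein
so residue-level observables can be reported in the conventional coordinates.

Masses are average (isotope-abundance-weighted) residue masses from a
versioned data file, plus one water for free N/C termini.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from io import StringIO

from Bio import SeqIO

__all__ = [
    "PeptideSequence",
    "parse_sequence",
    "average_mass",
    "apply_point_mutation",
    "residue_mass_table",
    "WT_C27",
    "C27_START",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Wild-type 27-mer, paper numbering 184-210 (Glu184 ... Ser210).
WT_C27 = "ENREVGDWRKNIDALSGMEGRKKKFES"
C27_START = 184


@lru_cache(maxsize=1)
def residue_mass_table() -> tuple[dict[str, float], float]:
    """(residue-code -> average mass in Da, water mass in Da)."""
    raw = resources.files("pepbiophys.data").joinpath("average_masses.json").read_text()
    table = json.loads(raw)
    masses = {k: float(v) for k, v in table["residues"].items()}
    if any(m <= 0 for m in masses.values()):
        raise ValueError("mass table contains non-positive masses")
    return masses, float(table["water"])


@dataclass(frozen=True)
class PeptideSequence:
    """Single-letter residue string with a numbering offset.

    ``start_number`` is the number of the first residue in the parent-protein
    coordinate system (contiguous numbering).
    """

    residues: str
    start_number: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        for i, code in enumerate(self.residues):
            if code not in AMINO_ACIDS:
                raise ValueError(
                    f"invalid residue code {code!r} at position "
                    f"{self.start_number + i} (sequence index {i + 1})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def numbering(self) -> range:
        return range(self.start_number, self.end_number + 1)

    def residue_at(self, position: int) -> str:
        """Residue code at a parent-protein position."""
        if not (self.start_number <= position <= self.end_number):
            raise ValueError(
                f"position {position} outside sequence range "
                f"{self.start_number}-{self.end_number}"
            )
        return self.residues[position - self.start_number]

    def format(self) -> str:
        return self.residues

    def to_fasta(self) -> str:
        header = self.name or f"peptide_{self.start_number}-{self.end_number}"
        return f">{header}\n{self.residues}\n"


def parse_sequence(text: str, start_number: int = 1, name: str = "") -> PeptideSequence:
    """Parse a single-record FASTA string or an inline residue string.

    Rejects invalid one-letter codes naming the offending position (in the
    parent-protein numbering given by ``start_number``).
    """
    text = text.strip()
    if not text:
        raise ValueError("empty sequence input")
    if text.startswith(">"):
        records = list(SeqIO.parse(StringIO(text), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record, found {len(records)}")
        record = records[0]
        return PeptideSequence(str(record.seq).upper(), start_number, name or record.id)
    return PeptideSequence("".join(text.split()).upper(), start_number, name)


def average_mass(seq: PeptideSequence) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water.

    Free (unmodified) termini are assumed; reproduces conventional peptide
    molecular weights to 0.01 Da.
    """
    masses, water = residue_mass_table()
    return sum(masses[c] for c in seq.residues) + water


def apply_point_mutation(
    seq: PeptideSequence, position: int, new_code: str
) -> PeptideSequence:
    """Replace the residue at a parent-protein position, e.g. (192, 'H') for
    the Arg192His variant. All other residues are unchanged."""
    old = seq.residue_at(position)  # raises on out-of-range
    if new_code not in AMINO_ACIDS:
        raise ValueError(f"invalid residue code {new_code!r}")
    idx = position - seq.start_number
    mutated = seq.residues[:idx] + new_code + seq.residues[idx + 1 :]
    suffix = f"_{old}{position}{new_code}" if new_code != old else ""
    return replace(seq, residues=mutated, name=(seq.name + suffix) if seq.name else "")
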
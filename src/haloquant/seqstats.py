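"""Sequence arithmetic for the cloned enzyme gene.

Small utilities tied to the screening workflow: the length of the protein
encoded by an ORF, standard-genetic-code translation, and the average
(isotope-averaged) molecular mass of a protein, reported the way gene
announcements print it (one water plus the sum of residue masses, in kDa
to one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "OrfSequence",
    "ProteinSequence",
    "orf_protein_length",
    "translate",
    "average_molecular_mass",
    "read_fasta",
    "WATER_MASS_DA",
    "AVERAGE_RESIDUE_MASS_DA",
]


class SequenceError(ValueError):
    """Malformed or invalid biological sequence."""


# Average residue masses in daltons (amino acid minus one water), standard
# isotope-averaged values.
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

WATER_MASS_DA = 18.0153

_STANDARD_AA = set(AVERAGE_RESIDUE_MASS_DA)
_DNA = set("ACGT")


@dataclass(frozen=True)
class OrfSequence:
    """A full open reading frame: start codon through stop codon.

    Input is uppercased and U (RNA) is normalised to T; any other character
    outside {A, C, G, T} is rejected.
    """

    nucleotides: str

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper().replace("U", "T")
        if not seq:
            raise SequenceError("empty ORF sequence")
        bad = set(seq) - _DNA
        if bad:
            raise SequenceError(f"non-ACGT characters in ORF: {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise SequenceError(f"ORF length {len(seq)} not divisible by 3")
        object.__setattr__(self, "nucleotides", seq)

    @property
    def length_bp(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein as one-letter residues (20 standard amino acids only)."""

    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise SequenceError("empty protein sequence")
        bad = set(seq) - _STANDARD_AA
        if bad:
            raise SequenceError(f"non-standard residues: {sorted(bad)}")
        object.__setattr__(self, "residues", seq)

    @property
    def length_aa(self) -> int:
        return len(self.residues)


def orf_protein_length(orf_length_bp: int) -> int:
    """Amino acids encoded by a full ORF: one codon per residue, stop excluded.

    ``orf_length_bp / 3 - 1``; e.g. a 1137 bp ORF encodes 378 residues.
    """
    if orf_length_bp % 3 != 0:
        raise SequenceError(f"ORF length {orf_length_bp} not divisible by 3")
    if orf_length_bp < 6:
        raise SequenceError("a full ORF needs at least one codon plus a stop")
    return orf_length_bp // 3 - 1


def translate(orf: OrfSequence | str) -> ProteinSequence:
    """Translate a full ORF with the standard genetic code (NCBI table 1).

    The trailing stop codon is removed; an internal stop raises
    :class:`SequenceError`.
    """
    if isinstance(orf, str):
        orf = OrfSequence(orf)
    aa = str(Seq(orf.nucleotides).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise SequenceError(f"internal stop codon at residue {aa.index('*') + 1}")
    if not aa:
        raise SequenceError("ORF encodes no residues")
    return ProteinSequence(aa)


def average_molecular_mass(protein: ProteinSequence | str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    if isinstance(protein, str):
        protein = ProteinSequence(protein)
    return sum(AVERAGE_RESIDUE_MASS_DA[r] for r in protein.residues) + WATER_MASS_DA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as a list of (record id, sequence string) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
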
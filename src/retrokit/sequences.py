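"""Basic DNA sequence containers and helpers shared across the toolkit.

Coordinates are 0-based half-open on the forward strand throughout the
library; GFF3 writers convert to 1-based closed on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")

# IUPAC nucleotide codes -> set of concrete bases they match.  N in the
# *genome* never matches a motif position (conservative), which is handled
# at match time, not here.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence (chromosome, scaffold, locus or strain clone).

    Residues are uppercase-normalized on construction; any character
    outside {A,C,G,T,N} is rejected with the offending symbol named.
    """

    id: str
    residues: str
    source_tag: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"sequence {self.id!r} contains non-DNA symbol(s): "
                f"{', '.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= len(self.residues)):
            raise ValueError(
                f"span [{start},{end}) outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start:end]

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id, revcomp(self.residues), self.source_tag)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
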
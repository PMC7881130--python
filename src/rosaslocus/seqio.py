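"""FASTA input/output and the nucleotide-sequence record type."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import IUPAC_SETS, reverse_complement

_VALID_NT = re.compile(r"^[%s]+$" % "".join(sorted(IUPAC_SETS)))


@dataclass
class NucleotideSequence:
    """A named nucleotide sequence (IUPAC alphabet, uppercase-normalised)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not _VALID_NT.match(self.residues):
            bad = sorted(set(self.residues) - set(IUPAC_SETS))
            raise ValueError(f"sequence {self.id!r} contains invalid symbols {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.residues), self.description)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read nucleotide FASTA into NucleotideSequence records."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(NucleotideSequence(rec.id, str(rec.seq), rec.description))
    return out


def write_fasta(records: Iterable[tuple[str, str]] | Iterable[NucleotideSequence],
                path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs or NucleotideSequence records as FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, NucleotideSequence):
            seqrecs.append(SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description))
        else:
            rid, seq = rec
            seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read any FASTA (nucleotide or peptide) into an id -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
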
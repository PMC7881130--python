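"""Six-frame, stop-to-stop ORF extraction (getorf-style semantics).

An ORF is a maximal run of sense codons between two stop codons (or a
sequence end) in one of the six reading frames.  ORFs are not required to
begin with ATG; the screen keeps every segment strictly longer than the
configured nucleotide cutoff (default 100 nt, i.e. >= 34 codons).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import translate_codon
from .seqio import NucleotideSequence

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ScreenParams:
    """Tunables of the ORF + similarity screen."""

    min_orf_nt: int = 100          # strict 'larger than'
    score_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    pass_threshold: float = 1.9    # score-per-residue stand-in for e < 0.05

    def __post_init__(self) -> None:
        if self.min_orf_nt < 3:
            raise ValueError("min_orf_nt must be >= 3")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame, with coordinates on the forward strand.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of
    the codon run, for every frame including the reverse ones.
    """

    source_id: str
    frame: int          # one of +1,+2,+3,-1,-2,-3
    start: int
    end: int
    peptide: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length_nt != 3 * len(self.peptide):
            raise ValueError("coordinate span does not match peptide length")
        if "*" in self.peptide:
            raise ValueError("ORF peptide contains an internal stop")


def _frame_segments(frame_seq: str) -> list[tuple[int, int, str]]:
    """Maximal stop-free codon runs of one frame.

    Returns (codon_start, codon_end, peptide) with coordinates in
    nucleotides of ``frame_seq`` (codon-aligned, half-open).
    """
    n_codons = len(frame_seq) // 3
    segments = []
    seg_start = 0
    peptide: list[str] = []
    for i in range(n_codons):
        codon = frame_seq[3 * i: 3 * i + 3]
        aa = translate_codon(codon)
        if aa == "*":
            if peptide:
                segments.append((seg_start, 3 * i, "".join(peptide)))
            peptide = []
            seg_start = 3 * (i + 1)
        else:
            peptide.append(aa)
    if peptide:
        segments.append((seg_start, 3 * n_codons, "".join(peptide)))
    return segments


def extract_orfs(seq: NucleotideSequence, params: ScreenParams = ScreenParams()) -> list[OrfRecord]:
    """Extract every six-frame ORF strictly longer than ``params.min_orf_nt``.

    Ambiguity codes translate to X (not treated as stops); an all-N
    sequence therefore yields ORFs of X residues only if long enough, and
    an empty result otherwise.  Raises ``ValueError`` on an empty sequence.
    """
    residues = seq.residues
    length = len(residues)
    if length == 0:
        raise ValueError("cannot extract ORFs from an empty sequence")
    rc = seq.reverse_complement().residues

    records: list[OrfRecord] = []
    for frame in FRAMES:
        offset = abs(frame) - 1
        template = residues if frame > 0 else rc
        usable = ((length - offset) // 3) * 3
        if usable <= 0:
            continue
        frame_seq = template[offset: offset + usable]
        for cstart, cend, pep in _frame_segments(frame_seq):
            seg_nt = cend - cstart
            if seg_nt <= params.min_orf_nt:
                continue
            if frame > 0:
                start = offset + cstart
                end = offset + cend
            else:
                # mirror reverse-strand codon run onto the forward strand
                start = length - (offset + cend)
                end = length - (offset + cstart)
            records.append(OrfRecord(seq.id, frame, start, end, pep))
    records.sort(key=lambda r: (r.start, r.end, r.frame))
    return records


def orf_nucleotide_sequence(seq: NucleotideSequence, rec: OrfRecord) -> str:
    """The coding-strand nucleotide sequence of an ORF."""
    sub = seq.residues[rec.start: rec.end]
    if rec.frame < 0:
        from .config import reverse_complement
        sub = reverse_complement(sub)
    return sub
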
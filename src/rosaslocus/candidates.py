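"""Candidacy scoring and the summary classification table.

A screened coding sequence becomes an S-RNase candidate when it encodes a
basic protein (high isoelectric point) and carries the conserved
amino-acid patterns; sequences with internal stops or broken reading
frames are flagged as pseudogenes and excluded from the protein-level
columns of the summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import DEFAULT_PATTERN1, DEFAULT_PATTERN2, translate_codon
from .isoelectric import isoelectric_point
from .motifs import ABSENT, PRESENT, ProsofilePattern, match_pattern, parse_pattern


@dataclass
class CandidateGene:
    """A screened coding sequence with its candidacy annotations.

    ``intron_count`` is a pass-through annotation (intron inference is
    out of scope); ``pseudogene`` is true iff the peptide has an internal
    stop or the CDS length is not a codon multiple.
    """

    id: str
    source: str
    location: tuple[str, int, int, str]     # contig, start, end, strand
    cds: str
    peptide: str = ""
    pi: float | None = None
    motif1_status: str = ABSENT
    motif2_status: str = ABSENT
    pseudogene: bool = False
    intron_count: int | None = None

    def __post_init__(self) -> None:
        if self.pi is not None and not (0.0 < self.pi < 14.0):
            raise ValueError(f"pI {self.pi} outside (0, 14)")

    @property
    def motif1_present(self) -> bool:
        return self.motif1_status != ABSENT

    @property
    def motif2_present(self) -> bool:
        return self.motif2_status != ABSENT

    @property
    def basic_protein(self) -> bool:
        """The S-RNase prior: isoelectric point above 8."""
        return self.pi is not None and self.pi > 8.0


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate an in-frame CDS; returns (peptide, pseudogene_flag).

    A trailing stop codon is trimmed; internal stops or a length not
    divisible by 3 mark the sequence as a pseudogene.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        usable = (len(cds) // 3) * 3
        pep = "".join(translate_codon(cds[i:i + 3]) for i in range(0, usable, 3))
        return pep.rstrip("*"), True
    pep = "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))
    if pep.endswith("*"):
        pep = pep[:-1]
    return pep, "*" in pep


def score_candidate(
    cand: CandidateGene,
    pattern1: ProsofilePattern | None = None,
    pattern2: ProsofilePattern | None = None,
    relaxed_first_position: bool = True,
    pka_set: str | None = None,
) -> CandidateGene:
    """Fill peptide, pseudogene flag, pI and motif statuses in place."""
    pattern1 = pattern1 or parse_pattern(DEFAULT_PATTERN1, "pattern1")
    pattern2 = pattern2 or parse_pattern(DEFAULT_PATTERN2, "pattern2")
    cand.peptide, cand.pseudogene = translate_cds(cand.cds)
    clean = cand.peptide.replace("*", "")
    if clean and set(clean) != {"X"}:
        kwargs = {"pka_set": pka_set} if pka_set else {}
        cand.pi = isoelectric_point(clean, **kwargs)
    cand.motif1_status = match_pattern(clean, pattern1, relaxed_first_position)
    m2 = match_pattern(clean, pattern2, relaxed_first_position=False)
    cand.motif2_status = PRESENT if m2 != ABSENT else ABSENT
    return cand


@dataclass
class ClassificationTable:
    """Per-genome summary counts of the screened S-RNase-like sequences.

    Column semantics follow the screen's reporting convention: motif and
    isoelectric-point columns exclude pseudogenes; the both-motif column
    uses IP >= 7 while the motif-2-only column uses IP > 7 (both
    comparators are intentional and kept distinct).
    """

    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = (
        "total",
        "excluding_pseudogenes",
        "both_motifs",
        "both_motifs_and_ip_ge_7",
        "only_2nd_motif",
        "only_2nd_and_ip_gt_7",
        "only_1st_motif",
    )


def classify_candidates(candidates: list[CandidateGene],
                        ip_threshold: float = 7.0) -> ClassificationTable:
    """Tally candidates per source genome into the summary table."""
    rows: dict[str, dict[str, int]] = {}
    for cand in candidates:
        row = rows.setdefault(cand.source, {c: 0 for c in ClassificationTable.COLUMNS})
        row["total"] += 1
        if cand.pseudogene:
            continue
        row["excluding_pseudogenes"] += 1
        m1, m2 = cand.motif1_present, cand.motif2_present
        pi = cand.pi
        if m1 and m2:
            row["both_motifs"] += 1
            if pi is not None and pi >= ip_threshold:
                row["both_motifs_and_ip_ge_7"] += 1
        elif m2:
            row["only_2nd_motif"] += 1
            if pi is not None and pi > ip_threshold:
                row["only_2nd_and_ip_gt_7"] += 1
        elif m1:
            row["only_1st_motif"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(ClassificationTable.COLUMNS))
    frame.index.name = "source"
    return ClassificationTable(frame)
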
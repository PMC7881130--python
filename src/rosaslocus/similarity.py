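"""Translated similarity screening of ORF peptides against references.

Local (Smith–Waterman) protein alignment replaces the BLAST step of the
original screen: without BLAST's e-value statistics, candidacy is decided
by a length-normalised local alignment score — the raw score divided by
the query peptide length, so a hit must cover a substantial fraction of
the ORF to pass (per-aligned-column scores reward tiny spurious local
matches).  The pass threshold is calibrated on shuffled-reference
fragments at the minimum ORF length (the worst-case null, since random
score per residue shrinks with query length) to a chosen false-pass rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .orf import OrfRecord, ScreenParams

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 10


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    raw_score: float
    normalized_score: float     # score per query residue
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    pass_flag: bool


def _neutral_x_matrix(name: str):
    """Substitution matrix with the X row/column zeroed (X scores neutral)."""
    mat = substitution_matrices.load(name)
    arr = np.array(mat)
    alphabet = mat.alphabet
    if "X" in alphabet:
        ix = alphabet.index("X")
        arr[ix, :] = 0.0
        arr[:, ix] = 0.0
    return substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)


def make_aligner(params: ScreenParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _neutral_x_matrix(params.score_matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(aligner: Align.PairwiseAligner, query: str, subject: str):
    """Best local alignment; returns (score, columns, q_interval, s_interval)."""
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0, (0, 0), (0, 0)
    aln = alignments[0]
    qblocks, sblocks = aln.aligned
    q_iv = (int(qblocks[0][0]), int(qblocks[-1][1]))
    s_iv = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return float(aln.score), int(aln.length), q_iv, s_iv


def translated_similarity_screen(
    orfs: list[OrfRecord],
    references: dict[str, str],
    params: ScreenParams = ScreenParams(),
) -> list[SimilarityHit]:
    """Score every ORF peptide against every reference peptide.

    Hits whose score-per-residue reaches ``params.pass_threshold`` carry
    ``pass_flag=True``.  Peptides shorter than 10 aa are skipped with a
    logged warning; an empty reference set is an error.
    """
    if not references:
        raise ValueError("reference peptide set is empty")
    aligner = make_aligner(params)
    hits: list[SimilarityHit] = []
    for rec in orfs:
        if len(rec.peptide) < MIN_PEPTIDE_LEN:
            logger.warning("skipping ORF %s: peptide shorter than %d aa",
                           orf_label(rec), MIN_PEPTIDE_LEN)
            continue
        for ref_id, ref_pep in references.items():
            score, columns, q_iv, s_iv = align_pair(aligner, rec.peptide, ref_pep)
            norm = score / len(rec.peptide)
            hits.append(SimilarityHit(
                query_id=orf_label(rec),
                subject_id=ref_id,
                raw_score=score,
                normalized_score=norm,
                query_interval=q_iv,
                subject_interval=s_iv,
                pass_flag=norm >= params.pass_threshold,
            ))
    return hits


def orf_label(rec: OrfRecord) -> str:
    strand = "+" if rec.frame > 0 else "-"
    return f"{rec.source_id}:{rec.start}-{rec.end}({strand}{abs(rec.frame)})"


def calibrate_pass_threshold(
    references: dict[str, str],
    params: ScreenParams,
    seed: int,
    n_null: int = 500,
    false_pass_rate: float = 0.002,
) -> float:
    """Pass threshold giving <= ``false_pass_rate`` on shuffled-peptide nulls.

    Each null is a fragment of a residue-shuffled reference (composition
    preserved, order destroyed) at the minimum ORF peptide length — the
    worst case, since the random score per residue decreases with query
    length.  The null statistic matches the screen's decision: the best
    per-residue score over all references.  The threshold is the
    (1 - fpr) quantile of that null distribution; the default fpr is
    per tested ORF, so a genome-scale screen with thousands of background
    ORFs stays near zero expected false candidates.
    """
    if not references:
        raise ValueError("reference peptide set is empty")
    rng = np.random.default_rng(seed)
    aligner = make_aligner(params)
    ref_peps = list(references.values())
    frag_len = max(params.min_orf_nt // 3 + 1, MIN_PEPTIDE_LEN)
    null_scores = []
    for i in range(n_null):
        base = ref_peps[i % len(ref_peps)]
        shuffled = "".join(rng.permutation(list(base)))
        if len(shuffled) > frag_len:
            start = int(rng.integers(0, len(shuffled) - frag_len + 1))
            shuffled = shuffled[start:start + frag_len]
        best = 0.0
        for ref_pep in ref_peps:
            score, _columns, _, _ = align_pair(aligner, shuffled, ref_pep)
            best = max(best, score / len(shuffled))
        null_scores.append(best)
    return float(np.quantile(np.asarray(null_scores), 1.0 - false_pass_rate))
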
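"""Shared constants: genetic code, pKa tables, motif patterns, enzymes.

Everything downstream (ORF translation, NG86 counting, codon models,
pI solving, digestion) reads the standard genetic code and ionisation
constants from here, so alternate tables can be swapped in one place.
"""

from __future__ import annotations

from Bio.Data import CodonTable, IUPACData

# ---------------------------------------------------------------------------
# Genetic code (standard table 1)
# ---------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (one letter), sense codons only
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: 61 sense codons in fixed lexicographic order (state space of codon models)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"))
)
SENSE_CODONS = tuple(c for c in SENSE_CODONS if c not in STOP_CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguity (non-ACGT) -> 'X', stop -> '*'."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    aa = CODON_TABLE.get(codon)
    return aa if aa is not None else "X"


# ---------------------------------------------------------------------------
# IUPAC nucleotide ambiguity codes
# ---------------------------------------------------------------------------

#: IUPAC symbol -> set of unambiguous bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    k: frozenset(v) for k, v in IUPACData.ambiguous_dna_values.items()
}

COMPLEMENT: dict[str, str] = {
    k.upper(): v.upper() for k, v in IUPACData.ambiguous_dna_complement.items()
}


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# pKa tables for isoelectric-point calculation
# ---------------------------------------------------------------------------
# "bjellqvist" is the ExPASy set (the default; values as used by ExPASy's
# Compute pI/Mw). N-terminal pKa depends on the first residue.

PKA_TABLES: dict[str, dict] = {
    "bjellqvist": {
        "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "cterm": 3.55,
        "cterm_by_residue": {"D": 4.55, "E": 4.75},
        "nterm_default": 7.5,
        "nterm_by_residue": {
            "A": 7.59,
            "M": 7.0,
            "S": 6.93,
            "P": 8.36,
            "T": 6.82,
            "V": 7.44,
            "E": 7.7,
        },
    },
    "emboss": {
        "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        "cterm": 3.6,
        "cterm_by_residue": {},
        "nterm_default": 8.6,
        "nterm_by_residue": {},
    },
}

DEFAULT_PKA_SET = "bjellqvist"

# ---------------------------------------------------------------------------
# Conserved amino-acid patterns of S-RNases (PROSITE syntax)
# ---------------------------------------------------------------------------
# The canonical patterns are defined in the T2/S-RNase literature and are not
# reproduced here; these defaults are NON-CANONICAL placeholders with the same
# structure (pattern 1 starts with [FST], which the relaxed rule widens to Y).
# Real analyses should supply the published patterns via configuration.

DEFAULT_PATTERN1 = "[FST]-H-G-L-W-P"
DEFAULT_PATTERN2 = "K-H-G-T-C"

# ---------------------------------------------------------------------------
# Restriction enzymes (recognition site with '^' marking the cut offset on
# the given strand)
# ---------------------------------------------------------------------------

RESTRICTION_ENZYMES: dict[str, str] = {
    "DdeI": "C^TNAG",
    "HinfI": "G^ANTC",
    "EcoRI": "G^AATTC",
}

# ---------------------------------------------------------------------------
# The genotype-association primer pair (degenerate, IUPAC)
# ---------------------------------------------------------------------------

PRIMER_RA_F = "GGAAGCCARACTGAAGAT"
PRIMER_RA_R = "AGCATCACAGTYTCGATCA"
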
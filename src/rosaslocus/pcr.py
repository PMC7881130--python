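"""In-silico PCR with degenerate primers and restriction digestion.

Primer binding uses IUPAC-aware matching: a template base matches a
primer symbol iff it belongs to the symbol's base set.  The forward
primer is scanned along the forward strand and the reverse primer as its
reverse complement; compatible site pairs yield amplicons whose length
(inclusive of both primers) is the genotyping assay's product size.
Restriction digestion locates recognition sites on both strands and cuts
a linear template at the enzyme's offset.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import IUPAC_SETS, RESTRICTION_ENZYMES, reverse_complement
from .seqio import NucleotideSequence

MIN_PRIMER_LEN = 10


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_PRIMER_LEN:
            raise ValueError(f"primer {self.name!r} shorter than {MIN_PRIMER_LEN} nt")
        bad = sorted(set(seq) - set(IUPAC_SETS))
        if bad:
            raise ValueError(f"primer {self.name!r} has invalid symbols {bad}")


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    forward_interval: tuple[int, int]     # 0-based half-open, forward strand
    reverse_interval: tuple[int, int]
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def product_length_nt(self) -> int:
        return self.reverse_interval[1] - self.forward_interval[0]


@dataclass(frozen=True)
class DigestPattern:
    enzyme: str
    recognition: str
    fragment_lengths: tuple[int, ...]     # sorted descending, linear template
    cut_positions: tuple[int, ...]


def _symbol_matches(template_base: str, primer_symbol: str) -> bool:
    return template_base in IUPAC_SETS.get(primer_symbol, frozenset())


def _scan_primer(template: str, primer: str, max_mismatch: int,
                 three_prime_exact_nt: int, three_prime_at_end: bool) -> list[tuple[int, int]]:
    """All (start, mismatches) where the primer binds the forward strand.

    ``three_prime_at_end`` marks whether the primer's 3' terminus sits at
    the right end of the written pattern (true for a forward primer and
    for a reverse-complemented reverse primer whose 3' end points left —
    the latter passes False).
    """
    hits = []
    plen = len(primer)
    exact = min(three_prime_exact_nt, plen)
    for start in range(len(template) - plen + 1):
        window = template[start:start + plen]
        mism = 0
        ok = True
        for k, (tb, ps) in enumerate(zip(window, primer)):
            if _symbol_matches(tb, ps):
                continue
            in_clamp = (k >= plen - exact) if three_prime_at_end else (k < exact)
            if in_clamp:
                ok = False
                break
            mism += 1
            if mism > max_mismatch:
                ok = False
                break
        if ok:
            hits.append((start, mism))
    return hits


def find_amplicons(
    template: NucleotideSequence,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 0,
    three_prime_exact_nt: int = 3,
    min_product_nt: int = 40,
    max_product_nt: int = 5000,
) -> list[AmpliconPrediction]:
    """Predict products of a primer pair on a linear template.

    Returns every compatible forward/reverse site pair with product
    length inside the configured bounds; an empty list means no product.
    """
    seq = template.residues
    if len(seq) < len(fwd.sequence) + len(rev.sequence):
        return []
    fwd_hits = _scan_primer(seq, fwd.sequence, max_mismatch,
                            three_prime_exact_nt, three_prime_at_end=True)
    rev_rc = reverse_complement(rev.sequence)
    # after reverse complementing, the reverse primer's 3' end is leftmost
    rev_hits = _scan_primer(seq, rev_rc, max_mismatch,
                            three_prime_exact_nt, three_prime_at_end=False)
    out = []
    for fstart, fmism in fwd_hits:
        fend = fstart + len(fwd.sequence)
        for rstart, rmism in rev_hits:
            rend = rstart + len(rev_rc)
            if rstart < fend:
                continue
            product = rend - fstart
            if min_product_nt <= product <= max_product_nt:
                out.append(AmpliconPrediction(
                    template_id=template.id,
                    forward_interval=(fstart, fend),
                    reverse_interval=(rstart, rend),
                    forward_mismatches=fmism,
                    reverse_mismatches=rmism,
                ))
    out.sort(key=lambda a: (a.forward_interval, a.reverse_interval))
    return out


def _parse_enzyme(pattern: str) -> tuple[str, int]:
    if "^" not in pattern:
        raise ValueError("enzyme pattern needs a '^' cut marker")
    cut = pattern.index("^")
    site = pattern.replace("^", "").upper()
    bad = sorted(set(site) - set(IUPAC_SETS))
    if bad:
        raise ValueError(f"enzyme pattern has invalid symbols {bad}")
    return site, cut


def _find_sites(template: str, site: str) -> list[int]:
    hits = []
    for start in range(len(template) - len(site) + 1):
        if all(_symbol_matches(tb, ps)
               for tb, ps in zip(template[start:start + len(site)], site)):
            hits.append(start)
    return hits


def digest(template: NucleotideSequence, enzyme: str,
           pattern: str | None = None) -> DigestPattern:
    """Fragment lengths of a linear template cut by one enzyme.

    ``enzyme`` may name a shipped enzyme (DdeI, HinfI, ...) or be
    accompanied by an explicit ``pattern`` like ``C^TNAG``.  Sites are
    located on both strands and resolved to unique cut positions on the
    forward strand.
    """
    if pattern is None:
        try:
            pattern = RESTRICTION_ENZYMES[enzyme]
        except KeyError:
            raise ValueError(f"unknown enzyme {enzyme!r}; supply a pattern") from None
    site, cut = _parse_enzyme(pattern)
    seq = template.residues
    plus_sites = set(_find_sites(seq, site))
    positions = {start + cut for start in plus_sites}
    # a location matching only on the minus strand is cut at the mirrored
    # offset; a palindromic match on both strands is a single cut event
    rc_site = reverse_complement(site)
    for start in _find_sites(seq, rc_site):
        if start not in plus_sites:
            positions.add(start + len(site) - cut)
    cuts = tuple(sorted(p for p in positions if 0 < p < len(seq)))
    bounds = (0,) + cuts + (len(seq),)
    fragments = tuple(sorted((bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)),
                             reverse=True))
    return DigestPattern(enzyme, pattern, fragments, cuts)
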
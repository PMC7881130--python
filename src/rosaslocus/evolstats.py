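"""Nei–Gojobori (1986) divergence and synonymous-site polymorphism.

Synonymous and non-synonymous sites are counted per codon from the
standard genetic code (mutations to stop codons are excluded from the
site denominators), and differences between codons are resolved by
equal-weight averaging over all minimal substitution pathways, with
pathways passing through stop codons discarded.  Observed proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3), which is undefined for
p >= 3/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .config import CODON_TABLE, STOP_CODONS
from .phylo import Alignment

JC_LIMIT = 0.75


@dataclass(frozen=True)
class NGCounts:
    pair: tuple[str, str]
    S: float            # synonymous sites (average of the two sequences)
    N: float            # non-synonymous sites
    Sd: float           # synonymous differences (pathway-averaged)
    Nd: float
    codons_used: int
    codons_skipped: int = 0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0


@dataclass(frozen=True)
class DivergenceEstimate:
    group_id: str
    pS: float
    pN: float
    dS: float | None          # None when the JC correction is undefined
    dN: float | None
    n_pairs: int = 1
    n_undefined: int = 0

    @property
    def dS_defined(self) -> bool:
        return self.dS is not None

    @property
    def dN_defined(self) -> bool:
        return self.dN is not None


@dataclass(frozen=True)
class PolymorphismEstimate:
    group_id: str
    n_sequences: int
    pi_total: float            # mean pairwise p-distance over all sites
    pi_synonymous: float       # mean pairwise Sd/S (optionally JC-corrected)
    correction: str = "none"   # none | JC

    @property
    def pi_synonymous_percent(self) -> float:
        return 100.0 * self.pi_synonymous


def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one sense codon (0..3).

    Per position: synonymous single-nucleotide changes over all non-stop
    changes at that position.
    """
    aa = CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(Sd, Nd) averaged over minimal substitution pathways.

    Pathways through stop codons are discarded; returns None when every
    pathway is blocked (the codon pair is then skipped by the caller).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


def _is_sense(codon: str) -> bool:
    return codon in CODON_TABLE


def ng86_counts(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> NGCounts:
    """Nei–Gojobori site and difference counts for one aligned pair.

    Sequences must be equal-length, in frame; codons containing gaps,
    ambiguity codes or stops in either sequence are skipped pairwise.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValueError("alignment length not divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if not (_is_sense(ca) and _is_sense(cb)):
            skipped += 1
            continue
        diffs = _pathway_differences(ca, cb)
        if diffs is None:
            skipped += 1
            continue
        sa, sb = _syn_site_fraction(ca), _syn_site_fraction(cb)
        S += 0.5 * (sa + sb)
        N += 3.0 - 0.5 * (sa + sb)
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    return NGCounts((id_a, id_b), S, N, Sd, Nd, used, skipped)


def jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None when undefined (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= JC_LIMIT:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pair_divergence(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> DivergenceEstimate:
    counts = ng86_counts(cds_a, cds_b, id_a, id_b)
    return DivergenceEstimate(
        group_id=f"{id_a}|{id_b}",
        pS=counts.pS, pN=counts.pN,
        dS=jc_correct(counts.pS), dN=jc_correct(counts.pN),
    )


def group_divergence(aln: Alignment, group_id: str = "group") -> DivergenceEstimate:
    """Mean pairwise JC-corrected dS and dN over all defined pairs."""
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    ds_vals, dn_vals = [], []
    ps_vals, pn_vals = [], []
    undefined = 0
    n_pairs = 0
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            n_pairs += 1
            counts = ng86_counts(aln.rows[i], aln.rows[j], aln.ids[i], aln.ids[j])
            ds, dn = jc_correct(counts.pS), jc_correct(counts.pN)
            ps_vals.append(counts.pS)
            pn_vals.append(counts.pN)
            if ds is None or dn is None:
                undefined += 1
                continue
            ds_vals.append(ds)
            dn_vals.append(dn)
    if not ds_vals:
        raise ValueError("JC correction undefined for every pair")
    return DivergenceEstimate(
        group_id=group_id,
        pS=sum(ps_vals) / n_pairs,
        pN=sum(pn_vals) / n_pairs,
        dS=sum(ds_vals) / len(ds_vals),
        dN=sum(dn_vals) / len(dn_vals),
        n_pairs=n_pairs,
        n_undefined=undefined,
    )


def synonymous_polymorphism(aln: Alignment, correction: str = "none",
                            group_id: str = "group") -> PolymorphismEstimate:
    """Average pairwise synonymous-site diversity (pi_s) of a gene family."""
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("none", "JC"):
        raise ValueError("correction must be 'none' or 'JC'")
    pis, totals = [], []
    undefined = 0
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            counts = ng86_counts(aln.rows[i], aln.rows[j], aln.ids[i], aln.ids[j])
            value = counts.pS
            if correction == "JC":
                corrected = jc_correct(value)
                if corrected is None:
                    undefined += 1
                    continue
                value = corrected
            pis.append(value)
            if counts.codons_used:
                total_p = (counts.Sd + counts.Nd) / (3.0 * counts.codons_used)
                totals.append(total_p)
    if not pis:
        raise ValueError("no pair yields a defined synonymous diversity")
    return PolymorphismEstimate(
        group_id=group_id,
        n_sequences=len(aln),
        pi_total=sum(totals) / len(totals) if totals else 0.0,
        pi_synonymous=sum(pis) / len(pis),
        correction=correction,
    )
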
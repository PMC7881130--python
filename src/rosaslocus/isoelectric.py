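"""Protein isoelectric point by bisection on the Henderson–Hasselbalch charge.

The net charge of a peptide at a given pH sums the partial charges of the
free termini and the ionisable side chains (D, E, C, Y negative; H, K, R
positive).  charge(pH) is strictly decreasing, so the pI — the root of
charge(pH) = 0 — is found by bisection to a fixed tolerance.  The pKa set
is selectable; the default is the ExPASy/Bjellqvist table.
"""

from __future__ import annotations

from collections import Counter

from .config import DEFAULT_PKA_SET, PKA_TABLES

PI_TOLERANCE = 1e-3
_PH_LO, _PH_HI = 0.0, 14.0


def net_charge(peptide: str, ph: float, pka_set: str = DEFAULT_PKA_SET) -> float:
    """Net charge of ``peptide`` at ``ph``; X residues carry no charge."""
    table = PKA_TABLES[pka_set]
    peptide = peptide.upper()
    counts = Counter(peptide)

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    nterm_pka = table["nterm_by_residue"].get(peptide[0], table["nterm_default"])
    cterm_pka = table["cterm_by_residue"].get(peptide[-1], table["cterm"])
    charge = pos(nterm_pka) + neg(cterm_pka)
    for aa, pka in table["positive"].items():
        if counts[aa]:
            charge += counts[aa] * pos(pka)
    for aa, pka in table["negative"].items():
        if counts[aa]:
            charge += counts[aa] * neg(pka)
    return charge


def isoelectric_point(peptide: str, pka_set: str = DEFAULT_PKA_SET,
                      tolerance: float = PI_TOLERANCE) -> float:
    """pH at which the peptide's net charge is zero (bisection).

    Raises ``ValueError`` for an empty peptide or one made only of X
    (no resolvable ionisable groups).
    """
    if not peptide:
        raise ValueError("peptide is empty")
    if set(peptide.upper()) <= {"X"}:
        raise ValueError("no ionizable groups resolvable: peptide is all X")
    lo, hi = _PH_LO, _PH_HI
    # charge is monotone decreasing in pH: charge(lo) > 0 > charge(hi)
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(peptide, mid, pka_set) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
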
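"""PROSITE-style amino-acid pattern parsing and matching.

Patterns use the PROSITE syntax: elements separated by ``-``; an element
is a residue letter, ``x`` (any residue), ``[ABC]`` (allowed set) or
``{ABC}`` (forbidden set), optionally followed by a repetition ``(n)`` or
``(n,m)``; ``<``/``>`` anchor the pattern to the termini.  Matching is
performed by a direct backtracking scanner (no regex), so the regex
translation can serve as an independent oracle in tests.

The screen's "relaxed first position" rule — accepting Y where the first
element requires [FST], a violation observed in bona fide S-RNases —
is applied by the matcher itself when requested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STRICT = "strict"
RELAXED_Y = "relaxed_Y"
ABSENT = "absent"
PRESENT = "present"


class PatternSyntaxError(ValueError):
    """Malformed PROSITE pattern; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class PatternElement:
    allowed: frozenset[str] | None   # None = wildcard
    negated: bool = False
    min_rep: int = 1
    max_rep: int = 1

    def matches(self, residue: str) -> bool:
        if self.allowed is None:
            return True
        if self.negated:
            return residue not in self.allowed
        return residue in self.allowed


@dataclass(frozen=True)
class ProsofilePattern:
    """A parsed PROSITE-style pattern."""

    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False
    name: str = "custom"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")


_REP_RE = re.compile(r"^\((\d+)(?:,(\d+))?\)")


def parse_pattern(text: str, name: str = "custom") -> ProsofilePattern:
    """Parse PROSITE syntax into a ProsofilePattern.

    Raises PatternSyntaxError with the character position on malformed
    input.
    """
    raw = text.strip().rstrip(".")
    anchored_start = raw.startswith("<")
    if anchored_start:
        raw = raw[1:]
    anchored_end = raw.endswith(">")
    if anchored_end:
        raw = raw[:-1]
    if not raw:
        raise PatternSyntaxError("empty pattern", 0)

    elements: list[PatternElement] = []
    pos = 0
    for token in raw.split("-"):
        if not token:
            raise PatternSyntaxError("empty element", pos)
        i = 0
        if token[i] in ("[", "{"):
            closer = "]" if token[i] == "[" else "}"
            j = token.find(closer, i)
            if j < 0:
                raise PatternSyntaxError(f"unclosed {token[i]!r}", pos + i)
            residues = token[i + 1: j]
            if not residues or any(r not in AMINO_ACIDS for r in residues.upper()):
                raise PatternSyntaxError("invalid residue set", pos + i + 1)
            allowed = frozenset(residues.upper())
            negated = closer == "}"
            i = j + 1
        elif token[i].lower() == "x":
            allowed, negated = None, False
            i += 1
        elif token[i].upper() in AMINO_ACIDS:
            allowed, negated = frozenset(token[i].upper()), False
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {token[i]!r}", pos + i)

        min_rep = max_rep = 1
        rest = token[i:]
        if rest:
            m = _REP_RE.match(rest)
            if not m or m.end() != len(rest):
                raise PatternSyntaxError(f"bad repetition {rest!r}", pos + i)
            min_rep = int(m.group(1))
            max_rep = int(m.group(2)) if m.group(2) else min_rep
            if min_rep > max_rep:
                raise PatternSyntaxError("repetition min > max", pos + i)
        elements.append(PatternElement(allowed, negated, min_rep, max_rep))
        pos += len(token) + 1
    return ProsofilePattern(tuple(elements), anchored_start, anchored_end, name, text)


def _match_from(peptide: str, start: int, elements: tuple[PatternElement, ...],
                idx: int, anchored_end: bool) -> bool:
    if idx == len(elements):
        return (not anchored_end) or start == len(peptide)
    elem = elements[idx]
    # consume the mandatory repetitions, then branch on the optional ones
    pos = start
    for _ in range(elem.min_rep):
        if pos >= len(peptide) or not elem.matches(peptide[pos]):
            return False
        pos += 1
    n_optional = elem.max_rep - elem.min_rep
    for extra in range(n_optional + 1):
        if _match_from(peptide, pos, elements, idx + 1, anchored_end):
            return True
        if extra == n_optional:
            break
        if pos >= len(peptide) or not elem.matches(peptide[pos]):
            return False
        pos += 1
    return False


def pattern_matches(peptide: str, pattern: ProsofilePattern) -> bool:
    """True if the pattern matches anywhere in the peptide (or at the
    anchored position)."""
    peptide = peptide.upper()
    starts = [0] if pattern.anchored_start else range(len(peptide) + 1)
    return any(
        _match_from(peptide, s, pattern.elements, 0, pattern.anchored_end)
        for s in starts
    )


def _relax_first_position(pattern: ProsofilePattern) -> ProsofilePattern:
    first = pattern.elements[0]
    if first.allowed is None or first.negated:
        widened = first
    else:
        widened = PatternElement(first.allowed | {"Y"}, False, first.min_rep, first.max_rep)
    return ProsofilePattern((widened,) + pattern.elements[1:],
                            pattern.anchored_start, pattern.anchored_end,
                            pattern.name, pattern.source)


def match_pattern(peptide: str, pattern: ProsofilePattern,
                  relaxed_first_position: bool = False) -> str:
    """Motif status: ``strict``, ``relaxed_Y`` or ``absent``.

    ``relaxed_Y`` is reported when the pattern fails as written but
    matches once Y is additionally allowed at the first element and the
    relaxation is enabled.
    """
    if pattern_matches(peptide, pattern):
        return STRICT
    if relaxed_first_position and pattern_matches(peptide, _relax_first_position(pattern)):
        return RELAXED_Y
    return ABSENT


def pattern_to_regex(pattern: ProsofilePattern) -> str:
    """Regex translation of a pattern (used as an independent matcher)."""
    parts = []
    for elem in pattern.elements:
        if elem.allowed is None:
            body = "."
        elif elem.negated:
            body = "[^%s]" % "".join(sorted(elem.allowed))
        else:
            body = "[%s]" % "".join(sorted(elem.allowed))
        if (elem.min_rep, elem.max_rep) != (1, 1):
            body += "{%d,%d}" % (elem.min_rep, elem.max_rep)
        parts.append(body)
    core = "".join(parts)
    if pattern.anchored_start:
        core = "^" + core
    if pattern.anchored_end:
        core += "$"
    return core
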
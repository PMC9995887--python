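"""PROSITE-style motif patterns for the PA2c domain and a scanner for them.

The PA2c domain carries two short diagnostic motifs: the calcium-binding
loop and the catalytic histidine-aspartate (HD) dyad.  Canonical secreted
sPLA2 proteins carry YGKYCGxxxxGC and DxCCxxHDxC; the PLA2-like family
carries the variant forms YGHYCGxxxxxGK (one extra residue in the loop)
and DxCCxxHDxG (terminal cysteine lost).  Patterns are written with
uppercase literals and lowercase ``x`` wildcards, the only constructs
these motifs need; bracket classes and ``x(n)`` repeats are a documented
extension point, not implemented.

Matching is conservative with respect to ambiguity: the residue ``X``
satisfies an ``x`` wildcard but never a literal position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from pa2c.core import PROTEIN_LETTERS, Pa2cError, ProteinRecord

#: regex character class for one wildcard position (any standard residue or X)
_X_CLASS = "[" + "".join(sorted(PROTEIN_LETTERS)) + "]"


class PatternError(Pa2cError):
    """Illegal motif pattern syntax."""


@dataclass(frozen=True)
class MotifPattern:
    """A named pattern of uppercase literals and ``x`` wildcards."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise PatternError(f"{self.name}: empty pattern")
        for ch in self.pattern:
            if ch != "x" and not ("A" <= ch <= "Z"):
                raise PatternError(
                    f"{self.name}: illegal pattern character {ch!r} "
                    "(uppercase literals and 'x' only)"
                )

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """A located motif hit; start/end are 1-based inclusive."""

    pattern: str
    sequence_id: str
    start: int
    end: int
    matched: str


# The four bundled diagnostics.  CA_* are calcium-binding loop variants,
# CAT_* catalytic-dyad variants; *_CANON marks the canonical sPLA2 form,
# *_LIKE the PLA2-like form.  The stricter historic dyad spelling with an
# alanine at position 2 (DACC...) is detected downstream as a boolean
# feature, not a separate pattern.
CA_CANON = MotifPattern("CA_CANON", "YGKYCGxxxxGC")
CA_LIKE = MotifPattern("CA_LIKE", "YGHYCGxxxxxGK")
CAT_CANON = MotifPattern("CAT_CANON", "DxCCxxHDxC")
CAT_LIKE = MotifPattern("CAT_LIKE", "DxCCxxHDxG")


def builtin_patterns() -> list[MotifPattern]:
    """The four bundled PA2c diagnostic patterns."""
    return [CA_CANON, CA_LIKE, CAT_CANON, CAT_LIKE]


@dataclass(frozen=True)
class CompiledPattern:
    """A compiled scanner for one motif pattern."""

    pattern: MotifPattern
    _regex: re.Pattern

    def finditer(self, sequence: str) -> Iterable[int]:
        """Yield 0-based start offsets of all (overlapping) matches."""
        for m in self._regex.finditer(sequence):
            yield m.start()

    def matches_at(self, sequence: str, offset: int) -> bool:
        """Position-by-position check at a 0-based offset (oracle-friendly)."""
        window = sequence[offset : offset + self.pattern.length]
        if len(window) < self.pattern.length:
            return False
        for p, c in zip(self.pattern.pattern, window):
            if p == "x":
                if c not in PROTEIN_LETTERS:
                    return False
            elif c != p:
                return False
        return True


def compile_pattern(pattern: MotifPattern) -> CompiledPattern:
    """Compile a pattern to an overlap-reporting scanner.

    A window matches iff every literal position equals the window residue
    and every ``x`` position holds any standard residue (or X).
    """
    parts = ["(?=("]
    for ch in pattern.pattern:
        parts.append(_X_CLASS if ch == "x" else re.escape(ch))
    parts.append("))")
    return CompiledPattern(pattern, re.compile("".join(parts)))


def scan(
    record: ProteinRecord, patterns: Optional[Iterable[MotifPattern]] = None
) -> list[MotifMatch]:
    """All overlapping matches of all patterns, sorted by start then name."""
    if patterns is None:
        patterns = builtin_patterns()
    hits: list[MotifMatch] = []
    for pat in patterns:
        compiled = compile_pattern(pat)
        for off in compiled.finditer(record.sequence):
            hits.append(
                MotifMatch(
                    pattern=pat.name,
                    sequence_id=record.id,
                    start=off + 1,
                    end=off + pat.length,
                    matched=record.sequence[off : off + pat.length],
                )
            )
    hits.sort(key=lambda h: (h.start, h.pattern))
    return hits


@dataclass(frozen=True)
class DomainSpan:
    """The approximate PA2c domain: calcium-loop start to catalytic-motif end."""

    start: int
    end: int


def pa2c_domain_span(
    matches: list[MotifMatch],
) -> tuple[Optional[DomainSpan], list[str]]:
    """Combine the left-most calcium-loop and catalytic hits into a span.

    Returns ``(span, flags)``.  The span is absent when either motif is
    missing; a catalytic hit upstream of the calcium loop yields no span
    and an ``ORDER_VIOLATION`` flag.  Only the left-most hit of each
    motif class is consumed, for determinism.
    """
    ca = next((m for m in matches if m.pattern.startswith("CA_")), None)
    cat = next((m for m in matches if m.pattern.startswith("CAT_")), None)
    if ca is None or cat is None:
        return None, []
    if cat.start <= ca.start:
        return None, ["ORDER_VIOLATION"]
    return DomainSpan(start=ca.start, end=cat.end), []


def load_patterns_tsv(path) -> list[MotifPattern]:
    """Load custom patterns from a two-column TSV (name, pattern)."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PatternError(f"{path}:{line_no}: expected 2 columns")
            out.append(MotifPattern(name=fields[0], pattern=fields[1]))
    return out
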
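"""Degenerate protein motif patterns: parsing, serialization and scanning.

Patterns use the dash-joined notation common in the transporter
literature: exact residues (``E``), bracketed alternative sets
(``[AG]``), and ``X`` wildcards with optional repeat counts (``X2``).
Example: ``G-I-G-X-[FY]-[LI]-X3-[GA]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .alignment import AA_LETTERS, GAP


class TokenKind(Enum):
    EXACT = "exact"
    CLASS = "class"
    WILDCARD = "wildcard"


@dataclass(frozen=True)
class MotifToken:
    kind: TokenKind
    residues: frozenset[str] = frozenset()

    def matches(self, aa: str) -> bool:
        if self.kind is TokenKind.WILDCARD:
            return aa in AA_LETTERS
        return aa in self.residues


def exact(aa: str) -> MotifToken:
    return MotifToken(TokenKind.EXACT, frozenset(aa))


def residue_class(residues: str | frozenset[str]) -> MotifToken:
    s = frozenset(residues)
    if len(s) == 1:
        return MotifToken(TokenKind.EXACT, s)
    return MotifToken(TokenKind.CLASS, s)


WILDCARD = MotifToken(TokenKind.WILDCARD)


class PatternError(ValueError):
    """Raised for malformed pattern text; message carries the token index."""


@dataclass
class MotifPattern:
    """A parsed degenerate pattern: one token per (expanded) position."""

    tokens: list[MotifToken]
    source_text: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def serialize(self) -> str:
        """Render back to dash-joined text, collapsing wildcard runs to Xn."""
        parts: list[str] = []
        i = 0
        while i < len(self.tokens):
            tok = self.tokens[i]
            if tok.kind is TokenKind.WILDCARD:
                n = 1
                while (
                    i + n < len(self.tokens)
                    and self.tokens[i + n].kind is TokenKind.WILDCARD
                ):
                    n += 1
                parts.append("X" if n == 1 else f"X{n}")
                i += n
            elif tok.kind is TokenKind.EXACT:
                parts.append(next(iter(tok.residues)))
                i += 1
            else:
                parts.append("[" + "".join(sorted(tok.residues)) + "]")
                i += 1
        return "-".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A pattern match in an ungapped sequence; 1-based inclusive coords."""

    seq_id: str
    start: int
    end: int
    matched_subsequence: str


def parse_pattern(text: str) -> MotifPattern:
    """Parse dash-joined degenerate pattern text into a :class:`MotifPattern`.

    Repeat wildcards expand (``X2`` -> two wildcard positions). Raises
    :class:`PatternError` naming the offending token on unknown characters,
    empty classes or zero repeat counts.
    """
    if not text.strip():
        raise PatternError("empty pattern")
    tokens: list[MotifToken] = []
    for idx, raw in enumerate(text.strip().split("-"), start=1):
        tok = raw.strip()
        if not tok:
            raise PatternError(f"empty token at position {idx}")
        if tok.startswith("["):
            if not tok.endswith("]") or len(tok) < 3:
                raise PatternError(
                    f"malformed class {tok!r} at token {idx}"
                )
            body = tok[1:-1]
            bad = [c for c in body if c not in AA_LETTERS]
            if bad:
                raise PatternError(
                    f"invalid residue(s) {bad} in class at token {idx}"
                )
            tokens.append(residue_class(body))
        elif tok[0] == "X":
            if tok == "X":
                tokens.append(WILDCARD)
            else:
                if not tok[1:].isdigit():
                    raise PatternError(
                        f"malformed wildcard repeat {tok!r} at token {idx}"
                    )
                n = int(tok[1:])
                if n < 1:
                    raise PatternError(
                        f"zero repeat count in {tok!r} at token {idx}"
                    )
                tokens.extend([WILDCARD] * n)
        elif len(tok) == 1 and tok in AA_LETTERS:
            tokens.append(exact(tok))
        else:
            raise PatternError(f"unknown token {tok!r} at position {idx}")
    return MotifPattern(tokens=tokens, source_text=text.strip())


def scan_pattern(pattern: MotifPattern, sequence: str, seq_id: str = "") -> list[MotifHit]:
    """Report every match of ``pattern`` in a gap-free amino-acid sequence.

    All start offsets are tested, so overlapping matches are all reported.
    Coordinates are 1-based inclusive residue numbers.
    """
    if GAP in sequence:
        raise ValueError(
            "sequence contains gap characters; de-gap before scanning"
        )
    bad = sorted({c for c in sequence if c not in AA_LETTERS})
    if bad:
        raise ValueError(f"invalid amino-acid letters in sequence: {bad}")
    m = len(pattern.tokens)
    hits: list[MotifHit] = []
    for start in range(len(sequence) - m + 1):
        window = sequence[start : start + m]
        if all(tok.matches(aa) for tok, aa in zip(pattern.tokens, window)):
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=start + 1,
                    end=start + m,
                    matched_subsequence=window,
                )
            )
    return hits
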
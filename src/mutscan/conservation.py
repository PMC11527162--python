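"""Per-column conservation profiles and degenerate consensus-motif discovery.

A column is *invariant* when exactly one residue and zero gaps occur
across every sequence in the family — the criterion behind reports such
as "35 invariant residues across 155 family members". Consensus motifs
are maximal, information-dense runs of columns rendered as degenerate
patterns (exact residue / bracketed class / X wildcard).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import GAP, AlignedFamily
from .motifs import MotifPattern, MotifToken, TokenKind, WILDCARD, exact, residue_class


@dataclass
class ColumnProfile:
    column: int                      # 1-based
    residue_counts: dict[str, int]   # AA -> count (gaps excluded)
    gap_count: int
    n_sequences: int
    per_group_conserved: dict[str, bool]
    per_group_chars: dict[str, set[str]] = field(default_factory=dict)

    @property
    def gap_fraction(self) -> float:
        return self.gap_count / self.n_sequences

    @property
    def n_distinct(self) -> int:
        return len(self.residue_counts)

    @property
    def is_invariant(self) -> bool:
        return self.n_distinct == 1 and self.gap_count == 0


@dataclass
class ConservationProfile:
    columns: list[ColumnProfile]

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, column: int) -> ColumnProfile:
        """1-based column access."""
        return self.columns[column - 1]

    def invariant_columns(self) -> list[int]:
        return [c.column for c in self.columns if c.is_invariant]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.columns:
            top = sorted(c.residue_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            row = {
                "column": c.column,
                "top_residues": "".join(aa for aa, _ in top[:3]),
                "n_distinct": c.n_distinct,
                "gap_fraction": c.gap_fraction,
                "invariant": c.is_invariant,
            }
            for g, flag in c.per_group_conserved.items():
                row[f"conserved_{g}"] = flag
            rows.append(row)
        return pd.DataFrame(rows)


def compute_profile(family: AlignedFamily) -> ConservationProfile:
    """Column-wise residue composition, gap fraction and conservation flags.

    ``per_group_conserved[g]`` is True when group *g*'s sequences show a
    single residue and no gaps in that column.
    """
    if len(family) == 0:
        raise ValueError("empty family")
    groups = family.groups_present()
    by_group = {g: [r for r in family.records if r.group == g] for g in groups}
    columns: list[ColumnProfile] = []
    for j in range(family.n_columns):
        counts: Counter[str] = Counter()
        gaps = 0
        for r in family.records:
            ch = r.aligned_seq[j]
            if ch == GAP:
                gaps += 1
            else:
                counts[ch] += 1
        per_group: dict[str, bool] = {}
        per_group_chars: dict[str, set[str]] = {}
        for g, recs in by_group.items():
            col_chars = {r.aligned_seq[j] for r in recs}
            per_group[g] = len(col_chars) == 1 and GAP not in col_chars
            per_group_chars[g] = col_chars
        columns.append(
            ColumnProfile(
                column=j + 1,
                residue_counts=dict(counts),
                gap_count=gaps,
                n_sequences=len(family),
                per_group_conserved=per_group,
                per_group_chars=per_group_chars,
            )
        )
    return ConservationProfile(columns)


def conserved_within(
    profile: ConservationProfile, column: int, groups: set[str]
) -> bool:
    """True when the column shows one residue and no gaps jointly across the
    union of the given groups (the criterion behind "conserved in plant and
    fungal sequences"). Groups absent from the family contribute nothing."""
    col = profile[column]
    union: set[str] = set()
    for g in groups:
        union |= col.per_group_chars.get(g, set())
    return len(union) == 1 and GAP not in union


@dataclass(frozen=True)
class ConsensusMotif:
    """A conserved alignment region rendered as a degenerate pattern."""

    motif_id: str
    column_start: int   # 1-based inclusive alignment columns
    column_end: int
    derived_pattern: MotifPattern
    fraction_non_wildcard: float

    @property
    def n_columns(self) -> int:
        return self.column_end - self.column_start + 1


@dataclass
class MotifParams:
    """Thresholds for consensus-motif derivation.

    class_coverage: minimum fraction of non-gap sequences a token's
        residue set must cover (1.0 demands strict identity for exact).
    max_class_size: largest bracketed alternative set before a position
        degenerates to a wildcard.
    min_length: shortest reportable motif, in columns.
    min_informative_fraction: minimum non-wildcard density over the motif.
    max_gap_fraction: columns gappier than this cannot join a motif.
    """

    class_coverage: float = 0.98
    max_class_size: int = 4
    min_length: int = 8
    min_informative_fraction: float = 0.5
    max_gap_fraction: float = 0.05


def classify_column(col: ColumnProfile, params: MotifParams) -> MotifToken:
    """Label one column exact / class / wildcard by coverage of non-gap
    sequences, choosing the smallest covering residue set (count-descending,
    alphabetical tie-break)."""
    n_nongap = col.n_sequences - col.gap_count
    if n_nongap == 0:
        return WILDCARD
    if params.class_coverage >= 1.0 and col.n_distinct == 1:
        return exact(next(iter(col.residue_counts)))
    ranked = sorted(col.residue_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    covered = 0
    chosen: list[str] = []
    for aa, cnt in ranked:
        chosen.append(aa)
        covered += cnt
        if covered / n_nongap >= params.class_coverage:
            break
    else:
        return WILDCARD
    if len(chosen) == 1:
        return exact(chosen[0])
    if len(chosen) <= params.max_class_size:
        return residue_class("".join(chosen))
    return WILDCARD


def derive_motifs(
    profile: ConservationProfile, params: MotifParams | None = None
) -> list[ConsensusMotif]:
    """Find maximal conserved runs and render them as degenerate patterns.

    Eligible columns have gap fraction <= ``max_gap_fraction``. Within each
    eligible run, motifs are grown greedily left-to-right: start at a
    non-wildcard column, extend to the farthest non-wildcard end that keeps
    the interval's non-wildcard fraction >= ``min_informative_fraction``,
    and keep intervals of >= ``min_length`` columns. Results are
    non-overlapping, ordered, and trimmed to non-wildcard ends.
    """
    params = params or MotifParams()
    tokens = [classify_column(c, params) for c in profile.columns]
    n = len(tokens)
    eligible = [
        profile.columns[i].gap_fraction <= params.max_gap_fraction
        for i in range(n)
    ]
    informative = [t.kind is not TokenKind.WILDCARD for t in tokens]

    motifs: list[ConsensusMotif] = []
    i = 0
    while i < n:
        if not (eligible[i] and informative[i]):
            i += 1
            continue
        # grow: best end is the farthest informative column j >= i such that
        # all of [i, j] is eligible and density >= threshold
        best_end = i
        n_info = 0
        j = i
        while j < n and eligible[j]:
            if informative[j]:
                n_info += 1
                if n_info / (j - i + 1) >= params.min_informative_fraction:
                    best_end = j
            j += 1
        length = best_end - i + 1
        if length >= params.min_length:
            span = tokens[i : best_end + 1]
            frac = sum(
                1 for t in span if t.kind is not TokenKind.WILDCARD
            ) / len(span)
            pattern = MotifPattern(tokens=list(span))
            pattern.source_text = pattern.serialize()
            motifs.append(
                ConsensusMotif(
                    motif_id=f"M{len(motifs) + 1}",
                    column_start=i + 1,
                    column_end=best_end + 1,
                    derived_pattern=pattern,
                    fraction_non_wildcard=frac,
                )
            )
            i = best_end + 1
        else:
            i += 1
    return motifs


def motifs_to_frame(motifs: list[ConsensusMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": [m.motif_id for m in motifs],
            "column_start": [m.column_start for m in motifs],
            "column_end": [m.column_end for m in motifs],
            "pattern": [m.derived_pattern.serialize() for m in motifs],
            "fraction_non_wildcard": [m.fraction_non_wildcard for m in motifs],
        }
    )


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two closed integer intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0
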
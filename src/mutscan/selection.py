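"""Rule-based nomination of mutagenesis candidate residues.

The selection logic mirrors rational mutant design in transporter
structure-function studies: within conserved motifs, discard invariant
positions (mutating them likely abolishes function), positions conserved
across the plant and fungal clades, and highly variable positions
(unlikely to matter); among the survivors keep those where the target
protein differs from a functionally characterized reference ortholog,
and propose swapping in the reference's residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import GAP, AlignedFamily, column_to_residue
from .conservation import ConsensusMotif, ConservationProfile, conserved_within

#: groups whose joint conservation disqualifies a column by default
DEFAULT_CONSERVED_GROUPS = frozenset({"plant", "ascomycete", "basidiomycete"})


@dataclass(frozen=True)
class ResiduePairDiff:
    """A target/reference residue difference at one alignment column."""

    column: int
    pos_a: int
    res_a: str
    pos_b: int
    res_b: str


@dataclass
class RuleVerdict:
    rule: str
    passed: bool
    detail: str = ""


@dataclass
class ColumnAudit:
    """Full per-column record of every exclusion rule's outcome."""

    column: int
    motif_id: str
    verdicts: list[RuleVerdict] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def reasons_discarded(self) -> list[str]:
        return [v.rule for v in self.verdicts if not v.passed]


@dataclass
class CandidateResidue:
    position: int          # target sequence's own 1-based numbering
    wildtype_res: str
    proposed_res: str      # residue of the reference ortholog
    motif_id: str | None
    exclusion_trail: ColumnAudit

    @property
    def mutation_name(self) -> str:
        return f"{self.wildtype_res}{self.position}{self.proposed_res}"


def pairwise_differences(
    family: AlignedFamily, id_target: str, id_reference: str
) -> list[ResiduePairDiff]:
    """All alignment columns where target and reference are both ungapped
    and carry different residues, with each sequence's own residue numbers."""
    rec_t = family[id_target]
    rec_r = family[id_reference]
    diffs: list[ResiduePairDiff] = []
    pos_t = pos_r = 0
    for col in range(1, family.n_columns + 1):
        ch_t = rec_t.aligned_seq[col - 1]
        ch_r = rec_r.aligned_seq[col - 1]
        if ch_t != GAP:
            pos_t += 1
        if ch_r != GAP:
            pos_r += 1
        if ch_t != GAP and ch_r != GAP and ch_t != ch_r:
            diffs.append(
                ResiduePairDiff(
                    column=col, pos_a=pos_t, res_a=ch_t, pos_b=pos_r, res_b=ch_r
                )
            )
    return diffs


@dataclass
class SelectionParams:
    conserved_groups: frozenset[str] = DEFAULT_CONSERVED_GROUPS
    max_distinct: int = 4               # columns more variable than this are discarded
    restrict_to_motifs: list[str] | None = None  # None = all supplied motifs


def select_candidates(
    family: AlignedFamily,
    profile: ConservationProfile,
    motifs: list[ConsensusMotif],
    diffs: list[ResiduePairDiff],
    id_target: str,
    params: SelectionParams | None = None,
) -> tuple[list[CandidateResidue], list[ColumnAudit]]:
    """Apply the exclusion rules over every motif column and return the
    surviving candidates plus the complete audit log.

    A column is kept iff it lies in a selected motif AND is not invariant
    AND is not jointly conserved within ``conserved_groups`` AND has
    ``n_distinct <= max_distinct`` AND appears in ``diffs``. Every rule is
    evaluated for every motif column even after a first failure, so the
    audit log is complete.
    """
    params = params or SelectionParams()
    if params.restrict_to_motifs is not None:
        known = {m.motif_id for m in motifs}
        unknown = set(params.restrict_to_motifs) - known
        if unknown:
            raise ValueError(f"unknown motif id(s): {sorted(unknown)}")
        selected = [m for m in motifs if m.motif_id in params.restrict_to_motifs]
    else:
        selected = list(motifs)

    diff_by_column = {d.column: d for d in diffs}
    audits: list[ColumnAudit] = []
    candidates: list[CandidateResidue] = []
    for motif in selected:
        for col in range(motif.column_start, motif.column_end + 1):
            cp = profile[col]
            audit = ColumnAudit(column=col, motif_id=motif.motif_id)
            audit.verdicts.append(
                RuleVerdict(
                    "not_invariant",
                    not cp.is_invariant,
                    "invariant column" if cp.is_invariant else "",
                )
            )
            jointly = conserved_within(profile, col, set(params.conserved_groups))
            audit.verdicts.append(
                RuleVerdict(
                    "not_conserved_in_groups",
                    not jointly,
                    f"conserved within {sorted(params.conserved_groups)}"
                    if jointly
                    else "",
                )
            )
            too_variable = cp.n_distinct > params.max_distinct
            audit.verdicts.append(
                RuleVerdict(
                    "not_too_variable",
                    not too_variable,
                    f"n_distinct={cp.n_distinct} > {params.max_distinct}"
                    if too_variable
                    else "",
                )
            )
            diff = diff_by_column.get(col)
            audit.verdicts.append(
                RuleVerdict(
                    "differs_target_vs_reference",
                    diff is not None,
                    "" if diff else "no target/reference difference",
                )
            )
            audits.append(audit)
            if audit.kept:
                assert diff is not None
                pos = column_to_residue(family, id_target, col)
                assert pos is not None  # diff guarantees no gap in target
                candidates.append(
                    CandidateResidue(
                        position=pos,
                        wildtype_res=diff.res_a,
                        proposed_res=diff.res_b,
                        motif_id=motif.motif_id,
                        exclusion_trail=audit,
                    )
                )
    return candidates, audits


# ---------------------------------------------------------------------------
# topology annotation


@dataclass(frozen=True)
class TopologySegment:
    label: str     # e.g. "TMS 3", "H3", "TMS11-12 loop"
    start: int     # 1-based inclusive residue numbers
    end: int
    domain: str = "other"   # core / gate / other


@dataclass
class TopologyAnnotation:
    """Ordered, non-overlapping structural segments of the target protein."""

    segments: list[TopologySegment]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping topology segments {a.label!r} and {b.label!r}"
                )

    def locate(self, position: int) -> str:
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.label
        return "unassigned"


def read_topology(path) -> TopologyAnnotation:
    """Read topology TSV: label<TAB>start<TAB>end<TAB>domain."""
    df = pd.read_csv(path, sep="\t", comment="#")
    segments = [
        TopologySegment(
            label=str(r["label"]),
            start=int(r["start"]),
            end=int(r["end"]),
            domain=str(r.get("domain", "other")),
        )
        for _, r in df.iterrows()
    ]
    return TopologyAnnotation(segments)


def annotate_topology(
    candidates: list[CandidateResidue], topo: TopologyAnnotation
) -> list[tuple[CandidateResidue, str]]:
    """Label each candidate with its containing structural segment
    ("unassigned" if outside every segment)."""
    return [(c, topo.locate(c.position)) for c in candidates]


def candidates_to_frame(
    annotated: list[tuple[CandidateResidue, str]]
) -> pd.DataFrame:
    import json

    rows = []
    for cand, loc in annotated:
        rows.append(
            {
                "mutation": cand.mutation_name,
                "position": cand.position,
                "wildtype": cand.wildtype_res,
                "proposed": cand.proposed_res,
                "motif": cand.motif_id or "",
                "location": loc,
                "trail": json.dumps(
                    [
                        {"rule": v.rule, "passed": v.passed}
                        for v in cand.exclusion_trail.verdicts
                    ]
                ),
            }
        )
    return pd.DataFrame(rows)
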
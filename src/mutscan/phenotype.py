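"""Growth-phenotype grouping and functional categorization of transporter
mutants.

Strains are scored on a four-level ordinal growth scale per medium
('-' < '+' < '++' < '+++', relative to the wild type) and carry a
quantitative uptake rate V% (percent of wild type). The phenotype group
is the pair of scores on the diagnostic media — purine as sole nitrogen
source vs the toxic analogue 8-azaguanine — and the functional category
(loss / decreased / equivalent / increased) is assigned from V%.
Growth and uptake report the same underlying transport activity, so the
two classifications should co-vary; discordant strains are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

ORDINAL_SCORES = ("-", "+", "++", "+++")

#: the expected growth group for each functional category (purine/8-azaguanine)
CONCORDANT_GROUP = {
    "loss": "-/+++",
    "decreased": "-/++",
    "equivalent": "+/+",
    "increased": "++/-",
}

CATEGORIES = ("loss", "decreased", "equivalent", "increased")


@dataclass(frozen=True)
class BelowDetection:
    """A V% below the assay's detection floor, printed as e.g. '<2'.

    The numeric floor is kept only for display; classification treats the
    value as loss-of-function without inventing a number.
    """

    floor: float

    def __str__(self) -> str:
        return f"<{self.floor:g}"


@dataclass
class StrainPhenotype:
    strain: str
    growth: dict[str, str]                 # medium -> ordinal score
    v_percent: float | BelowDetection
    v_sd: float = 0.0
    is_control: bool = False

    def __post_init__(self) -> None:
        for medium, score in self.growth.items():
            if score not in ORDINAL_SCORES:
                raise ValueError(
                    f"invalid growth score {score!r} for {self.strain} "
                    f"on {medium}"
                )
        if isinstance(self.v_percent, (int, float)) and self.v_percent < 0:
            raise ValueError("v_percent must be >= 0")


def score_growth_group(purine_score: str, azaguanine_score: str) -> str:
    """Phenotype-group label '<purine>/<8-azaguanine>' (e.g. '-/+++')."""
    for score in (purine_score, azaguanine_score):
        if score not in ORDINAL_SCORES:
            raise ValueError(f"invalid ordinal growth score {score!r}")
    return f"{purine_score}/{azaguanine_score}"


@dataclass
class FunctionThresholds:
    """V% cut-points for the functional categories.

    loss: below ``floor`` (or below detection); decreased: [floor, low);
    equivalent: [low, high]; increased: above ``high``. Defaults put the
    observed mutant clusters (≈20-25, 88-103, 140-155, <2) well inside
    their categories.
    """

    floor: float = 5.0
    low: float = 60.0
    high: float = 125.0


def classify_function(
    v_percent: float | BelowDetection,
    thresholds: FunctionThresholds | None = None,
) -> str:
    """Total, monotone step classification of V% into
    loss / decreased / equivalent / increased."""
    t = thresholds or FunctionThresholds()
    if isinstance(v_percent, BelowDetection):
        return "loss"
    if v_percent < 0:
        raise ValueError("v_percent must be >= 0")
    if v_percent < t.floor:
        return "loss"
    if v_percent < t.low:
        return "decreased"
    if v_percent <= t.high:
        return "equivalent"
    return "increased"


@dataclass
class PhenotypeSummary:
    table: pd.DataFrame
    category_counts: dict[str, int]
    growth_groups: list[str]
    discordant: list[str]


def build_summary(
    strains: list[StrainPhenotype],
    purine_medium: str = "hypoxanthine",
    azaguanine_medium: str = "8-azaguanine",
    thresholds: FunctionThresholds | None = None,
) -> PhenotypeSummary:
    """Per-strain group + category + concordance, with category counts over
    the non-control strains.

    Concordance: the growth group must match the category's expected
    purine/8-azaguanine pair (loss↔-/+++, decreased↔-/++, equivalent↔+/+,
    increased↔++/-). Media beyond the two diagnostic ones are carried in
    the data model but do not enter the group label.
    """
    if not strains:
        raise ValueError("no strains supplied")
    rows = []
    discordant: list[str] = []
    for s in strains:
        group = score_growth_group(
            s.growth[purine_medium], s.growth[azaguanine_medium]
        )
        category = classify_function(s.v_percent, thresholds)
        concordant = CONCORDANT_GROUP[category] == group
        if not concordant and not s.is_control:
            discordant.append(s.strain)
        rows.append(
            {
                "strain": s.strain,
                "growth_group": group,
                "v_percent": str(s.v_percent)
                if isinstance(s.v_percent, BelowDetection)
                else s.v_percent,
                "v_sd": s.v_sd,
                "category": category,
                "concordant": concordant,
                "is_control": s.is_control,
            }
        )
    table = pd.DataFrame(rows)
    mutants = table[~table["is_control"]]
    counts = {c: int((mutants["category"] == c).sum()) for c in CATEGORIES}
    groups = sorted(mutants["growth_group"].unique())
    return PhenotypeSummary(
        table=table,
        category_counts=counts,
        growth_groups=groups,
        discordant=discordant,
    )


def read_growth_scores(path) -> dict[str, dict[str, str]]:
    """Read long-format TSV (strain, medium, score) into nested dicts."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples():
        out.setdefault(row.strain, {})[row.medium] = row.score
    return out
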
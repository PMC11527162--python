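"""Synthetic data generators and transcribed study fixtures.

Two simulators provide inputs with the statistical structure the
analysis assumes, so every pipeline stage is testable without external
downloads:

* :func:`generate_family` builds an aligned protein family with planted
  invariant columns, planted degenerate-motif blocks, group-specific
  divergence and gaps — emulating a 155-member transporter family
  (11 functionally characterized + 144 hypothetical sequences across
  prokaryotes, plants, ascomycetes and basidiomycetes).
* :func:`generate_uptake` draws radiolabelled-uptake observations from a
  single-site competitive-inhibition rate model with multiplicative
  log-normal noise, triplicates in two experiments, plus a
  transporter-null background strain.

Alongside the simulators, this module ships verbatim transcriptions of
the study's printed summary table (growth scores and V% ± SD per
strain), the four published motif patterns, and the four growth-group
labels, for use as fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedFamily, AlignedRecord
from .kinetics import rate_to_counts
from .phenotype import BelowDetection, StrainPhenotype
from .selection import TopologyAnnotation, TopologySegment

AA = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# published motif patterns (degenerate notation, X = any residue)

PUBLISHED_MOTIFS = {
    "motif1": "E-X2-[AG]-[GA]-X-[ATV]-T-[FW]-X-[ATS]-M-X-Y-[IS]-[ILV]-X-V-N",
    "motif2": "P-X-[AGS]-X-[AG]-[PSC]-[GA]-[MLI]-[GS]-X-[NT]-A-[YF]-X-[AT]-[YF]-X2-V",
    "motif3": "G-I-G-X-[FY]-[LI]-X3-[GA]",
    "motif4": "[FY]-[IV]-E-S-X-[AST]-G-X2-[EAV]-G-G-[RKA]-T-G",
}

# ---------------------------------------------------------------------------
# aligned-family generator


@dataclass
class PlantedMotif:
    """A planted motif block: starting column (1-based) and one residue
    constraint set per position (a singleton set plants an exact/invariant
    position, ``None`` plants an unconstrained wildcard position)."""

    motif_id: str
    column_start: int
    position_sets: list[str | None]

    @property
    def column_end(self) -> int:
        return self.column_start + len(self.position_sets) - 1


@dataclass
class FamilyConfig:
    group_sizes: dict[str, int]
    n_columns: int
    planted_invariant_columns: list[int]
    planted_motifs: list[PlantedMotif]
    per_group_divergence: dict[str, float] | float = 0.5
    gap_rate: float = 0.02
    seed: int = 0

    def divergence_for(self, group: str) -> float:
        if isinstance(self.per_group_divergence, dict):
            return self.per_group_divergence.get(group, 0.5)
        return self.per_group_divergence

    def validate(self) -> None:
        occupied: set[int] = set()
        spans = [(c, c) for c in self.planted_invariant_columns] + [
            (m.column_start, m.column_end) for m in self.planted_motifs
        ]
        for lo, hi in spans:
            if lo < 1 or hi > self.n_columns:
                raise ValueError(
                    f"planted feature {lo}-{hi} outside 1..{self.n_columns}"
                )
            cols = set(range(lo, hi + 1))
            if cols & occupied:
                raise ValueError("planted features overlap")
            occupied |= cols
        for p, v in (("gap_rate", self.gap_rate),):
            if not 0 <= v <= 1:
                raise ValueError(f"{p} must be in [0,1]")


@dataclass
class FamilyGroundTruth:
    invariant_columns: list[int]      # includes singleton motif positions
    motif_intervals: dict[str, tuple[int, int]]
    consensus: dict[int, str]         # planted column -> residue/set drawn from


def generate_family(cfg: FamilyConfig) -> tuple[AlignedFamily, FamilyGroundTruth]:
    """Sample an aligned family with the planted conservation structure.

    Guarantees (by construction / resampling):

    * planted invariant columns hold one residue, zero gaps, everywhere;
    * singleton positions of planted motifs behave the same and are
      reported in the ground-truth invariant set;
    * multi-residue motif positions draw only from their constraint set
      and are resampled until >= 2 distinct residues appear;
    * every other column is resampled until >= 2 distinct residues appear
      among its non-gap characters, so invariant-column recovery is exact
      rather than probabilistic.

    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups: list[str] = []
    ids: list[str] = []
    for g, n in cfg.group_sizes.items():
        for i in range(n):
            groups.append(g)
            ids.append(f"{g}_{i + 1:03d}")
    n_seq = len(ids)
    if n_seq < 2:
        raise ValueError("need at least two sequences")

    kind: dict[int, tuple[str, str | None]] = {}   # column -> (kind, set)
    for c in cfg.planted_invariant_columns:
        kind[c] = ("invariant", None)
    for m in cfg.planted_motifs:
        for off, pset in enumerate(m.position_sets):
            col = m.column_start + off
            if pset is None:
                kind[col] = ("motif_wild", None)
            elif len(pset) == 1:
                kind[col] = ("motif_exact", pset)
            else:
                kind[col] = ("motif_class", pset)

    aa = np.array(list(AA))
    columns = np.empty((n_seq, cfg.n_columns), dtype="<U1")
    consensus: dict[int, str] = {}
    truth_invariants: list[int] = []
    div = np.array([cfg.divergence_for(g) for g in groups])

    for col in range(1, cfg.n_columns + 1):
        what, pset = kind.get(col, ("normal", None))
        if what == "invariant" or what == "motif_exact":
            res = pset if pset else str(rng.choice(aa))
            columns[:, col - 1] = res
            consensus[col] = res
            truth_invariants.append(col)
        elif what == "motif_class":
            chars = np.array(list(pset))
            while True:
                draw = rng.choice(chars, size=n_seq)
                if len(set(draw)) >= 2:
                    break
            columns[:, col - 1] = draw
            consensus[col] = pset
        elif what == "motif_wild":
            while True:
                draw = rng.choice(aa, size=n_seq)
                if len(set(draw)) >= 2:
                    break
            columns[:, col - 1] = draw
        else:
            while True:
                base = str(rng.choice(aa))
                draw = np.full(n_seq, base, dtype="<U1")
                mutate = rng.random(n_seq) < div
                n_mut = int(mutate.sum())
                if n_mut:
                    draw[mutate] = rng.choice(aa, size=n_mut)
                if cfg.gap_rate > 0:
                    gaps = rng.random(n_seq) < cfg.gap_rate
                    draw[gaps] = "-"
                nongap = draw[draw != "-"]
                if len(nongap) >= 1 and len(set(nongap)) >= 2:
                    break
            columns[:, col - 1] = draw

    records = [
        AlignedRecord(id=i, group=g, aligned_seq="".join(columns[k]))
        for k, (i, g) in enumerate(zip(ids, groups))
    ]
    truth = FamilyGroundTruth(
        invariant_columns=sorted(truth_invariants),
        motif_intervals={
            m.motif_id: (m.column_start, m.column_end)
            for m in cfg.planted_motifs
        },
        consensus=consensus,
    )
    return AlignedFamily(records), truth


def _pattern_to_position_sets(pattern_text: str) -> list[str | None]:
    from .motifs import TokenKind, parse_pattern

    sets: list[str | None] = []
    for tok in parse_pattern(pattern_text).tokens:
        if tok.kind is TokenKind.WILDCARD:
            sets.append(None)
        else:
            sets.append("".join(sorted(tok.residues)))
    return sets


def paper_family_config(seed: int = 0) -> FamilyConfig:
    """Family configuration mirroring the study's reported composition:
    155 sequences (11 characterized + 29 prokaryote, 35 plant,
    54 ascomycete, 26 basidiomycete hypothetical), four planted motif
    blocks shaped like the published patterns, and 35 invariant columns
    in total (19 of which are the singleton motif positions — invariant
    residues concentrate inside conserved motifs, as in the real family).
    """
    motif_specs = [
        ("motif1", 60), ("motif2", 140), ("motif3", 230), ("motif4", 320),
    ]
    motifs = [
        PlantedMotif(
            motif_id=mid,
            column_start=start,
            position_sets=_pattern_to_position_sets(PUBLISHED_MOTIFS[mid]),
        )
        for mid, start in motif_specs
    ]
    n_singletons = sum(
        1 for m in motifs for s in m.position_sets if s is not None and len(s) == 1
    )
    scattered = [
        5, 10, 15, 20, 25, 30, 35,
        105, 110, 115,
        185, 190, 195, 200, 205,
        265, 270, 275, 280, 285, 290, 295,
        360, 365, 370, 375, 380, 385, 390, 395, 400,
    ][: 35 - n_singletons]
    return FamilyConfig(
        group_sizes={
            "known": 11, "prokaryote": 29, "plant": 35,
            "ascomycete": 54, "basidiomycete": 26,
        },
        n_columns=420,
        planted_invariant_columns=scattered,
        planted_motifs=motifs,
        per_group_divergence={
            "known": 0.35, "prokaryote": 0.6, "plant": 0.4,
            "ascomycete": 0.4, "basidiomycete": 0.4,
        },
        gap_rate=0.02,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# uptake-assay generator


@dataclass
class UptakeConfig:
    """Single-site competitive-inhibition assay simulator settings.

    ``strains`` maps strain name to relative transporter activity
    (1.0 = wild type; 0 for dead mutants). The background strain carries
    no transporter; its non-specific uptake (``background_fraction`` of
    the wild-type rate) is added to every strain, exercising background
    subtraction nontrivially. ``competitors`` maps competitor name to its
    true Ki in µM (None = non-substrate, no inhibition); the homologous
    (self) competitor has Ki = Km. Defaults follow the assay design the
    analysis assumes: 0.2 µM labelled substrate, competitor grid
    0.1 µM–1 mM, triplicates in two experiments, 10% CV multiplicative
    noise, counts integrated over 1 min with 10^8 conidia.
    """

    strains: dict[str, float]
    background_strain: str = "ΔZAC"
    background_fraction: float = 0.01
    km_uM: float = 5.0
    labelled_conc_uM: float = 0.2
    competitors: dict[str, float | None] = field(
        default_factory=lambda: {"hypoxanthine": 5.0}
    )
    competitor_grid_uM: tuple[float, ...] = (
        0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0
    )
    replicates: int = 3
    experiments: int = 2
    noise_cv: float = 0.1
    time_min: float = 1.0
    spores: float = 1e8
    vmax_mol: float = 1e-11        # wild-type Vmax, mol/min/10^8 conidia
    hill_true: float = -1.0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1 or self.experiments < 1:
            raise ValueError("replicates and experiments must be >= 1")
        if any(r < 0 for r in self.strains.values()):
            raise ValueError("relative rates must be >= 0")
        if any(c <= 0 for c in self.competitor_grid_uM):
            raise ValueError("competitor grid must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class UptakeGroundTruth:
    v0: dict[str, float]               # uninhibited transporter rate, mol/min/10^8
    background_rate: float
    ic50_uM: dict[str, float | None]   # competitor -> true IC50
    km_uM: float
    labelled_conc_uM: float


def generate_uptake(cfg: UptakeConfig):
    """Draw an uptake observation table from the competitive-inhibition model.

    Expected transporter rate per strain: v0 = relative × Vmax × S/(Km+S).
    Under competitor concentration I: v = v0 / (1 + I/IC50) with
    IC50 = Ki(1 + S/Km) — so homologous competition has IC50 = Km + S.
    Non-specific background is added to every observation, counts are the
    exact inverse of the cpm→rate conversion, and multiplicative
    log-normal noise (mean 1, given CV) is applied to the counts.
    Returns ``(DataFrame, UptakeGroundTruth)``; columns follow the uptake
    TSV schema (strain, labelled_conc_uM, competitor, competitor_conc_uM,
    cpm, time_min, spores, replicate, experiment).
    """
    import pandas as pd

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    S, Km = cfg.labelled_conc_uM, cfg.km_uM
    occupancy = S / (Km + S)
    v0 = {s: rel * cfg.vmax_mol * occupancy for s, rel in cfg.strains.items()}
    background = cfg.background_fraction * cfg.vmax_mol * occupancy
    ic50 = {
        comp: (None if ki is None else ki * (1.0 + S / Km))
        for comp, ki in cfg.competitors.items()
    }

    sigma = float(np.sqrt(np.log(1.0 + cfg.noise_cv**2)))

    def noisy(x: float) -> float:
        if cfg.noise_cv == 0:
            return x
        return x * float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    all_strains = dict(cfg.strains)
    all_strains.setdefault(cfg.background_strain, 0.0)
    conditions: list[tuple[str | None, float]] = [(None, 0.0)]
    for comp in cfg.competitors:
        conditions += [(comp, c) for c in cfg.competitor_grid_uM]

    rows = []
    for strain in all_strains:
        v_strain = v0.get(strain, 0.0)
        for comp, conc in conditions:
            if comp is None or ic50[comp] is None:
                v = v_strain
            else:
                v = v_strain / (1.0 + conc / ic50[comp])
            total = v + background
            cpm_exact = rate_to_counts(
                total, cfg.time_min, cfg.spores
            )
            for e in range(1, cfg.experiments + 1):
                for r in range(1, cfg.replicates + 1):
                    rows.append(
                        {
                            "strain": strain,
                            "labelled_conc_uM": S,
                            "competitor": comp if comp else "none",
                            "competitor_conc_uM": conc,
                            "cpm": noisy(cpm_exact),
                            "time_min": cfg.time_min,
                            "spores": cfg.spores,
                            "replicate": f"r{r}",
                            "experiment": f"e{e}",
                        }
                    )
    truth = UptakeGroundTruth(
        v0=v0, background_rate=background, ic50_uM=ic50,
        km_uM=Km, labelled_conc_uM=S,
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# transcribed study fixtures


def table1_fixture() -> list[StrainPhenotype]:
    """The study's functional summary table, transcribed: 13 mutants plus
    the three control strains (wild type, reference ortholog, null)."""
    below = BelowDetection(2.0)

    def strain(name, hx, azg, v, sd=0.0, control=False):
        return StrainPhenotype(
            strain=name,
            growth={"hypoxanthine": hx, "8-azaguanine": azg},
            v_percent=v,
            v_sd=sd,
            is_control=control,
        )

    return [
        strain("Y54G", "-", "+++", below),
        strain("V58A", "-", "+++", below),
        strain("A128F", "-", "+++", below),
        strain("Y129D", "-", "+++", below),
        strain("A148V", "-", "+++", below),
        strain("T429P", "-", "+++", below),
        strain("L124M", "-", "++", 23.0, 3.0),
        strain("S133T", "-", "++", 21.0, 2.0),
        strain("T131A", "+", "+", 103.0, 7.0),
        strain("I388V", "+", "+", 96.0, 14.0),
        strain("A391G", "+", "+", 88.0, 8.0),
        strain("T392A", "++", "-", 142.0, 14.0),
        strain("A418V", "++", "-", 155.0, 23.0),
        strain("PhZwt", "+", "+", 100.0, 17.0, control=True),
        strain("AzgA", "++", "-", 155.0, 23.0, control=True),
        strain("ΔZAC", "-", "+++", below, control=True),
    ]


def table1_rate_profile() -> dict[str, float]:
    """Relative uptake rates (wild type = 1.0) read off the summary table's
    V% column, for driving the uptake simulator. Below-detection mutants
    get 0 (no transporter activity)."""
    return {
        "PhZwt": 1.00, "AzgA": 1.55,
        "Y54G": 0.0, "V58A": 0.0, "A128F": 0.0, "Y129D": 0.0,
        "A148V": 0.0, "T429P": 0.0,
        "L124M": 0.23, "S133T": 0.21,
        "T131A": 1.03, "I388V": 0.96, "A391G": 0.88,
        "T392A": 1.42, "A418V": 1.55,
    }


FIG3_GROUPS = ("-/+++", "-/++", "+/+", "++/-")

#: strain -> growth group, as reported for the four phenotypic groups
FIG3_GROUP_MEMBERS = {
    "Y54G": "-/+++", "V58A": "-/+++", "A128F": "-/+++",
    "Y129D": "-/+++", "A148V": "-/+++", "T429P": "-/+++",
    "L124M": "-/++", "S133T": "-/++",
    "T131A": "+/+", "I388V": "+/+", "A391G": "+/+",
    "T392A": "++/-", "A418V": "++/-",
}


def synthetic_topology() -> TopologyAnnotation:
    """Synthetic topology segment ranges for the target transporter.

    The study reports only the segment *label* per mutated residue
    (e.g. TMS 1, TMS 3, H3), not segment boundaries; these ranges are
    invented so that every analysed residue falls in its reported
    segment. Use for demonstrations and tests, not as structural truth.
    """
    return TopologyAnnotation(
        [
            TopologySegment("TMS 1", 45, 70, "core"),
            TopologySegment("TMS 3", 118, 140, "core"),
            TopologySegment("TMS 4", 144, 166, "core"),
            TopologySegment("TMS 10", 380, 405, "core"),
            TopologySegment("H3", 410, 424, "other"),
            TopologySegment("TMS11-12 loop", 425, 445, "other"),
        ]
    )
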
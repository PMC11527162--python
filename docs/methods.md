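# Methods

This note documents the models behind each mutscan module, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the underlying
procedure is usually left unstated.

## Conservation profiling

A column of the aligned family is **invariant** when exactly one residue
and zero gaps occur across all sequences. The strict no-gap requirement
is a deliberate choice: a column that any family member bridges with a
gap cannot support a claim of absolute conservation. Per-group
conservation uses the same rule within one taxonomic group; "conserved
in plant and fungal sequences" is evaluated *jointly* — one residue, no
gaps, across the union of the plant, ascomycete and basidiomycete
sequences — because the selection rules treat plant-and-fungal
conservation as a single criterion, and per-group flags alone would
admit a column fixed at different residues in different clades.

## Motif derivation

Each column is labelled by the smallest residue set (count-descending,
alphabetical tie-break) covering at least a fraction `class_coverage`
of its non-gap characters: a singleton gives an *exact* token, a set of
size ≤ `max_class_size` a bracketed *class*, anything larger a
wildcard. Motifs are maximal runs found greedily left to right inside
gap-eligible stretches (`gap_fraction ≤ max_gap_fraction`): a run
starts at a non-wildcard column and extends to the farthest non-wildcard
column that keeps the interval's non-wildcard density ≥
`min_informative_fraction`; runs shorter than `min_length` are
dropped. Intervals are therefore non-overlapping, trimmed to informative
ends, and never include a gappy column.

Defaults: `class_coverage` 0.98, `max_class_size` 4, `min_length` 8
columns, `min_informative_fraction` 0.5, `max_gap_fraction` 0.05.
The published motif strings give only the outputs of such an analysis,
never the thresholds; these defaults are this package's documented
choice, set so that blocks with the published motifs' density
(10–19 columns, 60–75% informative positions) are recovered as single
intervals while isolated conserved columns are not promoted to motifs.

## Candidate selection

Within the selected motifs, a column survives iff it is (i) not
invariant, (ii) not jointly conserved in the plant + fungal groups,
(iii) not hypervariable (`n_distinct ≤ 4` non-gap residues by default —
the variability cut-off is configurable because no numeric rule is
standard), and (iv) a position where target and reference orthologs are
both ungapped and differ. Every rule is evaluated for every motif
column, even after an earlier rule has failed, so the audit trail is a
complete per-column log rather than a short-circuit record. Kept
columns become proposed substitutions (reference residue into target,
named `L124M`-style in the target's own ungapped numbering). Selection
is monotone in the variability cut-off: loosening it can only add
candidates. A whole-alignment mode (`restrict_to_motifs=None` over a
synthetic all-column motif) supports candidates outside motifs.

Topology annotation maps candidate positions into user-supplied
non-overlapping segments (TMS helices, internal helices, loops). The
packaged segment table is synthetic: only segment *labels* per analysed
residue are public for the modelled transporter, so the packaged ranges
are invented to be consistent with those labels and are for
demonstration only.

## Uptake kinetics

Counts/min convert to rates as

```
rate = (cpm / efficiency) / (SA × 2.22×10¹² dpm/Ci) mmol
       → mol, per min, per 10⁸ conidia
```

with SA = 19.5 Ci/mmol (tritiated hypoxanthine) by default. Counting
efficiency defaults to 1.0 (cpm treated as dpm): absolute rates are
therefore conventional, but V% and all fitted parameters are invariant
to the efficiency because it rescales every observation equally.

Background subtraction matches each observation to the mean of the
transporter-null strain under the *same condition* (tracer
concentration, competitor, competitor concentration) and errors loudly
when a matched background is missing. Negative corrected rates are kept
and flagged, not clamped, so downstream SDs propagate honestly.

V% is 100 × mean(strain)/mean(reference); the reference is exactly 100
and SDs scale by the same factor (simple scaling, not error-in-ratio
propagation — consistent with how such panels are conventionally
reported, e.g. a wild type of 100 ± 17).

### Dose-response model

Homologous competition series are fitted with the four-parameter
variable-slope logistic on log₁₀ concentration (top, bottom ≥ 0,
log₁₀ IC₅₀, Hill slope). The sign convention makes descending
inhibition curves fit with slope ≈ −1, the single-site expectation.
Numerical choices:

- zero-competitor observations cannot sit on a log axis; they enter the
  objective as direct constraints on the `top` asymptote, which is the
  quantity they measure;
- residuals are divided by the predicted value (floored at 0.1% of the
  data scale), matching the proportional error of scintillation
  counting; plain least squares is available via `weighting="absolute"`;
- the fit runs on data rescaled by its own maximum, so mol-scale
  (~10⁻¹²) and percent-scale inputs behave identically;
- initialization: top = baseline mean, bottom = mean at the highest
  competitor level, log₁₀ IC₅₀ = grid midpoint, slope = −1; bounds keep
  log₁₀ IC₅₀ within 3 decades of the measured grid and |slope| ≤ 5;
- flat series (top ≈ bottom within 10⁻⁹ of the data scale) return
  `converged=False` and carry no Ki.

On exact model data the fit recovers all four parameters to ≤ 10⁻⁴
relative error; at 10% CV with six observations per level, IC₅₀ lands
within ±15% of truth in ≥ 90% of seeded simulations and the Hill slope
within ±0.15 of −1 (both properties are tested).

Cheng–Prusoff, `Ki = IC₅₀/(1 + [S]/Km)`, is applied when Km is known;
when it is not, the tracer regime [S] ≤ Km/10 bounds the correction to
1/11 relative, so Ki = IC₅₀ is returned with an approximation flag.
The printed-equation ambiguity (`IC50 / 1 + [S]/Km`) is resolved as the
standard Cheng–Prusoff denominator.

### Competition profiles and statistics

Percent-remaining is computed against each strain's *own* uninhibited
baseline, so strains of different absolute activity are comparable;
self-competition with the unlabelled substrate is the maximum-inhibition
control (≥ 95% at the assay geometry: 0.2 µM tracer, 1 mM competitor,
Km 10–50× above the tracer).

Strain comparisons run Shapiro–Wilk on the one-way model residuals:
p < 0.05 selects Kruskal–Wallis with Dunn's mean-rank z tests
(tie-corrected; Bonferroni-adjusted p gates the letters, Holm is
reported alongside, since both corrections are in common use);
otherwise one-way ANOVA with Tukey HSD. Letters come from the
insert-and-absorb algorithm with strains processed in descending-mean
order, which guarantees that significantly different pairs share no
letter and non-significant pairs share at least one, deterministically.
Dunn's test is implemented in-package (mean-rank z statistics with the
standard tie correction) with adjustment via statsmodels.

## Phenotype classification

Growth is a four-level ordinal scale per medium ('-' < '+' < '++' <
'+++' relative to wild type). The phenotype group is the score pair on
the two diagnostic media, purine/8-azaguanine (e.g. `-/+++`: no growth
on purine, full resistance to the toxic analogue — a dead transporter).
The functional category is a step function of V%: loss < 5, decreased
5–60, equivalent 60–125, increased > 125 (boundaries closed as listed).
These cut-points are this package's choice — the underlying study
separates categories by significance letters, not thresholds — placed
so the observed V% clusters (< 2, ≈ 20, 88–103, 142–155) sit well inside
their categories; a letters-based mode via `compare_strains` is the
statistically faithful alternative when replicates are available.
Below-detection values are carried as a `<floor` marker, never as a
number, because any numeric stand-in would be arbitrary. Category and
growth group must co-vary (loss↔`-/+++`, decreased↔`-/++`,
equivalent↔`+/+`, increased↔`++/-`); strains violating this are
reported as discordant rather than silently reassigned.

## Synthetic data

**Family generator.** Sequences are drawn per column: planted invariant
columns get one residue everywhere with no gaps; planted motif columns
draw uniformly from their per-position constraint sets (singleton sets
behave as invariant and are reported in the ground-truth invariant
set); all other columns start from a random consensus residue, mutate
each sequence with a per-group substitution probability, receive gaps
at `gap_rate`, and are **resampled until at least two distinct residues
appear** — which makes invariant-column recovery an exact check, not a
probabilistic one. The default `paper_family` configuration plants
155 sequences (11/29/35/54/26 across the five groups), four motif
blocks shaped like the published degenerate patterns, and 35 invariant
columns in total, with prokaryotes given the highest divergence (0.6 vs
0.35–0.4), mirroring the reported pattern that prokaryotic members are
the most diverse. Scattered invariant columns are spaced ≥ 25 columns
from motif blocks so a lone conserved column can never be absorbed into
a derived motif interval. The generator does **not** emulate
phylogenetic correlation (no tree), realistic indel structure, or
residue-class substitution preferences; passing recovery tests
demonstrates the analysis logic, not robustness to real evolutionary
alignment noise.

**Uptake generator.** Each strain's uninhibited rate is
`relative_rate × Vmax × S/(Km+S)` (defaults: Vmax 10⁻¹¹ mol/min/10⁸
conidia, S = 0.2 µM, Km = 5 µM — a value placed inside the assay's
stated 10–50× tracer window, since the study reports affinities only as
curves). Competitor concentration I scales the rate by
`1/(1 + I/IC₅₀)` with `IC₅₀ = Ki(1 + S/Km)`, so homologous competition
has IC₅₀ = Km + S; a non-substrate competitor (Ki = ∞) leaves the rate
untouched. A non-specific background (1% of the wild-type rate,
unaffected by competitors) is added to every strain, and the null
strain carries only background, so subtraction is exercised
nontrivially. Counts are the exact inverse of the cpm→rate conversion;
noise is multiplicative log-normal on counts, parameterized by CV with
unit mean. The study design is triplicates × two independent
experiments (n = 6 per condition). The noise model is a documented
choice: reported SDs are consistent with proportional error, but no
error model is stated; counting (Poisson) noise, inter-experiment batch
effects and spore-count error are not modelled separately.

**Fixtures.** The strain summary table (growth scores, V% ± SD), the
four growth-group labels with their reported strain memberships, and
the four published motif strings are transcribed verbatim as package
fixtures. The topology segment ranges are synthetic (see above).

## Problem sizes

The packaged analyses and tests run at the study's own scales: 155
sequences × 420 columns for the family, 9 competitor concentrations × 6
replicates for kinetics, 200 seeded simulations for the IC₅₀-recovery
property, and 100 seeded datasets for the letter-assignment oracle.

## Known limitations

- Motif derivation assumes a reasonably gap-free alignment of a single
  protein family; it does not handle domain shuffling or long
  insertions gracefully (gappy columns simply break motifs).
- The four-parameter fit needs ≥ 4 distinct positive competitor levels
  plus a baseline; sparser designs should fix the slope at −1 instead
  (not implemented).
- V% SD propagation ignores the reference strain's own uncertainty.
- The threshold-based functional classifier is an approximation to the
  letters-based grouping; with replicate-level data, prefer
  `compare_strains`.
- Compact letters use greedy insert-absorb; letter *identity* (which
  letter names which tier) is deterministic but not unique across
  algorithms, only the sharing structure is.
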
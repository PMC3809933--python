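# Methods

`chrysodiag` implements a molecular-diagnostic workflow for a cryptic
species complex: find alignment columns that separate one species from all
its relatives, turn them into allele-specific PCR assays, verify those
assays in silico, and support the surrounding ecology statistics and
distance-based species assignment. The concrete system it models is the
*Penicillium chrysogenum* complex — four morphologically indistinguishable
species (*P. chrysogenum*, *P. rubens*, *P. chainii*, *P. floreyi*) that
diverged roughly 0.75 Myr ago, typed at four loci (*benA*, *trpC*, *crt1*,
*ITS*) — but nothing in the code is specific to it.

## Diagnostic sites

A column of a per-locus alignment is *diagnostic* for a target species when
(a) every target sequence carries the same unambiguous base and (b) that
base occurs in no non-target sequence. Fixation within the target is
required: the scan is deliberately conservative, because a primer anchored
on a within-species polymorphism would miss part of its own species.
Columns containing gaps or IUPAC ambiguity codes in any counted sequence
are skipped by default; with `allow_missing` those sequences are ignored at
that column (subject to `min_target_depth`, default 2), except that a
non-target ambiguity code whose expansion contains the target allele still
disqualifies the column — specificity always outranks sensitivity. Sites
supported by fewer than `min_target_depth` target sequences are flagged
`low_support` rather than dropped, because per-species samples can be
legitimately small.

Outgroup handling is a surfaced choice, not an assumption: by default the
scan contrasts only the in-complex species; with `include_outgroups` the
outgroup sequences join the non-target panel. Assays intended for
environmental screening, where most templates are *not* complex members,
should be designed with the outgroup constraint on — the examples and the
acceptance script do exactly that.

## Primer design

Candidate primers are enumerated at every length in 17–29 nt (the range
the published assay primers span) whose 3′-terminal base sits on a
diagnostic site: forward primers read the plus strand ending at the
column, reverse primers read the minus strand ending at the same column.
This is the allele-specific PCR logic — polymerase extension requires a
paired 3′ terminus, so a primer ending on the diagnostic base extends only
on the target species.

Pairs must produce an amplicon of 100–200 bp (configurable), measured
5′ end to 5′ end inclusive of both primers. Only one primer of a pair must
be anchored; the companion is a plain oligo enumerated from the
target-species consensus, because loci rarely carry two diagnostic columns
within amplicon range. Anchoring both is a score bonus.

Scoring is a weighted sum chosen by this package (the original design
step was delegated to interactive software, so the model here is our own):
Tm balance between the pair, GC closeness to 0.5, a both-anchored bonus,
and a penalty on the longest 3′-complementary run (a cheap primer-dimer
propensity proxy). Ties break deterministically (score, then shorter
amplicon, then lexicographic sequences), so re-running with identical
inputs is byte-identical. Melting temperatures come from the Wallace
2(A+T)+4(G+C) rule by default, or from nearest-neighbour thermodynamics
(Allawi & SantaLucia stacking parameters, SantaLucia entropy salt
correction at 50 mM Na⁺, 250 nM primer) via Biopython. PCR cycle numbers
are carried as assay metadata only; no computational analogue of cycle
optimisation is attempted.

## In-silico PCR

A primer binds a template site when its 3′-terminal clamp (default 3
bases) matches perfectly and at most `max_total_mismatches` (default 2)
mismatches occur over the whole primer. The clamp-dominance rule is the
standard rationale for allele-specific PCR and mirrors the 3′-anchored
design. IUPAC codes in the template match optimistically (any compatible
base) but are counted in `ambiguous_matches` so callers can flag them.
Every forward/reverse site combination with the forward 5′ end upstream of
the reverse 5′ end and a product length within bounds (default 50–2000 bp)
is reported as an amplicon.

Species calls enforce the no-overlap contract of a clean species-specific
panel: exactly one positive assay names its target species; no positives
is "other"; two or more is "conflict". An isolate missing an assay's locus
is "untested" for it and never counted positive. When truth is known the
classifier also returns the assay × true-species positive-rate matrix.

## Synthetic complex generator

The generator produces the structure the analysis assumes, not a faithful
population-genetic model. Sequences evolve by a Jukes–Cantor process (equal
rates, uniform base frequencies) along a fixed species tree with branch
lengths = years × rate. Defaults are the study conditions: clock rate
3 × 10⁻⁹ substitutions/site/yr, complex root at 7.5 × 10⁵ yr, within-complex
clades at 4.7/4.5 × 10⁵ yr, outgroup split at 2.75 × 10⁶ yr, four loci of
440–560 bp, 10 isolates per species. The within-complex topology
`((rubens, floreyi), (chrysogenum, chainii))` is configurable because the
real branching order is not resolved with statistical confidence.

Within-species variation is added as independent private mutations per
isolate calibrated so expected pairwise diversity equals
`within_species_polymorphism` (default 10⁻³) — not a coalescent. Loci share
one rate (per-locus rates in the real data vary ~3×; the hook is the
config, not a default guess). There are no indels, no recombination, no
base-composition skew and no rate heterogeneity across sites; passing tests
therefore show the algorithms are correct under clean divergence structure,
not that the assays would survive every quirk of real templates.

Isolate panels are multinomial draws per location over named species plus
an "other" category, with Bernoulli mating types (default ratio 0.5). The
`other_species` field pins the "other" pool to specific (outgroup) species;
left unset it falls back to every species the proportions never name. All
randomness flows from one integer-seeded numpy generator; output is
byte-identical across runs and platforms for a fixed config.

## Count-table statistics

Chi-square tests of independence are Pearson, without Yates continuity
correction and without switching to exact tests at small expected counts.
That convention is deliberate: it is what a plain spreadsheet analysis
computes, and the packaged survey table reproduces all forty published
pairwise-location p-values (including small-count cells such as 0.945) only
under it. Expected counts below 5 attach a warning annotation to the
result instead of changing the method.

The ratio-comparison matrix builds, for every location pair and each
comparison (chrysogenum:rubens, chrysogenum:other, rubens:other,
complex:other), the corresponding 2×2 table and applies the independence
test; cells whose table has a zero margin are undefined (NaN) rather than
errors. One-way ANOVA uses classical sums of squares with the conventions
F = 0, p = 1 when all observations are identical (where a naive 0/0 would
appear). Tukey–Kramer uses the studentized-range distribution with the
Kramer standard error √(MSW·½(1/nᵢ+1/nⱼ)) for unequal group sizes. The
published colony-count ANOVA p-values are *not* reproducible from the
published tables (the per-plate replicate structure was never released), so
ANOVA and Tukey–Kramer are validated against closed-form and quadrature
oracles instead. The exposure estimator converts a plate count and sampled
air volume to conidia inhaled per minute via tidal volume (0.5 l) ×
respiratory rate (15/min).

## Distances, trees, assignment, dating

Pairwise distances (p, JC69, K80) use pairwise deletion of gap/ambiguous
columns; saturated pairs (p ≥ 3/4 under JC69, non-positive logs under K80)
return NaN markers. JC69 is the default stand-in for "maximum likelihood
distances" whose model the original analysis never recorded; full ML
distances are out of scope. Neighbour joining is the classical Q-criterion
algorithm with a deterministic lexicographic tie-break; negative branch
lengths are kept as computed (standard NJ behaviour). The NJ tree is
emitted for inspection — species assignment itself is by nearest type
isolate per locus, with the margin to the nearest other species reported,
and an overall call only when all testable loci agree ("discordant"
otherwise, in the genealogical-concordance spirit). Equidistant species tie
to the lexicographically first and are flagged ambiguous. A locus with
fewer than `min_overlap` (default 50) comparable sites against every type
is untestable.

Divergence dating is the strict-clock conversion years = height/rate on
node heights in substitutions/site. The simulation-facing estimator uses
net divergence d_a = d_xy − (d_x + d_y)/2 so within-species polymorphism
does not inflate T̂ = d_a/(2µ), and reports a Monte-Carlo standard error
across loci. At the study's own scale (four ~500 bp loci, ~9 expected
cross-complex substitutions in total) the estimator is intrinsically noisy
— roughly ±20 % across seeds — which is the same order as the credible
interval the original Bayesian dating reported. Bayesian species-tree
inference itself (HKY fitting, posteriors, HPD intervals) is explicitly not
reimplemented.

## Problem sizes

The test suite and acceptance script run the generator at 5–10 isolates
per species with the default four loci (~2 000 sites), 100–200-isolate
panels, and a 1 000-replicate mating-ratio calibration; these sizes put
every Monte-Carlo check within comfortable tolerance while keeping the
whole suite around half a minute on one CPU.

## Known limitations

- The generator's JC process and star-like within-species model make the
  diagnostic-site yield optimistic relative to real data with rate
  heterogeneity, indels and recombination.
- Primer scoring has no secondary-structure folding energy and no
  multiplex cross-talk model; the dimer proxy is a complementarity run,
  not a thermodynamic calculation.
- In-silico PCR models binding combinatorics, not amplification
  efficiency; cycle counts are metadata.
- Nearest-type assignment degrades when within-species polymorphism
  approaches sister-species divergence; the concordance rule then returns
  "discordant" rather than a forced call.
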
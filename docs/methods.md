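# Methods

## Problem and data model

`karyostat` compares numerical chromosomal variation — whole-chromosome
gains and losses — between predefined groups of single cells. The shared
container is a cell × chromosome matrix of non-negative integer copy
numbers with an explicit boolean missing-entry mask; a statistic never sees
a masked entry, in a numerator or a denominator. Chromosome labels are
normalized (leading `chr` stripped, sex chromosomes uppercased) so FISH
probe panels, SKY karyotypes, and sc-WGS bins share one label space and can
appear in the same summary tables and plots.

Three readers produce the matrix:

- **FISH**: a delimited table, one row per cell, one integer column per
  probed chromosome. Empty, `NA`, `na`, and `NaN` entries become missing;
  any other non-numeric token is an error, never silently missing.
- **SKY**: ISCN karyotype strings (`47,XY,+8`). The leading modal number
  sets the baseline ploidy (nearest multiple of 23), the sex complement
  gives the X/Y counts, and `+N`/`−N` tokens shift single chromosomes.
  Structural tokens (translocations, deletions, markers, …) change no
  whole-chromosome count; they are collected as unparsed tokens. Mosaic
  karyotypes use the first clone with a warning; modal ranges (`44~47`) use
  the first number; clone-size brackets are stripped. The derived counts
  are checked against the reported modal total and mismatches are flagged
  per cell, never corrected. The full ISCN grammar (breakpoints,
  derivative-chromosome arithmetic) is deliberately out of scope.
- **sc-WGS**: an integer copy-number state per genomic bin (BED-convention
  0-based half-open coordinates) as produced by an upstream caller;
  read alignment and segmentation are not reimplemented here. Each
  (cell, chromosome) is reduced to `round(Σ state·len / Σ len)` over the
  cell's observed bins. Halves round away from zero (2.5 → 3) — the
  rounding direction is a convention this package fixes and tests, since
  "nearest integer" alone is ambiguous at halves. Bins missing for a cell
  are dropped and the weights renormalized; a chromosome with no observed
  bin becomes a missing entry.

## Statistics

With N cells, T chromosomes, counts c and euploid reference e (default 2
per chromosome, configurable per chromosome for sex-aware analyses):

- Instability index `I = 100·meanₜ(1 − p̂ₜ/Nₜ)` with p̂ₜ the modal-state
  cell count of chromosome t. The widely-printed form `(1 − p̂ₜ)/Nₜ` is
  negative whenever p̂ₜ > 1 because p̂ₜ is a count, so the fraction-of-cells
  reading is used; under it I is bounded by `100·(1 − 1/N)`, not unbounded.
  Modal ties are broken toward the state closest to e (then the smaller
  state); only the modal count, not its label, enters I.
- ANCA `A = meanₙ qₙ` with qₙ the number of observed chromosomes where
  c ≠ e ("non-diploid" generalized to non-euploid so e = 1 chromosomes are
  handled); normalized ANCA `AN = A/T ∈ [0, 1]`.
- Aneuploidy score `D`: mean |c − e| over all observed entries.
- Heterogeneity score `H`: per chromosome, state counts sorted descending
  (m₀ ≥ m₁ ≥ …) and rank-weighted, `Σ_f f·m_f / Nₜ`, averaged over
  chromosomes. H depends only on the multiset of state counts (tie order
  among equal m values is irrelevant), is 0 iff every chromosome is
  single-state, and is maximal at (N−1)/2 when all cells differ.
- Ploidy proportions: each cell with ≥1 observed count is classified as
  euploid/diploid (all counts equal e), polyploid (uniform integer
  multiple ≥ 2 of e — whole-genome duplication), or aneuploid (everything
  else, including uniform reductions below euploid, since polyploidy is an
  *increase*). The three proportions sum to exactly 1.

With missing entries, D is averaged over all observed entries while I and H
are per-chromosome quantities averaged over chromosomes (each normalized by
its own observed cell count Nₜ). For complete matrices both conventions
coincide with the 1/(TN) double-sum forms, and the mean of per-chromosome D
(or H) equals the aggregate — an identity the tests check numerically.
Per-chromosome summaries report A, AN, D, H with T = 1; the instability
index and ploidy proportions are population-of-cells features and are not
broken out per chromosome.

## Permutation testing

The null hypothesis is that all groups share the statistic's value. All
cell labels across all groups are shuffled jointly (group sizes preserved)
rather than per pair, keeping one permutation stream per run; each
unordered pair's permuted |difference| is compared with its observed one.
Differences are compared in magnitude (two-sided) since the statistics are
nonnegative with no natural sidedness. P-values use the add-one convention
`p = (1 + #{≥ observed})/(1 + B)`, which avoids p = 0 and gives the floor
1/(B+1) — 1/501 ≈ 0.002 at the default B = 500. Benjamini–Hochberg
step-up q-values (via statsmodels) correct across the pairwise tests of one
run; corrections are not pooled across statistics. A single seeded
generator drives the shuffles, so identical seeds reproduce identical
tables.

## Visualization

Every figure is backed by a pure data function so coordinates are testable
and serializable independent of rendering: the D-vs-H scatter (one point
per group × source stratum; color = group, marker = source), the ternary
plot whose barycentric coordinates *are* the ploidy proportions, the
bivariate percentage heatmap (joint copy-number grid of a chromosome pair,
entries summing to 100%, axes covering observed states plus the euploid
state — bolded — with one state of margin), and the group-blocked
copy-number heatmap with missing entries as a distinct category. Grids use
pairwise-complete cells (a cell missing either chromosome of the pair is
excluded from that grid only) and are produced for every source, not only
FISH, since the restriction is presentational rather than mathematical.
A panel of T chromosomes yields C(T, 2) grids. The PDF report has one page
per figure in fixed order (scatter, ternary, grids, heatmap).

## Synthetic populations

The generator emulates a study with treatment arms of varying severity:
each cell starts at the euploid vector, is whole-genome doubled with
probability `polyploid_fraction`, then each (cell, chromosome) gains or
loses one copy with probability `missegregation_rate` (direction
equiprobable); counts are clipped to [0, max_state] (default 8). Defaults:
100 cells/group, 4 chromosomes (a typical FISH probe panel), rates
(0, 0.1, 0.3) across Control/TreatmentA/TreatmentB, 5% polyploid cells —
chosen so all three ploidy classes occur and the arms are clearly ordered.
Single-step ±1 missegregation keeps expectations binomial
(E[ANCA] ≈ rate·T), so distributional tests can assert agreement within
3 standard errors. The generator has no selection, lineage structure, CNV
hotspots, or measurement noise (no FISH false positives or sc-WGS false
negatives), so passing tests demonstrate correctness of the computations,
not robustness to real measurement artifacts.

## Numerical and testing choices

Statistic implementations route through array-level evaluators shared with
the permutation test, and are verified exhaustively against independent
direct-from-formula brute-force evaluations over all small matrices
(N ≤ 4, T ≤ 2, counts ∈ {1,2,3}), plus property tests for the invariances
(cell/chromosome permutation, cell duplication, state relabeling). The
sc-WGS reduction is checked against a per-basepair expansion on toy
genomes and for bin-splitting invariance. Null calibration uses 500
replicate datasets of 50 cells/group at B = 200 permutations; power
monotonicity uses 60 replicates per effect gap — sizes chosen to give
stable rates while keeping the suite quick. Ploidy-proportion sums are
asserted to 1e−9; they are exact rational arithmetic in practice.

## Known limitations

Whole-chromosome integers only — no segment-level CNV scoring, no
derivative-chromosome arithmetic from SKY, no raw-read processing for
sc-WGS. The instability index is bounded under the implemented reading;
values from tools using other conventions are not directly comparable.
Permutation p-values are discrete with resolution 1/(B+1); q-values
inherit that granularity.
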
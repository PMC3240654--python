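# Methods

This note records the models, conventions and deliberate design choices
behind `phylopop`, and what the validation suite does and does not
demonstrate.

## Data model and table expansion

All computation runs over per-individual alignments (equal-length strings
over `A C G T - N`, each individual carrying a locality and a population
label). Published short-fragment surveys are often printed only as a
polymorphic-site haplotype table: one row per haplotype, one column per
variable site, `.` for identity with the reference row, `-` for a gap, and
per-locality counts. `expand_table` reconstructs the per-individual
alignment from such a table by resolving the dots and embedding the printed
columns in a monomorphic background of a fixed filler base (`A` by default)
so the alignment reaches the declared fragment length (535 bp for the
packaged 16S table). Invariant columns that are identical across all
individuals cancel out of every pairwise comparison, so neither the filler
base nor the placement of the variable columns affects any distance,
haplotype, site or tree statistic; the test suite asserts filler invariance
explicitly. The source table prints site coordinates, but its first digit
column is not machine-readable, so positions are carried as optional
metadata only and never used in computation. The packaged table declares
535 columns; a figure caption in the same source says 536 bp for the
corresponding tree, a one-unit discrepancy that cannot change any statistic
computed here (the extra column would necessarily be invariant or
indel-deleted in every pair).

## Haplotype and site statistics

Individuals share a haplotype iff their full aligned sequences are
identical, with gaps as ordinary states (the one indel column in the 16S
table is what separates some haplotype pairs). A column is *variable* with
≥2 observed states (`N` never counts as a state; a gap does), and
*parsimony informative* with ≥2 states each carried by ≥2 individuals.
Nei's unbiased haplotype diversity is *h = n(1 − Σ pᵢ²)/(n − 1)*.

A column is a *fixed difference* between two populations when their state
sets are disjoint. "Nearly fixed" has no standard definition; here a
column is nearly fixed when removing at most *t* exception individuals in
total (default *t* = 2, a CLI flag) makes the sets disjoint while leaving
both populations represented. The minimal removal is found exactly: each
shared state must lose all its carriers on one side, and sides are chosen
(exhaustively, the shared-state count is tiny) to minimise the total. `N`
is excluded from state sets so missing data can neither create nor destroy
a diagnosis.

## K2P distances and group summaries

Pairwise distances use Kimura's two-parameter model with *pairwise
deletion*: for each pair independently, columns with a gap or `N` in either
member are dropped (complete deletion would discard the indel column's
information for all pairs, and the published 16S averages clearly retain
all 20 individuals). With transition and transversion proportions P and Q
over the L usable columns, *d = −½ ln[(1 − 2P − Q)√(1 − 2Q)]*. A
non-positive log argument (saturation) raises an error rather than
returning NaN: data in this package's scope sit far from saturation, so a
saturated pair signals misuse. Identical sequences return exactly 0.

Group summaries average over *individual* pairs — each individual counts
with its multiplicity, not one term per haplotype — matching the
"between individuals" convention of survey reports. The attached
uncertainty is a nonparametric *site bootstrap*: columns are resampled with
replacement (B = 1000 by default, seeded), the group mean recomputed per
replicate, and the standard deviation across replicates reported as the SE.
Replicates with undefined distances are redrawn and counted; more than 10%
redraws escalates to an error. Distances are substitutions/site
internally; percent with one decimal is applied only in the reporting
layer.

## Neighbor joining and bootstrap support

NJ follows Saitou & Nei with the Studier–Keppler criterion
*Q(i,j) = (m−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k)*. Ties in Q are broken toward
the pair whose members were created earliest (input order, then join
order), which makes results deterministic — relevant here because samples
with repeated haplotypes produce exactly tied zero distances. Branch
lengths use the standard split formula; negative estimates are clamped to
zero without moving the deficit to the sister branch. On additive matrices
NJ is exact, and the suite verifies topology and all path lengths against
randomly generated trees (n ≤ 8), plus scikit-bio's independent NJ as a
cross-check.

Bootstrap supports are MEGA-style: column resampling → K2P matrix → NJ per
replicate, and each internal edge of the *original* tree is annotated with
the percentage of replicates containing the same canonical split (no
consensus tree is built). Splits are canonicalised as the side not
containing the lexicographically smallest leaf. Trees are unrooted
(internal nodes of degree 3); rooting on an outgroup leaf is a pure display
operation that splits the pendant edge and preserves all path lengths.
Newick output stores supports as internal-node labels and lengths to six
decimals, and round-trips through the package's own reader (dendropy is
used in tests to confirm interoperability).

## Molecular clock

The calibration divides an observed *total* pairwise divergence between a
geminate pair by the elapsed time (e.g. a 12.4% trans-isthmian COI distance
over 3.1 MY gives 4.0%/MY), so dating divides another total divergence by
the same rate with no factor of two — the two conventions must not be
mixed, and a `per_lineage` flag halves the rate for users of the other
convention. The point estimate carries no model of rate variation; when a
site-bootstrap SE for the observed distance is available it is propagated
linearly into a ±2 SE interval for T, labelled as an extension of the
published point-estimate arithmetic.

## Simulator

`simulate_split` draws a uniform-random ancestor of length L, evolves two
population ancestors independently for `T_split` under the exact
finite-time K2P transition probabilities (rates α = κμ/(κ+2) for the one
transition target and β = μ/(κ+2) per transversion target, so μ is the
total substitution rate per site per MY along a lineage), then gives each
sampled individual Poisson(θ_w·L/2) private point mutations with the same
transition bias, so the expected within-population pairwise distance is
θ_w. Within-population variation is thus a *star genealogy*, not a
coalescent — a deliberate simplification: the pipeline consumes only
pairwise summaries, and the star model keeps every expectation in closed
form (the test oracle composes matrix exponentials for the
branch-plus-mutation process and pushes the implied P, Q through the K2P
formula). Consequences: the simulator does not reproduce the correlated
genealogical structure, skewed haplotype-frequency spectra, or migration
histories of real samples, so passing recovery tests validate the
*estimators*, not any demographic realism.

Defaults mirror the motivating 16S survey: L = 535, 7 + 13 individuals,
μ = 0.02 subs/site/MY (a 4%/MY total-divergence isthmian rate split across
two lineages), κ = 5 (a typical mtDNA transition bias, consistent with the
16S table where the region-diagnostic substitutions are predominantly
transitions), T_split = 0.95 MY, θ_w = 0.005.

`recovery_experiment` runs the full pipeline per replicate and dates the
split from the *net* between-group distance (between mean minus the average
of the two within means). The raw between mean estimates 2μT + θ_w, so
dating it directly would inherit an upward bias of θ_w/(2μ) MY; the net
correction removes it, and the recovery suite confirms the split time is
recovered within a few percent (the default validation uses 200 replicates
at L = 1000 with 10+10 individuals, and a per-replicate calibration pair
simulated at 3.1 MY). The headline dating function itself
(`date_divergence`) reproduces the conventional raw-distance arithmetic;
the net correction is a choice of the recovery harness, where the truth is
known.

## Numerical and interface conventions

- Coordinates are 1-based and inclusive in all reports.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; identical config + seed reproduces every output file
  byte for byte (no timestamps are written).
- Degenerate inputs fail loudly with typed exceptions (`AlignmentError`,
  `FormatError`, `UndefinedDistanceError`, `SaturationError`, ...) naming
  the offending record or pair; the pipeline prefixes stage names.
- Validation problem sizes (bootstrap replicate counts in tests, recovery
  replicate counts, simulated sequence lengths) are chosen so the whole
  suite runs in well under a minute of CPU apart from the 200-replicate
  recovery experiment, which dominates at roughly ten seconds.

## Known limitations

- Only the K2P model is implemented; no JC69/HKY/GTR, no model selection,
  and no likelihood or parsimony tree search — distance/NJ only.
- "Nearly fixed" is an interpretation (tolerance-based); counts at other
  published tolerances require choosing *t* accordingly.
- The clock assumes a single constant rate; calibration-age uncertainty and
  among-lineage rate variation are not modelled.
- The simulator has no indel process; gap handling is exercised only by the
  table-derived and hand-built fixtures.
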
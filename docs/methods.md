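# Methods

## Model

Each position of a retrotransposon consensus reference is treated as a
large population of homologous sites: the remnants of a subfamily silenced
`t` myr ago have accumulated substitutions independently per site at
context-dependent rate constants `r(i→j)` (byr⁻¹). In the regime
`r·t ≪ 1` the expected fraction of remnants carrying base `j` at a
position whose consensus is `i` grows linearly, `f_j(t) ≈ r(i→j)·t`, so an
ordinary least-squares slope of fraction versus age across subfamilies
estimates the rate. The recovered quantity is the *core* rate — the
genomic single-base average plus the short-range (≤ 7 nt) context
deviation; CpG-driven, long-range, gene and targeted effects are outside
the model and are suppressed by the stringency filters rather than
modelled.

Assumptions inherited by everything downstream: rates are constant over
the dated window; sites evolve independently given their 7-mer context;
subfamily ages are known inputs (myr), never hard-coded; repeated hits at
one site are negligible over the window (the expected second-hit bias is
`100·r·δt` percent — `repeated_substitution_bias` quantifies it, and the
exact-chain generator mode can produce it).

## Inference pipeline

**Alignment.** Remnants are aligned to the reference pairwise and
semi-globally with Biopython's `PairwiseAligner`: the reference's
unaligned flanks cost nothing (a truncated remnant may land anywhere) while
gaps at the remnant's own ends pay the ordinary cost, keeping the remnant
one contiguous block. An `overlap` mode (both ends free) is a switch.
Default scoring is match +1, mismatch −1, gap open −5, gap extend −2 —
deliberately indel-hostile, as expected for high-identity remnants; all
four values are configurable, and tests show score agreement with an
exhaustive DP oracle and insensitivity of inference to these defaults for
high-identity synthetic remnants. Co-optimal alignments break ties to the
leftmost reference start (scanning at most 16 co-optima) so runs are
byte-reproducible. Bases opposite gaps are never counted; N bases are
never counted. Synthetic pools carry ground-truth offsets, and
`trusted_offsets=True` bypasses the aligner — alignment cost is not the
method's point and desk-scale tests use this path.

**Stringency criteria.** A position reports rates only when (1) every
subfamily has ≥ 700 mapped bases there (`min_depth`); (2) the reference's
consensus base is the most prevalent variant at ≥ 80% in every subfamily
(`min_prevalence`; inclusive, and the ordering clause is checked
separately so a 45% consensus never passes against a 50% rival); (3) the
fraction-versus-age Pearson correlation exceeds 0.7 strictly
(`min_pearson`). The correlation criterion applies per substitution type:
a position may report G→A but not G→T (`require_all_fits` restores the
all-or-nothing reading). Excluded reference ranges — for the packaged
L1Hs-like case the low-complexity 3' stretches 5856–5895 and 6018–6064 —
are never evaluated.

**Fitting.** Ages are converted myr → byr so slopes are byr⁻¹. The fit
has a free intercept (no implicit (0, 0) anchor; `through_origin` is a
sensitivity switch), Pearson r is computed on the same points, and the
t-value is slope / SE(slope) with n−2 degrees of freedom. Negative slopes
are clamped to 0 in the reported rates (rates are non-negative by
definition and downstream sampling requires it) with the raw slope
retained. The sweep is vectorised across positions but is tested to agree
with per-position `fit_rate` calls to 1e-12.

## The k-mer database and mapper

Every passing position contributes its centred 7-, 5-, 3- and 1-mer (a
level only when the window fits inside the reference and contains no N);
per (k-mer, target) the **median** rate over contributing positions is
stored, with occurrence counts and the median t-value. Ties in the median
use the midpoint of the two central values; permuting contributors never
changes the database.

Queries walk 7 → 5 → 3 → 1 per target base and return the longest-context
record; an entry missing even at level 1 is an error (an incomplete
database cannot map arbitrary sequence). Sub-k-mers containing N fall
through. At a query sequence's first/last 3 positions the centred window
cannot fit; the mapper shrinks to the longest centred k-mer that does.
This edge rule is this package's choice — genome-scale use makes edges
negligible, but desk-scale fixtures meet them constantly.

Strand symmetrization pairs (K, j) with (revcomp K, complement j) at the
same context level: both present → both rates set to their mean (t-values
averaged; each record keeps its own occurrence count, which is what makes
the operation idempotent record-for-record); one present → its value is
copied to the missing mate at the same level, so the better-quality
context wins and longer-k coverage grows. Odd k guarantees no k-mer is
its own reverse complement.

For bulk work (the evolver, BSP-weighted site sampling) the fallback is
resolved once into a dense 4⁷ × 4 table; it is tested to agree with
record-by-record queries.

## Sequence evolver

The in-silico genome is a uint8 code array with a per-position 4-vector of
rates maintained alongside. Each step samples a batch (default 5000) of
substitutions proportionally to all per-position rate constants —
time-homogeneous weighted sampling; the trajectory is tracked in
substitution counts, not a physical time variable. Within a batch,
positions are drawn *without replacement* (Gumbel top-k), so no site is
hit twice before its rates refresh; `batch=1` recovers the exact
sequential chain, and tests compare the two. After a batch only positions
within ±3 nt of a change are recomputed (the context window is 7 nt);
a full-recomputation cross-check runs in the tests after every step.

Equilibrium is declared when the G+C drift across a trailing window of 2
substitutions per site — measured as the difference between the first- and
second-half mean G+C of the window, which is robust to snapshot noise —
falls below tolerance. The default tolerance is max(0.05 pp,
3·√(0.25/L)): the nominal 0.05-percentage-point criterion floored at the
binomial Monte-Carlo noise of the sequence length, without which
desk-scale sequences (≤ 100 kb) could never terminate. A cap (default 20
substitutions per site) returns with a warning. Simulations at this
package's test scale use 20–100 kb sequences; equilibrium composition is a
property of the database alone and is checked against the analytic
stationary distribution (left null vector of the 4×4 generator) for
context-free databases, and for start-composition independence (60% vs
30% G+C) for context-dependent ones.

## k-mer analytics and enrichment

Spectra index k-mers lexicologically (A<C<G<T, base-4); windows containing
N are skipped. Expected-by-chance fractions are products of base
fractions. Two CpG-exclusion semantics coexist as explicit flags, because
they answer different questions: `contains_cg` (a CG dinucleotide anywhere
in the k-mer) for spectrum comparisons, `central_cpg` (the central base is
the C or G of a CpG dyad) for enrichment fits.

Mutation-site tables keep non-coding rows, drop SNP-flagged rows, then
drop duplicate (chrom, pos, ref, alt) rows keeping the first encountered.
The enrichment ratio of a 7-mer is its occurrence fraction among the
(filtered) sites' centred heptamers divided by its fraction in the whole
background genome, counted with overlapping windows genome-wide; sites
whose ref base mismatches the genome, or whose window leaves the sequence
or contains N, are rejected and logged. The ratio-versus-BSP association
is summarised as an OLS slope over records with central BSP below 1.3
byr⁻¹, central-CpG 7-mers excluded (smoothed curves are presentation, not
measurement, and are out of scope).

The genome-wide rate estimate is the base-composition-weighted mean of the
four singleton BSPs; per-generation conversion is exactly
`rate_byr × generation_years / 1e9`, and `convert_rate` is its inverse.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical premise of the method: remnant
copies of a known reference, 5'-truncated (truncation point uniform; a
configurable fraction full length; default ages 3.1, 7, 10, 15, 20.4 myr
spanning the dated window), accumulating substitutions per site under a
known context-rate table. Mode (a) draws one Bernoulli event per site
with p = r·t — the single-hit regime the inference assumes; mode (b) runs
an exact continuous-time chain per remnant with the context refreshed
after every event, which is what makes the repeated-hit bias measurable.
Every remnant carries an event log that replays to it byte-for-byte.
Default truth rates are drawn uniformly per (heptamer, target) from
0.2–4 byr⁻¹.

Not emulated: real L1 biology (ORFs, poly-A, promoter structure),
CpG-specific hypermutation, regional (long-range) rate variation,
selection, indels beyond an optional alignment-exercise mode, and
subfamily age uncertainty. Passing tests therefore demonstrate that the
estimator recovers rates *under its own model assumptions* at realistic
depths — not that those assumptions hold for any particular genome.

Two statistical facts shaped the fixture sizes. First, OLS slope noise
scales as 1/√depth: at the 700-base depth floor with rates spread over
0.2–4 byr⁻¹ the recovered-versus-true correlation clears 0.9, but a
*split-half* comparison with both halves pinned exactly at the floor
carries twice the noise, so the half-pool check generates 3000
remnants/subfamily (halves of 1500, still subject to the 700 filter) —
mirroring the original design, where positions surviving the cutoff had
depths well above it. Second, enrichment fixtures use reduced-alphabet
genomes (2 letters for null-ratio checks, 3 letters for slope fits) so
heptamers recur often enough for per-7-mer ratios to concentrate; a 4-letter
30 kb genome has mostly unique heptamers and observed-only selection bias
then dominates the ratios.

## Numerical choices and limitations

- Coordinates are 1-based inclusive in all files and messages; 0-based
  internally.
- All randomness flows through seeded `numpy` generators; the evolver
  records its seed.
- Degenerate inputs: zero-depth subfamilies fail prevalence with a reason;
  constant fractions give undefined Pearson and fail the correlation
  criterion; an all-zero-rate sequence is an "absorbed state" error;
  compositions must sum to 1 within 1e-9.
- Test and acceptance problem sizes (2 kb references, 800–3000
  remnants/subfamily, 20–100 kb simulations, 8000-site tables) were chosen
  so each statistical assertion sits several standard errors from its
  pass boundary under the stated conditions.
- The printed per-level record counts of any particular rate table
  (how many constants resolve at 7/5/3/1) are data-dependent and are not
  treated as invariants; only completeness (3 constants per heptamer) is.
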
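# Methods

This note documents the models, algorithms and numerical choices behind
`tisim`, and what its synthetic benchmarks do and do not demonstrate.

## Genetic model

Individuals are diploid with `P` ordered, phased, biallelic markers coded so
that 1 is the favorable allele.  A trait architecture designates `n_TL`
target loci (the introgression goal) and a nonnegative allele-effect vector
`W`; all other loci are background.  Background recovery rate `RC`,
background GEBV `V_B` and pairwise genetic potential `GP` are defined in the
README.  Two conventions are fixed deliberately:

- **Success boundary.**  A successful individual satisfies `RC ≥ RC_goal`
  (the boundary counts).  The verbal definition of success and the
  mate-selection program's constraint disagree on `>` vs `≥`; we adopt `≥`
  everywhere for consistency with the optimization model.
- **Background always excludes the target loci**, in every phase and every
  strategy.

## Meiosis

Recombination follows Haldane's mapping function, i.e. crossovers form a
Poisson process of rate 1 per Morgan with no interference.  A gamete is the
path of a two-state Markov chain over loci: uniform start haplotype, switch
probability `rf[p]` between loci `p` and `p+1`.  Map input is converted with
`r = (1 − e^{−2d})/2`; adjacent markers on different chromosomes get
`rf = 0.5` (free assortment), which is exactly equivalent to independent
per-chromosome draws because the chain re-randomizes at such an interval.
`rf` values are clipped to `[1e−6, 0.5]` so the vector stays inside its
nominal domain `(0, 0.5]` even for colocated markers (which are jittered by
1e−9 cM to keep strict order, with a warning).

The production sampler does not flip a Bernoulli coin per interval.  It maps
each finite interval back to its effective Morgan length
`u_p = −ln(1 − 2 rf_p)/2`, draws crossover events from a Poisson process on
the concatenated length, and takes per-interval event parity as the switch
indicator; segment starts draw a fresh uniform source bit.  This is
distributionally identical to the chain (parity of a Poisson count with mean
`2u` is 1 with probability `(1 − e^{−2u})/2 = rf`) at roughly an order of
magnitude fewer random draws.  A literal Bernoulli-chain sampler is kept in
the code base, and both are validated against exhaustive gamete-distribution
enumeration (`P ≤ 12`) in the test suite.  In the look-ahead's terminal
selfing step, progeny are scored without materializing their genotypes: a
gamete is a sequence of parental-haplotype chunks between crossovers, so
`V_B` and the background allele count are prefix-sum differences per chunk
and only the target loci are read individually.  The fused kernel is tested
to agree bit-for-bit with the materialized path under a shared random
stream.

## Predicted cross value

`PCV(P1, P2)` — the probability that a random gamete of a random progeny of
the pair is favorable at every locus — is computed exactly by a
transfer-matrix dynamic program with 8 states: (which progeny gamete the
final gamete copies from) × (source haplotype inside P1's meiosis) ×
(source haplotype inside P2's meiosis).  The three chains switch
independently with probability `rf[p−1]`; a state survives locus `p` only if
its implied allele is favorable.  The initial distribution is uniform over
the 8 states and `PCV` is the surviving mass after the last locus.  The
quantifier runs over *all* `P` loci (targets and background), following the
printed definition.  Any algorithm producing this probability is
acceptable; the DP is validated against composing the gamete-distribution
enumeration twice (`≤ 1e−10` on random instances with `P ≤ 6`).

## Selection strategies

**BGS-BC / PCV-BC / LAS-BC** rank the positive individuals of the current
generation and cross the top `NC` to the RP, with stable tie-breaking by
(score, `V_B`, id).  If fewer than `NC` positives exist the plan shrinks
with a warning.

**BGS-IC** solves the mate-selection integer linear program exactly as
printed: over unordered pairs `(i, j)`, `i ≤ j`, drawn from {RP} ∪
population (RP at index 1), maximize
`Σ x_{ij} (W* · targetdose_i + V_{B,j})` subject to member `i` meeting
`RC_goal`, joint coverage of every target locus, exactly `NC` crosses, and
the printed single-use constraints (which exempt the RP).  `W*` is
`2 Σ_{p∉TL} W_p + 1`; any strictly larger constant yields the same optima
(tested).  The asymmetry — constraint on `i`, GEBV credit to `j` — is kept
verbatim; a `symmetric_rc` flag applies the RC constraint to both members
for users who prefer the symmetric reading.  One consequence of the printed
objective worth knowing: a positive individual that meets the recovery goal
is selected to *self* rather than backcross, because the RP earns no `W*`
credit as member `i`; early generations, where almost nobody meets the
goal, therefore still come out overwhelmingly backcross.  The solver is
HiGHS via `scipy.optimize.milp` with variables pre-pruned by constraints;
infeasible instances relax in stages (first the cross count, then the RC
threshold to the best attainable), both logged.  Solutions are checked
against exhaustive enumeration on all small instances in the tests.

**PCV-IC** evaluates PCV only for unordered pairs over {RP} ∪ the top 20 %
of individuals by `V_B` (the printed candidate-set sentence is ambiguous;
we read it as all pairs within that pool), keeps pairs with full target
coverage, and selects the top `NC` with every non-RP individual used at
most once.

**LAS-IC** first filters candidate pairs: full genetic potential at the
target loci; joint background potential strictly above `RC_goal`; rank by
summed background GEBV.  The top `round(0.1 N)` pairs (N = current
population size) are each scored by look-ahead simulation: cross the pair
(K progeny), then in each simulated generation apply the same filter at
`round(0.05 N)` and cross one uniformly chosen surviving pair, until
generation `T − 1`; self the positives (up to `N_pos`) for K progeny each
and record `V = (1/N_pos) Σ_i V_{B,i} n_i / K`.  Repetitions with no
surviving pair or no positives score 0.  The best `NC` pairs are selected;
the same individual may appear in several pairs, and reciprocal duplicates
cannot occur because pairs are unordered.

Look-ahead conventions: the horizon `T` defaults to generation 5 (the
success-by-G5 benchmark) and shrinks as the program advances; `V_{B,i}` is
read as the maximum background GEBV among individual `i`'s K selfed progeny;
when fewer than `N_pos` positives exist the missing terms contribute 0 and
the divisor stays `N_pos`, so scarcity is penalized.  In LAS-BC's
intermediate generations a random *positive* progeny carries the chain; if
none exists a random progeny is used and the path almost surely scores 0.

### Computational budgets

Look-ahead selection is by far the dominant cost (the underlying approach is
known to need multi-core hours at full scale).  Three bounded knobs keep it
tractable, all configurable: LAS-BC evaluates at most `max_candidates = 10`
candidates, prescreened by `V_B`; the LAS-IC outer and inner pools are
capped at 10 and 6 pairs after the `0.1 N` / `0.05 N` rules; and
`N_pos = 5` positives are selfed in the terminal step (the source method
leaves `N_pos` unstated).  These are breadth-of-search limits, not changes
to the scoring rule; they were fixed once from profiling, before any
benchmark comparisons were run.

## Pipeline and selfing phase

Initialization produces the F1 (t = 0) and a BC1F1 population of K (t = 1).
Selection runs at t = 2 and t = 3 with `NC(t)` crosses of K progeny; the
next generation is the union of all cross progenies (no truncation).
Resource levels R1–R5 allot 2–6 crosses per generation from t = 2 on, one
cross at t = 1.

From t = 4 each of `NC(t)` selected individuals is selfed for 1,000
progeny.  The selection criterion — "most likely to yield a successful
selfed progeny" — is made concrete as `Π_{p∈TL} q_p · 1[RC attainable]`,
with `q_p = 1, 1/4, 0` for fixed-favorable / heterozygous /
fixed-unfavorable target loci, where attainability means the fraction of
background loci carrying at least one favorable allele reaches the goal.
When a top candidate's RC outcome is genuinely uncertain (attainable but not
guaranteed), the estimate is refined by a 200-progeny Monte Carlo selfing;
ties break by `V_B`, then id.  Success is declared in the generation whose
realized selfed cohort contains a successful individual; a budget of `NC`
individuals is selfed per generation (the resource schedule applies to all
of t = 2–8).  Past the 8-generation deadline the program records a failure.

## Randomness and reproducibility

All randomness flows from one root seed.  Each program's seed is derived
from the root seed and the program key (donor id via a stable FNV hash,
strategy, level) through `numpy.random.SeedSequence`, so campaign results
are independent of iteration order and bit-for-bit reproducible; the seed is
stored in the program record for exact replay.  The recovery-goal
sensitivity comparison reuses the same per-program seeds at both goals.

## Synthetic data

The generator emulates the structure of the motivating maize setup: 390
SNPs on 10 chromosomes (markers proportional to chromosome length, placed
uniformly; 1.5 Morgans per chromosome as an order-of-magnitude maize-like
default), three target loci on chromosomes 3, 5 and 8 (the median marker of
each), 90 fully inbred donors homozygous favorable at every target locus,
and an RP favorable at all background loci.  Donor background alleles are
i.i.d. Bernoulli(π) with π = 0.5 by default; allele effects are exponential
with the three target effects set largest, mimicking the sparse output of a
Bayesian whole-genome regression without estimating anything.  A
heterozygosity knob exists but defaults to 0 (inbred donors).

What this does *not* emulate: linkage disequilibrium between background
loci, realistic allele-frequency spectra, imputation/phasing artifacts, or
the particular effect sizes of any real panel.  Donor background
frequencies of the real data are unknown, so campaign-level success
proportions are not expected to match any published table; the benchmarks
below therefore check *orderings*, which are robust to π, not levels.

## Benchmarks (what the acceptance script computes)

- The reference table's standard errors are recomputed from its printed
  proportions at n = 90 via `sqrt(p(1−p)/(n−1))` — the convention that
  reproduces every parenthesized value to 4 decimal places.
- Oracle equivalence on 1,000 random small instances each: PCV DP vs
  two-meiosis enumeration (`≤ 1e−10`), and the BGS-IC ILP vs exhaustive
  enumeration (equal objectives).
- Meiosis calibration over 100,000 gametes on the maize-like map (adjacent
  recombinant fractions vs `rf`, within 3 SE allowing the expected handful
  of excursions among 389 intervals) and the 1/64 selfing-fixation law.
- A scaled-down campaign — 30 donors, 100 Monte Carlo repetitions, K = 100,
  all six strategies — comparing the extremes of the resource ordering
  (R1 vs R5), the recovery-goal ordering (0.96 vs 0.97 at matched seeds, on
  the two cheap-selection strategies BGS-BC and PCV-IC), and LAS-IC vs
  LAS-BC at R1.  Problem sizes were chosen so the whole script runs in
  minutes on one CPU; orderings are asserted within twice the combined
  standard errors.
- Determinism: repeated programs and campaigns serialize byte-identically.

## Known limitations

- Diploids only; no crossover interference, mutation, genotyping error or
  phenotypic selection.
- The candidate-pool caps above make LAS rankings approximate relative to an
  unbounded search; widening them trades time for search breadth.
- The selfing-phase selection criterion is a concrete reading of a verbal
  rule; other readings (e.g. always Monte Carlo) are possible and would
  change mainly which of several near-equivalent candidates is selfed.
- `enumerate_gamete_distribution` is exponential in `P` and refuses
  `P > 12` by design; it exists as an oracle, not a production path.
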
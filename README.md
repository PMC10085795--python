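# tisim — a marker-assisted trait-introgression breeding simulator

`tisim` simulates trait-introgression (TI) breeding programs: moving the
favorable alleles of a few major QTL from a donor line into an elite
*recurrent parent* (RP) while recovering as much of the recipient's genetic
background as possible, within a fixed number of generations and a fixed
number of crosses per generation.  It is aimed at quantitative geneticists
and breeding-program designers who want to compare **selection strategies**
— in particular, whether allowing *intercrosses* between selection
candidates (rather than only backcrosses to the RP) buys success
probability at a given resource level.

## The model

Individuals are diploid and fully phased: a `P x 2` binary matrix `G`,
where 1 is the favorable allele.  A small set of target loci `TL` must be
introgressed; everything else is *background*.  The core quantities are

- **background recovery rate**  `RC = Σ_{p∉TL} Σ_m G_{p,m} / (2 (P − n_TL))`,
- **background GEBV**  `V_B = Σ_{p∉TL} Σ_m W_p G_{p,m}` for allele effects `W ≥ 0`,
- **genetic potential**  `GP(i,j; L) = (1/|L|) Σ_{p∈L} 1[dose_i(p) + dose_j(p) ≥ 1]`,
- a **positive** individual carries ≥ 1 favorable allele at every target
  locus; a **successful** one is homozygous favorable at every target locus
  with `RC ≥ RC_goal`.  The first generation containing a successful
  individual is the *successful generation*.

Meiosis follows the Haldane (no-interference) model: map distance `d`
Morgans gives recombination fraction `r = (1 − e^{−2d})/2`, and gametes are
sampled from the induced two-state Markov chain over ordered loci, with free
assortment across chromosomes.

A program runs in three phases: initialization (donor × RP, then one
backcross, giving a segregating BC1F1 population), two generations of
strategy-driven selection with `NC` crosses of `K` progeny each, and
repeated selfing (1,000 progeny per selfed individual) until success or an
8-generation deadline.

Six interchangeable selection strategies are provided:

| strategy | ranks by | crosses |
|----------|----------|---------|
| `bgs-bc` | background GEBV | backcross only |
| `pcv-bc` | predicted cross value (exact 8-state DP) | backcross only |
| `las-bc` | look-ahead Monte Carlo score | backcross only |
| `bgs-ic` | mate-selection integer program | BC + intercross + self |
| `pcv-ic` | predicted cross value over a top-20 %-GEBV pool | BC + intercross + self |
| `las-ic` | look-ahead Monte Carlo over a filtered pair pool | BC + intercross + self |

The **predicted cross value** `PCV(P1, P2)` is the exact probability that a
random gamete of a random progeny of the pair carries the favorable allele
at *every* locus — computed by a transfer-matrix dynamic program whose
8 states track which progeny gamete the final gamete copies from and the
source haplotype inside each parent's meiosis.  The **look-ahead** score
simulates each candidate cross forward to the target generation `T`, selfs
the terminal population's positives, and averages
`V = (1/N_pos) Σ_i V_{B,i} · n_i / K` over Monte Carlo repetitions, where
`n_i` counts successful selfed progeny of individual `i` and `V_{B,i}` is
the best background GEBV among them.

## Worked example

Generate a small synthetic panel and run one donor's program:

```
$ tisim generate-data --out panel --preset micro --seed 7
wrote 4 files to panel

$ tisim run --panel panel --strategy bgs-bc --level R2 --rc-goal 0.7 --seed 1
{
  "donor_id": "D000",
  "strategy": "bgs-bc",
  "level": "R2",
  "rc_goal": 0.7,
  "deadline": 8,
  "seed": 1715462895,
  "successful_generation": 4,
  "failure_reason": null,
  "cross_fractions": {
    "2": {"backcross": 1.0, "intercross": 0.0, "self": 0.0},
    "3": {"backcross": 1.0, "intercross": 0.0, "self": 0.0}
  }
}
```

(cross-type fractions abbreviated to one line each)

The record says donor `D000` produced its first successful individual in
generation 4 (the first selfing generation): both target loci were fixed
favorable and the 0.7 background-recovery goal met.  Under a backcross-only
strategy every selection cross contains the RP, so the cross-type fractions
are all backcross.

A campaign (every donor × strategy × level) aggregates outcomes into a
tidy table with the success-by-generation-5 proportion and its standard
error `sqrt(p(1−p)/(n−1))`:

```
$ tisim campaign --panel panel --strategy bgs-bc --strategy bgs-ic \
      --level R1 --rc-goal 0.7 --seed 3 --out camp
$ tisim report --records camp/records.jsonl
strategy level  rc_goal  gen4  gen5  gen6  gen7  gen8  fail  n  success_by_g5  se_g5
  bgs-bc    R1      0.7     6     0     0     0     0     0  6            1.0    0.0
  bgs-ic    R1      0.7     6     0     0     0     0     0  6            1.0    0.0
```

The maize-like preset (`--preset maize`) reproduces the standard study
conditions: 390 SNPs on 10 chromosomes, 3 target loci on chromosomes 3, 5
and 8, 90 inbred donors homozygous favorable at all targets, and an RP
favorable everywhere else.

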
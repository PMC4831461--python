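# Methods

## Model and assumptions

`btrefuge` implements a deterministic, infinite-population, discrete-
generation model of one biallelic resistance locus in a pest exposed to
a landscape split between a Bt-expressing crop (fraction ω) and a
non-toxic refuge (1 − ω).  The assumptions, and what they exclude:

* **Spatially unstructured landscape.**  Larvae are assigned to crop
  types at random, so a genotype's landscape fitness is the ω-weighted
  mean of its two survival probabilities.  Block vs seed-blend refuge
  geometry, dispersal kernels and local density dependence are out of
  scope; ω must be read as an *effective* Bt fraction.
* **Per-generation fixation index.**  Assortative mating enters as a
  fixed deviation F from Hardy–Weinberg genotype proportions applied
  anew each generation (RR = q² + pqF, RS = 2pq(1 − F), SS = p² + pqF),
  not as cumulative inbreeding.  This matches a "mating to type" or
  limited-premating-dispersal mechanism that resets with every
  generation's emergence.
* **Deterministic dynamics.**  No drift, no mutation, no demography.
  q₀ is an input.  Consequently every result is exactly reproducible and
  the recursion is a brute-force oracle for all approximations.
* **Viability selection only**, ordered: zygotes at F-adjusted
  proportions → landscape-weighted survival → allele frequencies among
  survivors become the next generation's q.  This is the only event
  order consistent with defining average allelic fitnesses from the
  zygote genotype proportions.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| ω | Bt fraction of landscape | — | [0, 1]; ω = 1 allowed, flagged as the textbook pure-selection limit |
| F | fixation-index / assortative-mating coefficient | 0 | per generation |
| h | dominance of resistance on Bt plants | 0 | V_RS = V_SS + h·(V_RR − V_SS) |
| g | dominance of the fitness cost on refuge | 0 | U_RS = U_SS − g·(U_SS − U_RR): the heterozygote expresses fraction g of the cost.  This (not the interpolation from U_RR) is the convention under which the composite χ = F + g − F·g emerges from the allelic-fitness algebra |
| U_SS, V_SS | susceptible survivals | 1, 0 | the reference normalization; not enforced, so arbitrary tables are expressible |
| U_RR | resistant survival on refuge | 1 | 1 − U_RR is the fitness cost; ~0.25 is a field-plausible magnitude |
| V_RR | resistant survival on Bt | 1 | V_RR < U_SS is incomplete resistance |
| q₀, q_k | initial and critical allele frequency | 10⁻⁴, 0.1 | q_k = 0.1 is the conventional loss-of-containment proxy |

Composites: ε = F + h − F·h (Bt-side deviation), χ = F + g − F·g
(refuge-side cost expression).  When a fitness table is supplied
explicitly, h and g are inferred from the heterozygote survivals (taken
as 0 when the homozygote span is zero, where the interpolation is moot).

## Passage-time computations

* **Iterative (exact).**  Integer count of generations with q < q_k.  A
  non-increasing or stalled trajectory returns a distinguished infinite
  value (`NEVER`) — refuge above the protective threshold is a desired
  regime, not an error.  Closed forms return reals; comparisons never
  round.
* **Idealized closed form** (ε = 0, no cost, complete resistance,
  V_SS = 0): T = [(1−ω)/ω]·[1/y₀ − 1/y_k + ln(y_k/y₀)].
* **ε > 0 closed form** (no cost, complete resistance): exact
  partial-fractions integral of dy/dt = [ω/(1−ω)]·y·(y+ε)/(1+y),
  giving T = [(1−ω)/ω]·(1/ε)·[ln(y_k/y₀) + (ε−1)·ln((ε+y_k)/(ε+y₀))].
  It is continuous with the idealized form as ε → 0 (verified at
  ε = 10⁻⁸) and ε below 10⁻¹² delegates to it.  The integral is kept as
  a single expression; no separate small-α correction term is exposed,
  since the exact integral already contains it.
* **General closed form** (rare-allele limit, reference normalization):
  T\* = (1−ω)·ln(y_k/y₀) / [ω·ε·V_RR − (1−ω)·χ·(1−U_RR)].  The
  bracketed denominator is the rare-allele pace ξ; freezing the pace at
  its slowest (rare-allele) value makes T\* an upper bound on the
  continuous passage time.

### Validity domains (measured against the exact iterate)

All continuous forms share a systematic bias: a discrete generation
multiplies y by (1 + Λ), not e^Λ, so the iterate needs roughly
½·ln(y_k/y₀) more generations than the ODE solution (≈ 3.5 generations
for q₀ = 10⁻⁴ → q_k = 0.1).  Hence:

* the idealized form is within 2% of the iterate whenever y₀ < 0.01
  (passage times are then thousands of generations and the bias is
  negligible);
* the ε form is within 10% of the iterate when the rare-allele pace
  ωε/(1−ω) ≤ 0.05 per generation and q₀ ≪ q_k (measured worst case ≈ 8%
  over random sweeps with ω ≤ 0.85); at pace ≳ 0.1 the bias alone
  exceeds 10% — e.g. for ω = 0.8, ε ≈ 0.05 the closed form gives 29.8
  generations while the exact recursion needs 34;
* the upper-bound property of T\* holds against the *continuous*
  dynamics always, and against the iterate whenever the pace is ≤ 0.08
  per generation; at higher paces the discretization penalty can
  overtake T\*'s margin.  The property tests assert these statements on
  their measured domains.

## Refuge solvers

The protective threshold (1 − Ω) = ε·V_RR/(ε·V_RR + χ·(1−U_RR)) is
closed-form; its sign behaviour is verified by evaluating the odds
growth rate at q = 10⁻⁸ just above and below the threshold.  The
minimal refuge for a target passage time is found by bisection on the
refuge fraction over [10⁻⁶, 1 − 10⁻⁶] to 10⁻⁶ absolute tolerance —
passage time is monotone in refuge, so bisection is robust for both the
closed forms and the integer-valued iterate (where the answer lands on
a step of the staircase).  Within the admissible fitness tables
(U_SS ≥ U_RR, V_RR ≥ V_SS) any positive target becomes reachable as
refuge → 1, so the unreachable branch is defensive only.

## Monitoring estimators

ξ\* = ln(y_j/y₀)/T^j converts two frequency surveys into a
per-generation pace on the log-odds scale; T^k\* = ln(y_k/y₀)/ξ\*
projects it to the critical frequency.  Design choices:

* **Censoring.**  A frequency reported only as exceeding a bound
  (">0.1") yields a lower bound on ξ\* (computed at the bound, using a
  bounded elapsed time "<N" at N) and no passage projection; an
  observed q_j already at or above q_k likewise yields no projection.
  A missing q₀ is replaced by 0.001 and flagged `q0_assumed` — the
  conventional detectability ceiling.
* **Calendar years** use the midpoint of the generations-per-year range
  (4–5 → 4.5, 3–5 → 4), which reproduces the published year figures.
* **Accuracy.**  Round-trip tests (simulate → sample → project) show
  T^k\* is an upper bound, recovering the exact passage time within 15%
  when the survey window covers ≳ 60% of the eventual passage time and
  the passage time is in the estimator's useful range (≲ 100
  generations, where the pace is roughly constant on the log-odds
  scale).  Early observations of slow, strongly-curved trajectories
  (large cost, long T) overestimate by more.
* Two ξ\* cells of the packaged survey table (the Chinese cotton
  bollworm and *H. punctigera* rows) cannot be reproduced from their own
  printed survey values by the estimator (direct evaluation gives
  ≈ 0.073 and ≈ 0.079 instead of the published 0.069 and 0.093,
  presumably from different elapsed-generation bookkeeping); the
  packaged golden report records the recomputed values.  The South
  African maize stalk borer worked example uses 14 elapsed generations
  (the monitoring interval 1998–2004), while the survey table's
  censored row bounds it by 16; both are exposed.

## Numerical conventions

* Fixation handling: q′ is clamped to [10⁻³⁰⁰, 1 − 10⁻¹²] and the
  trajectory terminates with reason `fixation_floor`, keeping
  y = q/(1−q) finite.
* Zero mean fitness raises an explicit extinction error; zero
  susceptible allelic fitness makes the odds growth rate +∞ (reported,
  not raised).
* Sweeps evaluate cells independently and record per-cell errors
  in-row; reports render +∞ as `Inf`, missing values as `NA`, floats at
  6 significant digits (TSV) or full precision (JSON), and carry a
  version + config-hash + timestamp header for provenance.

## Synthetic data and what the tests show

The package needs no empirical input beyond the packaged survey table
(printed frequencies and elapsed generations from published monitoring
compilations).  All trajectories used in tests are generated by the
model itself, so the round-trip results validate the *internal*
consistency of the estimators under deterministic, unstructured-
landscape dynamics — they do not test robustness to sampling noise in
allele-frequency estimates, spatial structure, or demographic
fluctuations, none of which the model represents.
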
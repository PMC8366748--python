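# Methods

## Allocation rules

All procedures target 1:1 allocation of n subjects to an experimental arm
E and a control arm C. Writing D(i) = N_E(i) − N_C(i) for the imbalance
after i assignments, the conditional probability φ of assigning E next is:

| design | rule |
|---|---|
| CRD | φ = 1/2 always |
| Rand | φ = (n/2 − N_E(i)) / (n − i); equivalent to a uniform draw from the (n choose n/2) balanced sequences |
| TBD | φ = 1/2 while both arms are below the quota n/2; 0 or 1 once a quota fills |
| PBD(2b) | the Rand rule restarted within each consecutive block of 2b |
| BSD(b) | φ = 1/2 while \|D\| < b; the assignment is forced toward balance at \|D\| = b |
| BCD(p) | φ = 1/2 at D = 0, otherwise p toward the under-represented arm (p ∈ (1/2, 1]) |
| BCDWIT(p, b) | the BCD(p) rule with a forced assignment at \|D\| = b |
| ABCD(a) | φ = 1/2 at D = 0; 1/(1 + Dᵃ) for D ≥ 1; symmetric for D ≤ −1 |
| GBCD(γ) | φ = N_C(i)^γ / (N_E(i)^γ + N_C(i)^γ), with φ = 1/2 at i = 0 |

Notes on the choices that the literature leaves open:

- The ABCD family admits several decreasing bias functions; the form above
  is one member (F(x) = 1/(1 + xᵃ)) and other members would shift its
  per-step numbers slightly, so no published ABCD-specific value is
  asserted in the tests.
- The GBCD rule is the Smith-type adaptive coin on the group counts. It
  reproduces the known asymptotic expected loss 1/(2γ + 1) (checked by
  simulation at n = 2,000 for γ = 1, 2, 5).
- For every supported rule φ depends on the history only through (i, D):
  the block position is i mod 2b, and the group counts are recovered as
  N_E = (i + D)/2. This is what makes the exact computations below
  possible, and it implies the E↔C relabeling symmetry φ(D) = 1 − φ(−D),
  which is property-tested.

## Exact engine

Two exact computations complement Monte Carlo:

- **Reference-set enumeration** (n ≤ 16): depth-first search over the
  assignment tree, pruning zero-probability branches; each feasible
  sequence appears once with probability equal to the product of its
  conditional assignment probabilities. Probabilities are validated to
  sum to 1 within 1e−12.
- **Forward dynamic programming** over the distribution of D(i) on the
  lattice {−i, −i+2, …, i}: yields per-step E|D(i)|, expected loss
  E[L_i] = E[D(i)²]/i, E|φᵢ − ½| (the forcing-index increment), the
  probability of a deterministic assignment, and the correct-guess
  probability under either guessing strategy.

Long-run predictability uses the stationary distribution of the imbalance
walk, solved from πP = π (the chain has period 2; π is the time-average).
For MTI designs the walk lives on |D| ≤ b and puts mass 1/(2b) on the
boundary; for the unbounded biased-coin rules the state space is truncated
at |D| = 400, where the geometric tail is negligible. For PBD the limit is
the exact average over one block. A second route — averaging the exact
per-step values over 10,000 steps — agrees with the stationary route to
better than 5e−4 and is kept as a cross-check in the tests. CRD is
special-cased to (0, 0): it is never deterministic and guesses stay at
chance.

Guessing strategies: *convergence* guesses the currently under-represented
arm (random at a tie); *optimal* guesses the arm with φ > 1/2 (random at
φ = 1/2), giving correct-guess probability max(φ, 1 − φ). The two coincide
for PBD and BSD; published predictability tables are computed under
optimal, the selection-bias outcome model under convergence, and both are
exposed through a strategy flag.

## Metrics

Per-step summaries follow the standard balance/randomness formulation:
loss L_i = |D(i)|²/i (so that the variance of the efficient
treatment-difference estimator is V = 4σ²/(n − L_n)); cumulative average
loss Imb(i); forcing index FI(i) = Σⱼ≤ᵢ E|φⱼ − ½| / (i/4) (0 for CRD, 1
for PBD(2)); proportion of correct guesses PCG(i) ∈ [0.5, 0.75]; tradeoff
distance d(i) = √(Imb(i)² + FI(i)²), used to rank designs. Monte Carlo
estimates take the forcing-index increments from the realized φ paths, so
designs whose increments are non-random (CRD, PBD(2)) produce FI exactly;
all estimates carry Monte Carlo standard errors and are cross-checked
against the exact engine (within 3 SE at 10,000 replicates, all twelve
designs, in the acceptance suite).

A caveat the ranking inherits from the underlying study design: the exact
d(50) values of CRD (1.000) and PBD(2) (1.0013) differ by less than the
Monte Carlo error at 10,000 replicates, so which of the two ranks last is
not reproducible — the tests pin BSD(3) first and {CRD, PBD(2)} as the
bottom pair without fixing their mutual order.

## Outcome models

Continuous outcomes: Y_i = δᵢ μ_E + (1 − δᵢ) μ_C + u_i + ε_i with

- M1: u ≡ 0, ε ~ N(0, σ²) — the reference model;
- M2: u_i = trend · i/(n + 1) (default trend 5), normal errors — a linear
  enrollment-time drift;
- M3: u ≡ 0, ε ~ Cauchy(0, 1) — misspecified error distribution;
- M4: u_{i+1} = −ν · sign(D(i)), D(0) = 0, normal errors (default
  ν = 0.5, the sweep exposes 0–1) — an investigator guessing by
  convergence enrolls a healthier patient when E is the likely next
  assignment. With ν = 0 the model is bitwise identical to M1 under the
  same generator state.

Alternative-hypothesis effect sizes are defined operationally: Δ/σ is
solved from the noncentral-t power function to give 70/80/90% analytic
power at the trial size (0.717/0.809/0.936 at n = 50), matching how the
scenarios are described rather than guessing unpublished values.

Survival: T_i ~ Exponential(rate = h_c · exp(δᵢ log HR + u_i)), no
censoring. The covariate generator emulates a strong decreasing enrollment
trend in log serum bilirubin: a linear mean from 4.5 down to 1.0 over 248
subjects plus N(0, 0.7²) noise. These values were fixed once so that the
time-ignorant analyses show the documented qualitative pattern (an
unadjusted population-model test is anticonservative under TBD, ~2%
conservative under PBD/BSD/GBCD, and valid under CRD/Rand; TBD has ~25%
probability of a significant baseline covariate imbalance). What a linear
trend with independent noise cannot emulate is meso-scale autocorrelation
(plateaus, recruitment-policy shifts) present in real enrollment streams;
consequently power differences *within* the locally-balancing design class
(PBD(2) vs PBD(4) vs BSD(3)) are second-order here and should not be read
off these simulations, while differences *between* classes (TBD vs
final-balance-only vs locally-balancing) are large and robust.

## Inference

- Pooled t-test with n − 2 degrees of freedom; linear rank statistic
  S = Σ δᵢ(aᵢ − ā) with mid-ranks for ties.
- Monte Carlo randomization tests: P̂ = (1/L) Σ 1{|S_ℓ| ≥ |S_obs|} over L
  fresh sequences from the design, responses fixed; significance at
  P̂ < α. The plain proportion is the default (matching the definition
  being reproduced); a conservative (1 + count)/(1 + L) variant is
  available. Re-randomized sequences with an empty arm (possible under
  CRD at small n) are redrawn and counted for the mean-difference
  statistic; the rank statistic is always defined. Statistic comparisons
  use a 1e−12 relative tie tolerance so exact ties are counted as "at
  least as extreme".
- Exact randomization p-values sum reference-set probabilities of
  sequences at least as extreme in favor of E; for binary outcomes the
  statistic is the difference in success proportions, which for
  4:4-balanced reference sets is equivalent to the count of successes on
  E. Under the random allocation rule this reproduces the one-sided
  Fisher exact p-value for every binary outcome configuration
  (permutation-test equivalence; verified exhaustively at n = 8).
- Survival: per-dataset Cox fits (Breslow ties) through lifelines with a
  Wald test for the treatment coefficient. The experiment grids fit tens
  of thousands of Cox models, so they use an in-package Newton solver for
  the partial likelihood vectorized across replicates; it is validated
  against lifelines to 4 decimals. Randomization-based survival tests use
  linear score statistics S = Σ δᵢ mᵢ with martingale residuals m from
  the null model (the logrank score; unadjusted analysis) or from the
  covariate-only Cox fit with its Breslow baseline (adjusted analysis) —
  the standard score-form randomization test, chosen because refitting
  the full model for each of L re-randomizations is computationally
  prohibitive. Under the null the responses are independent of the
  assignments, so these tests are exact up to Monte Carlo error for any
  statistic.

## Monte Carlo engineering and problem sizes

Sequence generation, the t-test, the Cox fits and all re-randomization
tests are vectorized across replicates. Re-randomization banks of L
sequences are shared within blocks of ~20–40 replicates and refreshed
between blocks: each replicate's p-value remains a valid Monte Carlo
randomization p-value, and the block size was chosen so that the observed
seed-to-seed spread of rejection-rate estimates matches the binomial
standard error. Default experiment sizes are 2,000 simulated trials with
L = 1,000 re-randomizations (binomial SE ≈ 0.5 points at the 5% level);
`--paper-scale` restores 10,000/10,000. The metric ranking uses 10,000
replicates. All runners derive every stream from a single master seed via
spawned child sequences, so identical seeds give bitwise-identical CSVs.

## Known limitations

- Multi-arm trials, unequal allocation, covariate-adaptive and
  response-adaptive randomization, stratified schemes, censoring, and
  non-exponential baseline hazards are out of scope.
- Reference-set enumeration is capped at n = 16.
- The maximal procedure and other non-Markovian rules are not supported:
  the exact engine requires the (i, D) sufficiency that all twelve
  implemented designs share.
- The synthetic bilirubin covariate reproduces the *class-level*
  consequences of a hidden time trend, not the patient-level covariate of
  any historical trial; numeric power values in the survival study are
  properties of this generator, not of the original data.
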
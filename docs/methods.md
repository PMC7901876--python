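# Methods

## The problem

Cognitive diagnostic assessment infers, from an examinee's binary item
responses, which of K binary skills ("attributes") they have mastered.
The latent state is one of T = 2^K attribute patterns, so scoring is a
T-class classification problem, and the quality of the classification is
bounded by how well the administered items separate the latent classes.
This package addresses *test assembly*: choosing J items from a calibrated
bank of M items so the assembled test separates the classes as well as
possible.

## Response models

Three standard conjunctive/disjunctive cognitive diagnostic models supply
the class-conditional correct-response probability P_j(α):

* **DINA** — with η = 1 iff α masters every attribute item j measures
  (Q-matrix row q_j), P_j(α) = (1 − s_j)^η g_j^(1−η). s_j is the slip and
  g_j the guess probability.
* **DINO** — identical form with the disjunctive ideal response ϖ = 1 iff
  α masters at least one measured attribute.
* **R-RUM** — P_j(α) = π*_j Π_k r*_jk^{(1−α_k) q_jk}: a baseline success
  probability π*_j for fully-mastered examinees, multiplied by a penalty
  r*_jk ∈ (0,1) for each measured attribute the examinee lacks.

All computed probabilities are clamped to [1e−12, 1 − 1e−12] before any
logarithm. Under the generating ranges used here the clamp is never
active; it exists so user-supplied parameter files cannot produce −inf
log-likelihoods.

Latent classes are ordered by the base-2 value of the pattern with
attribute 1 as the most significant bit ((0,0), (0,1), (1,0), (1,1) for
K = 2). The ordering is arbitrary but must be fixed: class-pair row
indices, file round-trips and tie-breaking all depend on it.

## Class separation and the maximin program

Item j separates classes u and v according to the Kullback–Leibler
divergence between its two Bernoulli response distributions,

D(u, v, j) = P_j(α_u) log[P_j(α_u)/P_j(α_v)] + (1 − P_j(α_u)) log[(1 − P_j(α_u))/(1 − P_j(α_v))],

which is nonnegative, zero iff the probabilities coincide, and asymmetric
(both directions of every pair are therefore kept). Natural logarithms are
used; the base only rescales every coefficient of the assembly program
jointly and cannot change which selection is optimal, but fixing it makes
distance values reproducible. Stacking the off-diagonal entries of every
item's T × T distance matrix (row-major, u outer, v inner) gives the
pair-by-item matrix V with R = T(T−1) rows (FULL mode).

The maximin assembler solves

    minimize    f1·x + f2·y
    subject to  V x + y ≥ b,  Σ_j x_j = J,  x ∈ {0,1}^M,  y ∈ R

with f1_j = −mean(V[:, j]) (so minimizing f1·x maximizes the test's total
class separation), f2 = J·mean(V) > 0, and b_t = J·mean(V[t, :]) the
bank-average target separation for pair t. At any fixed x the optimal
slack is y = max_t (b_t − V_t·x); because f2 > 0, minimizing f2·y pushes
up the *smallest* inter-class distance of the selected test, while f1·x
simultaneously rewards the mean. y may be negative when every pair already
exceeds its target.

**Simplified pair set.** The hardest classes to distinguish are those
differing in a single attribute, and each pattern has exactly K such
neighbours. SIMPLIFIED mode keeps only the T·K ordered Hamming-distance-1
pairs (24 rows for K = 3; 64 instead of 240 for K = 4; 2048 instead of
65,280 for K = 8). The coefficient formulas above are means over V's rows;
with the simplified V they are taken over its T·K rows, which is the only
reading that keeps the program identically scaled. FULL mode with K > 6
requires an explicit opt-in flag because of the row count.

## Solver

The program is a mixed 0–1 linear program solved by HiGHS branch-and-bound
(through `scipy.optimize.milp`). `solve_mmd` defaults to proven optimality
(zero relative gap); on toy banks this is instant and is verified against
exhaustive subset enumeration to 1e−9. At bank scale (M = 300) the
*incumbent* selection stabilizes within a couple of seconds while proving
optimality can take minutes — in our profiling the incumbent found at 2 s
differed from the proven optimum by ~1e−7 in objective after a further
7 minutes of bound-closing. The Monte-Carlo harness therefore runs each
solve with a per-solve budget (`milp_time_limit`, default 3 s; 10 s for
the K = 8 configuration, whose program has 2048 rows) and uses the
incumbent, reporting TIME_LIMIT status. Per-replication accuracy
differences between 2 s and 30 s budgets were ≤ 0.004 with no systematic
direction. The reported slack is always recomputed from the returned
selection as y = max_t (b_t − V_t·x).

Among equally optimal selections any optimum is accepted; tests compare
objective values, never selection identity.

## Baselines

**CDI-greedy.** The cognitive diagnostic index summarizes an item's
separation power in one number: the inverse-Hamming-weighted mean of its
pairwise KL distances,

    CDI_j = [Σ_{u≠v} h(u,v)^{-1} D(u,v,j)] / [Σ_{u≠v} h(u,v)^{-1}],

so near-identical patterns (small Hamming distance h) carry the largest
weight. Greedy assembly takes the J largest-CDI items, with ties broken to
the smallest item index.

**Random.** A uniform J-subset of the bank.

## Blueprint constraints

Three constraint modes apply to all assemblers:

* **NC** — none beyond the test length.
* **IC** — item-count quotas by number of measured attributes; the K = 4,
  J = 20 default is {1: 4, 2: 7, 3: 9} (4 single-attribute, 7
  two-attribute, 9 three-attribute items). For other K no canonical quota
  exists and `ic_counts` must be supplied explicitly.
* **AC** — every attribute must be measured by at least `ac_min` selected
  items (default 7, the K = 4/J = 20 convention; configurable).

In the MILP these are linear rows. In CDI-greedy, IC fills each stratum
with its top-CDI items; AC adds a feasibility guard that restricts the
greedy pool to deficit-covering items once an attribute's remaining
coverage deficit equals the remaining open slots (the guard is our design
— how the original greedy handled coverage was never specified). Random
assembly satisfies IC by stratified uniform sampling and AC by rejection
sampling (capped at 10,000 draws) followed by greedy swap repair.

## Simulation design

The generator reproduces the published study conditions:

* **Bank**: M = 300 items; each Q row is the binary expansion of a uniform
  integer on [1, 2^K − 1] (every nonzero attribute profile equally likely,
  no empty rows). DINA/DINO: s_j, g_j ~ U(0.05, 0.4) independently. R-RUM:
  π*_j ~ U(0.75, 0.95), r*_jk ~ U(0.2, 0.95) on measured attributes.
* **Examinees**: latent traits ~ MVN(0, Σ) with unit variances and common
  correlation ρ ∈ {0, 0.5}; attribute k is mastered iff the latent value
  is ≥ 0 (the tie at exactly 0 maps to mastery, matching the ≥ convention;
  it has probability zero). ρ = 0 makes all 2^K patterns equally likely.
  Two independent groups of N examinees are drawn per replication: one
  supplies the empirical prior, the other is classified.
* **Responses**: X_ij = 1 iff an independent U(0, 1) draw is ≤ P_j(α_i).
* **Scoring**: MAP over latent classes — argmax of log prior plus Bernoulli
  log-likelihood of the observed responses on the assembled test. Classes
  with zero empirical prior are excluded from the search (faithful to the
  empirical-prior design); a `prior_floor` option can mix in a uniform
  floor for settings (K = 8, ρ = 0.5) where some of the 256 classes may be
  unobserved at moderate N. Ties break to the smallest class index.
* **Metrics**: ACR (proportion of correctly classified attribute entries)
  and PCR (proportion of exactly recovered patterns); PCR ≤ ACR always.
  A product rule (`expected_pcr_independent`) converts per-attribute rates
  into the pattern rate implied by independence.

Within a replication, every method and constraint mode shares the same
bank and the same examinee groups, so method comparisons (mean differences
and per-replication "outperform" proportions) are paired. Each replication
regenerates the bank and both groups. Child seeds are spawned from the
master seed with `numpy.random.SeedSequence`, so any replication is
re-runnable in isolation.

The simplification check compares FULL-mode and SIMPLIFIED-mode maximin
accuracy by balanced one-way ANOVA: S_A the between-group and S_E the
within-group sum of squares, F = S_A / (S_E / (2n − 2)) on (1, 2n − 2)
degrees of freedom with the exact F upper tail as p-value, significance
level 0.05.

## Problem sizes

Desk-scale defaults (chosen once as this package's standard conditions)
are 50 replications of N = 2000 examinees per group — the full published
design used 200 replications of N = 10000 — with bank size, test length
and parameter distributions unchanged. `desk_study_configs` bundles the
four headline unconstrained conditions (DINA/DINO/R-RUM at K = 4,
DINA at K = 8 with 30 replications). Per-replication Monte-Carlo noise in
ACR/PCR is a few thousandths at N = 2000, so 30–50 replications pin means
to ~±0.01.

## What the generator does not emulate

Item parameters are treated as known; calibration error from estimating a
real bank (finite calibration samples, model misfit, Q-matrix
misspecification) is outside scope. Attributes have no hierarchical
structure, items are conditionally independent given the latent class, and
examinees are exchangeable. Passing tests show the assembly methods rank
as published *under the generating model*; they do not certify behavior on
real response data.

## Known limitations

* FULL-mode assembly at K = 8 (65,280 rows) is legal with the override
  flag but slow; the simplified set is the intended path for large K.
* The maximin MILP's LP relaxation is weak (the free slack lets fractional
  selections look better than any integral one), so *proving* optimality
  at bank scale is much slower than *finding* the optimum; the time-limit
  incumbent is the practical default, and proven-optimal solves remain
  available with `milp_time_limit=None`.
* IC-mode quotas for K ≠ 4 and AC minima for other (K, J) have no
  canonical values and must be chosen by the user.
* Time-limited MILP solves are wall-clock bounded, so the incumbent can
  depend on machine speed and load; fixed seeds make every *other* source
  of randomness bit-reproducible, and `milp_time_limit=None` restores full
  determinism at the cost of proving optimality. Summary accuracies move
  by at most a few thousandths between incumbents.
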
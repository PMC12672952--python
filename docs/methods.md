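# Methods

## The measurement model

Visual-analogue-scale (slider) responses are scored as the proportion of the
distance between the two anchors, giving bounded continuous data on (0, 1).
`vascareless` models an attentive response of person *i* to item *j* as
Beta-distributed with "acceptance" and "refusal" shape parameters

    a_ij = exp[(s_j θ_{i,d(j)} − b_j + α_j) / 2]
    b_ij = exp[−(s_j θ_{i,d(j)} − b_j − α_j) / 2]

where θ is the latent trait (one entry per dimension, simple structure via
the item-to-dimension map d(j)), s_j ∈ {−1, +1} is the pre-specified wording
sign, b_j the item difficulty and α_j the item dispersion.  Two properties
pin this parameterization down: the expected response a/(a+b) is exactly
logistic(s_j θ − b_j), so the dispersion never moves the mean; and α_j shifts
only the total concentration a+b, so larger α means smaller conditional
variance µ(1−µ)/(a+b+1).  At θ = b = α = 0 the model reduces to the uniform
Beta(1, 1).

Item information is computed numerically: Gauss–Legendre quadrature (201
nodes on (0, 1)) of the negative second derivative of the log density, the
derivative taken by central differences in θ with step 1e−4.  Both constants
are arguments of `item_information`.  No closed form is used.

## The careless mixture

Careless respondents answer without processing item content, so their
responses carry no information about θ or the item.  They are modeled by a
single unstructured Beta(m, n) shared by all persons and items — a residual
class meant to absorb the *marginal* distribution of whatever careless
behaviors are present, not to describe any one of them.  Each response cell
is a two-component mixture with a person-level weight:

    f(y_ij) = π_i · Beta(y_ij; a_ij, b_ij) + (1 − π_i) · Beta(y_ij; m, n)

π_i is person *i*'s probability of attentiveness; the class indicator is
marginalized out (never sampled), which keeps the posterior amenable to any
sampler.  A hierarchical Dirichlet prior ties individuals to the population:
(π_i, 1−π_i) ~ Dirichlet(ω·(π, 1−π)), which collapses to
π_i ~ Beta(ωπ, ω(1−π)).  π is the population attentive proportion (flat
Dirichlet(1,1) prior) and ω a concentration (half-Cauchy(0, 5)) governing
how tightly individuals cluster around π.

Remaining priors: N(0, 10) on each b_j and α_j; half-Cauchy(0, 5) on each
trait SD and on m and n; LKJ(1) on the trait correlation matrix when the
model has more than one dimension (unidimensional fits skip the correlation
block entirely).  Trait means are fixed at zero for identification; the
trait scale is identified by the unit coefficient on θ.  All scales are
configurable through `PriorConfig`; the defaults are the diffuse choices
above.

### Why the simple 0.5 threshold fails at low contamination

When careless respondents are rare, the posterior for π sits near 1 and the
hierarchical prior pulls every π_i toward it.  A careless person's π_i is
then a compromise between ten cells of likelihood evidence and a prior
concentrated near attentiveness, and can land above 0.5 — the threshold rule
quietly stops flagging anyone.  The ranking rule (flag the
k = round(N(1−π̂)) least attentive) stays calibrated because it uses the
estimated prevalence rather than an absolute cutoff; it is the recommended
rule at low contamination.

## Estimation

Posterior computation is adaptive random-walk Metropolis-within-Gibbs,
written directly in NumPy.  The blocking exploits conditional independence:
given items and the careless component, person blocks (θ_i rows, π_i) are
independent across persons and are proposed, evaluated, and accepted in one
vectorized pass; given the traits, the per-item (b_j, α_j) blocks factorize
over columns the same way.  Scalar blocks handle (m, n) jointly, the trait
SDs, π, and ω — π and ω deliberately separately, because their conditional
posteriors have very different widths and a shared proposal scale would
throttle ω's mixing.  Proposal scales adapt in windows of 50 sweeps toward
acceptance rates of 0.44 (scalar blocks) or 0.30 (small vector blocks)
during burn-in only, so the retained draws come from a fixed-kernel chain.
Initialization is near the attentive-dominant regime (π_i ≈ 0.9, π ≈ 0.8,
m = n ≈ 1, ω ≈ 2, items near prior means, traits near 0), jittered per
chain.

In multidimensional fits the trait correlation matrix is sampled through
atanh canonical partial correlations (C-vine order).  The level-j partial
correlation receives an independent shifted-Beta prior with shape
η + (D−1−j)/2, which is exactly equivalent to LKJ(η) on the full matrix and
removes any Jacobian bookkeeping from the Metropolis step.

Defaults mirror the reference protocol — 2 chains × 40,000 iterations, first
half burn-in — but every fitting entry point takes an `McmcSpec`, and the
replication harness and acceptance script run 2 × 4,000 with thinning 2,
which the classification and recovery results below were measured at.  All
randomness flows from a single integer seed through `numpy.random.SeedSequence`
spawns, so identical (data, spec) runs are bit-identical.

Convergence is judged by the Gelman–Rubin estimated potential scale
reduction (EPSR) per parameter, all values < 1.1.  Strictly positive
parameters (trait SDs, m, n, ω) are transformed to the log scale first: ω in
particular inherits a heavy right tail from its half-Cauchy prior, and the
raw-scale statistic compares what can be effectively infinite-variance
estimands, so it never stabilizes even for well-mixed chains.  A split-chain
variant is available (`epsr(draws, split=True)`).  Non-convergence is never
an exception — it is flagged in `PosteriorResult.converged`, and the
replication harness reports the convergence rate per cell while aggregating
over converged replications only (falling back, flagged, to all replications
in cells where none converge at desk scale).

## The synthetic-data generator

`generate_dataset` reproduces the validation design: N = 300 persons,
10 items with the first 5 reverse-keyed, b_j ~ N(0,1), α_j ~ U[0,3],
θ_i ~ N(0,1) (unidimensional — deliberately the hard case for detection,
since multidimensional structure makes careless patterns stand out more),
and a fixed count round(N·π_c) of careless persons drawn without
replacement, π_c on the grid {0.05, 0.10, 0.15, 0.25, 0.40}.  Careless rows
follow one of three patterns:

* `beta_extremes` — i.i.d. Beta(0.5, 0.5), values piling at both ends;
* `end_preference` — each person is assigned a side once (probability 1/2)
  and all of that person's responses are U(0, 0.2) or U(0.8, 1); the side is
  a person attribute, so rows are internally coherent;
* `midpoint_normal` — Normal(0.5, 0.25) truncated to (0, 1).

Only the first pattern is itself a Beta; the other two can only be
approximated by the careless component, which is the point of including
them.  The careless count is fixed rather than Bernoulli so classification
metrics have a deterministic denominator per dataset.  All generated values
are clamped to [1e−3, 1−1e−3] so that Beta log densities (including shapes
below 1) stay finite; the same clamp is applied when reading stored
responses, which slider software exports on the closed interval.

What the generator does *not* emulate: real respondents mixing behaviors
within a row, item-level attentiveness lapses, response-time information,
multidimensional content structure, or missingness mechanisms.  Passing
recovery tests therefore demonstrate internal consistency of model and
sampler under the stated design, not robustness to everything field data
can do.

## Classification and scoring

Two rules convert posterior mean π_i into labels: careless iff π_i < 0.5
(ties labeled attentive, since careless is defined by *strictly* lower
attentiveness probability), or flag the k = round(N(1−π̂)) persons with the
smallest π_i, ties broken by ascending person index, with π̂ the posterior
mean of π and rounding half away from zero.

The five metrics treat **attentive as the positive class**: sensitivity is
the fraction of truly attentive respondents kept, precision the fraction of
kept respondents who are truly attentive, FPR the fraction of truly careless
respondents who slip through as attentive, FNR the fraction of attentive
respondents wrongly flagged (so FNR = 1 − sensitivity by construction).
These orientations are unusual but intentional; undefined ratios (zero
denominators) are reported as missing, never as zero.

## The mis-specified baseline

For comparison, a one-factor normal mixture CFA replaces both mixture
components with normals: attentive cells N(ν_j + λ_j θ_i, σ_j), careless
cells N(µ_c, σ_c), identical attentiveness hierarchy.  Loading signs are
fixed by item wording (|λ_j| gets a half-normal(0, 10) prior) and the trait
is standardized, with loadings free — a standard CFA identification choice,
made here as an assumption since the comparison protocol leaves it open.
µ_c gets N(0, 10) to match the diffuse intent.  On bounded, skewed slider
data its normality assumptions fail, and the head-to-head comparison in the
harness quantifies how much of the Beta mixture's detection ability comes
from modeling the bounded response distribution itself.

## Numerical choices and limitations

* All density arithmetic is in log space (log-gamma for Beta normalizing
  constants, log-sum-exp for mixtures); shapes below 1 near the boundary
  clamp stay finite by construction.
* The boundary clamp (1e−3) is a documented constant shared by generator
  and readers; responses exactly at 0/1 are squeezed in and counted, not
  rejected.
* `classify_proportion` uses stable argsort, making the index tie-break
  reproducible.
* Replication seeds derive from (base seed, pattern, proportion, replication
  index) through `SeedSequence`, giving independent, reproducible streams
  below 2^31.
* Desk-scale runs (2 × 4,000 iterations) leave some replications past the
  EPSR gate, especially under end-preference contamination where the
  careless component is badly mis-specified; convergence rates are reported
  per cell and improve with iterations, matching the reference protocol's
  own experience of needing up to 100,000 burn-in iterations in the hardest
  cell.
* Known limitation: at very low contamination the estimated concentration ω
  settles small, individual π_i separate strongly, and the threshold rule's
  false-pass rate measured here is lower than the reference results report
  for Beta-pattern contamination; the ranking rule's metrics, the
  careless-shape recovery, and the factor-score comparison reproduce well.
  See the repository's acceptance output for the measured values.
* A single careless class is fitted; multiple empirically determined
  careless classes, item-level attentiveness, response times, and
  longitudinal dynamics are out of scope.
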
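# Methods

## Setting and hypothesis family

A trial compares treatments A, B and their combination AB against a
shared control on a normally distributed endpoint with known standard
deviation σ. The one-sided family is H0j: μ_j ≤ μ0 for j ∈ {A, B, AB},
tested with a common critical value k so that the familywise error rate —
the probability of rejecting any true null — equals α. Allocation is
summarised by r (each single-treatment group as a multiple of the control
group) and q (the combination group as a multiple of control). Tests are
z-tests throughout: σ is treated as known, which is the standard planning
approximation and keeps every operating characteristic an exact
multivariate-normal probability.

## Factorial statistics and their joint law

Under additivity, each single-treatment effect has two independent
estimates: the own-arm contrast (Ȳ_A − Ȳ_0) and the combination contrast
(Ȳ_AB − Ȳ_B). The factorial statistic combines them with
inverse-variance (information) weights w₁ = n₀r/(1+r) and
w₂ = n₀rq/(r+q):

    Z_A = [w₁(Ȳ_A − Ȳ_0) + w₂(Ȳ_AB − Ȳ_B)] / (σ √(w₁+w₂)),

symmetrically for Z_B, while the combination hypothesis is tested on its
own arm and control only: Z_AB = (Ȳ_AB − Ȳ_0) √(n₀q/(1+q)) / σ. These are
the maximum-likelihood contrasts of the additive (no-interaction) linear
model for the single arms, and of the full model for the combination.

The three statistics are jointly trivariate normal with unit variances,

    corr(Z_A, Z_B)  = [r(r+q)² + qr(1+r)² − 2q(1+r)(r+q)]
                      / [(1+r)(r+q)(r+2q+rq)],
    corr(Z_A, Z_AB) = corr(Z_B, Z_AB)
                    = (1+2r+q) √( rq / [(1+r)(1+q)(r+q)(r+2q+rq)] ).

Two geometric facts the tests exercise: corr(Z_A, Z_B) = 0 exactly on the
curve q = r², where corr(Z_A, Z_AB) = √(r/(1+r²)) is maximised at r = 1
with value 1/√2; and at r = q = 1 the law is *singular* —
Z_A + Z_B = √2·Z_AB almost surely — so the covariance is positive
semidefinite, not definite, and the code treats it as such.

The multi-arm (Dunnett) design replaces these with the many-to-one law:
Z′_j = (Ȳ_j − Ȳ_0)/(σ√((n₀+n_j)/(n₀n_j))), correlations r/(1+r) between
single arms and √(rq/((1+r)(1+q))) to the combination arm. Z′_AB is the
same statistic in both designs.

Under an alternative the correlation matrix is unchanged and the mean
vector is the statistic's formula evaluated at the group means. Power is
disjunctive: 1 − P(all three statistics ≤ k) under the alternative law.

## Numerical evaluation

Bivariate normal CDFs use Owen's T function (scipy.special.owens_t) with
the usual zero-argument and |ρ| → 1 special cases. The trivariate CDF
conditions on the first coordinate and integrates the conditional
bivariate CDF against the standard normal density with a 96-point
Gauss–Legendre rule on [−8.5, b₁]; when the conditional correlation
degenerates to ±1 (the singular balanced law) the integrand is piecewise
smooth and the rule is applied on each side of the kink. Absolute accuracy
is well below 1e−6, comfortably inside the 3-decimal precision at which
critical values are reported; determinism was preferred over scipy's
quasi-Monte-Carlo integrator so that solved boundaries never wobble in
the last digit. Critical values are found with Brent's method bracketed
by the single-test bound Φ⁻¹(1−α) and the Bonferroni bound Φ⁻¹(1−α/3),
xtol 1e−8.

Sample-size searches solve power(n₀) = target on continuous n₀ (power is
strictly increasing whenever some arm is effective), then scan to the
smallest integer n₀ whose power reaches the target. The reported total is
round(n₀(1+2r+q)); per-group sizes are rounded individually. For balanced
designs this reproduces totals that are exact multiples of 4; for extreme
ratios (r ≈ 0.01) the convention can differ from alternative roundings by
one or two patients, which is why grid minima are only meaningful to ±2.

Allocation grid searches evaluate the objective at every (r, q) point in
row-major order with first-point tie-breaking. Note that the
critical-value surface is extremely flat near its optimum (≈5e−4 across
r = q ∈ [1.6, 2.1]), so argmin locations are only meaningful to the
precision of the objective; the reported optimum *values* are stable.

## Two-stage MAMS design

Three active arms and control are run in two equally sized stages with
equal allocation (r = q = 1), so the interim sits at half the maximum
sample size. At the interim, any statistic above u₁ stops the trial with
rejection (efficacy takes precedence); arms below l₁ are dropped; if all
arms are dropped the trial stops for futility. Survivors are retested on
cumulative data (stage-1 plus stage-2, against the pooled control)
against u₂. Bounds follow the O'Brien–Fleming shape u₁ = √2·u₂ with
l₁ = 0 and l₂ = u₂. The correlation between a stage-1 and a cumulative
statistic is 1/√2 (equal information increments).

Conditioning on the control arm's two standardised stage increments
(t₁, t₂) makes the arms independent, giving the FWER as a double integral
of the cubed per-arm no-rejection probability

    g₀ = Φ(√2·l₁ + t₁)
       + Φ₂(√2·u₁ + t₁, √2·u₂ + (t₁+t₂)/√2; 1/√2)
       − Φ₂(√2·l₁ + t₁, √2·u₂ + (t₁+t₂)/√2; 1/√2),

solved for the O'Brien–Fleming constant by Brent's method. Power is
defined under the least favourable configuration (μ_AB − μ0 = Δ,
μ_A − μ0 = μ_B − μ0 = δ₀) as the probability that H0AB is rejected with
the combination arm carrying the maximal statistic at the deciding stage —
the event multi-stage Dunnett design software calibrates. Conditioning
additionally on the combination arm's own path reduces it to one single
and one double integral (the rival-arm factors enter squared; the control
cancels from between-arm comparisons). Both integrals use 80-point
Gauss–Hermite quadrature. The calibrated α = 0.05 bounds are
u₁ = 2.932, u₂ = 2.073, and both the FWER and the LFC power agree with
10⁵-fold seeded simulation of the stopping rules within Monte-Carlo
error.

A useful degenerate check implemented in the tests: with u₁ unreachable
and l₁ = −∞ the two-stage power collapses to the single-stage probability
P(Z′_AB > u₂, Z′_AB ≥ Z′_A, Z′_AB ≥ Z′_B) at the cumulative sample size,
which the code reproduces to 1e−6 via an independent trivariate-normal
route. Note this is *not* the disjunctive single-stage power: the
"combination arm maximal" requirement is part of the LFC power
definition.

Expected sample size has no convenient closed form once dropping rules
interact with stopping, and is estimated by seeded vectorised simulation
(default 10⁵ replicates), reported with its standard error.

## Simulator

Patient responses follow the full interaction model
Y = β₀ + β₁I_A + β₂I_B + β₃I_AI_B + ε, ε ~ N(0, σ²), so the combination
cell mean is β₀+β₁+β₂+β₃ and β₃ < 0 is antagonistic, β₃ > 0 synergistic.
`simulate_groups` draws individual responses (σ = 0 is allowed and yields
the cell means exactly, a convenient fixture for exactness tests). The
replicated operating-characteristic estimators draw per-group sample
means from their exact sampling distribution N(μ_j, σ²/n_j) instead of
looping over patients — the sample mean is sufficient, so the two routes
are distributionally identical while 10⁵ replicates stay under a second.
Group sizes derive from (n₀, r, q) by nearest-integer rounding. All
randomness flows through a single numpy Generator seeded per call, and
seeds are recorded in every output; identical seeds give identical
estimates, and sweeps reuse one seed so comparisons ride on common random
numbers (which makes, e.g., the single-arm rejection rate exactly
monotone in β₃ draw-by-draw).

What the simulator does *not* emulate: non-normal endpoints, unknown σ
(t-statistics), covariate adjustment, attrition, or staggered accrual.
Passing tests therefore certify the designs' operating characteristics
under the idealised normal-known-σ model, not robustness to those
real-data features.

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| α | 0.05 | one-sided FWER |
| 1−β | 0.9 | target disjunctive (or LFC) power |
| r, q | 1, 1 | balanced allocation |
| Δ, δ₀, σ | 0.5, 0.1, 1 | standardised planning effects (generic scale) |
| Δ, δ₀, σ | 28, 7, 50 | case-study scale (WOMAC points); δ₀ = Δ/4 |
| nsim | 10⁴ (CLI), 10⁵ (expected N) | simulation replicates |
| grid | r: 0.1–2.5 step 0.01; q: 0.1–2 step 0.1 | allocation search |
| β₃ sweep | −Δ to Δ step Δ/4 | spans the antagonistic LFC to equal synergy |

The β₃ sweep default is expressed in response units and scaled to Δ so
that the end points correspond to the scenario where the combination is
no better than a single arm (β₃ = −Δ) and its synergistic mirror image.

## Design choices that were genuinely open

* **Power definition.** Disjunctive ("reject at least one") for the
  factorial and MA designs; per-hypothesis rates are exposed by the
  simulator. The two-stage LFC power additionally requires the effective
  arm to be maximal, matching the design-software convention that
  produces the published per-stage size of 38.
* **Stage-2 statistics** use cumulative data from surviving arms against
  the cumulative control, with dropped arms simply absent — the standard
  multi-stage Dunnett formulation; the FWER of that choice is verified by
  simulation.
* **Rounding.** Integer n₀ via smallest-integer-meeting-target;
  totals via round(n₀(1+2r+q)). Chosen because it reproduces every
  balanced published total exactly and non-balanced grid minima to ±2.
* **Efficacy precedence at the interim**: if one arm crosses u₁ while
  another sits below l₁, the trial stops with a rejection.
* **Objective grids** default to the published map resolution and break
  ties to the first point in row-major order, making argmins
  deterministic.

## Known limitations

* Two stages only, equal stage sizes, equal allocation in the MAMS
  design; no Pocock or triangular boundary families.
* Known σ; no t-distributed analogues.
* The critical-value surface is flat near its optimum, so reported
  optimal (r, q) locations are resolution-limited even though the optimal
  values are stable (see the numerical notes above).
* The expected-sample-size comparison between designs depends strongly on
  the assumed effect scenario; the package reports it per scenario rather
  than claiming a universal ordering.
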
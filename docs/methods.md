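# Methods

## Response mechanisms

All designs perturb a sensitive quantitative variable X (mean μ_X,
variance σ²_X) with positive-valued scrambling variables whose first two
moments are known to the analyst. The three-stage optional mechanism
draws, independently of X and S, a Bernoulli scramble indicator J with
success probability A = F + (1−T−F)·W: a proportion T of respondents is
instructed to answer truthfully, a proportion F to scramble
unconditionally, and the rest scramble exactly when they consider the
question sensitive (probability W, the unknown sensitivity level). A
scrambled response adds (subsample 1, and the additive-additive designs'
subsample 2) or subtracts (the split design's subsample 2, and the second
response of the double design) the scrambling value:

    Z = X + sign·S·J.

The double-response design collects both signed responses from each
respondent of a single sample. Two behavioural conventions are
configurable because the mechanism does not pin them down:

* `shared_indicator` (default on): one scramble decision per respondent
  governs both responses. This is the convention under which an honest
  respondent reports the same value twice — the stated hallmark of the
  design — and under which the pair covariance is
  σ²_X − A(1−A)θ₁θ₂.
* `shared_scramble_value` (default off): off means S⁽¹⁾ and S⁽²⁾ are
  independent draws, so the true X cannot be reconstructed from a
  scrambled pair (with a shared value, (Y₁+Y₂)/2 would reveal X whenever
  θ₁ = θ₂-type devices are used).

The combined-scrambling comparator replaces the additive rule by
Z = T_i·X + S_i with probability W and Z = X otherwise, with T_i a
positive multiplicative scrambler of known mean μ_Ti and variance τ²_i.

## Estimators

Subsample means z̄₁, z̄₂ satisfy two linear moment equations; solving them
yields exactly unbiased estimators of μ_X and A (hence of
W = (A−F)/(1−T−F)):

| design | μ̂ | Â |
|---|---|---|
| additive-additive | (θ₂z̄₁ − θ₁z̄₂)/(θ₂−θ₁) | (z̄₁−z̄₂)/(θ₁−θ₂) |
| split / double | (θ₂z̄₁ + θ₁z̄₂)/(θ₁+θ₂) | (z̄₁−z̄₂)/(θ₁+θ₂) |

Both estimators are linear in sample means, so the central limit theorem
gives asymptotic normality; the test suite verifies a Kolmogorov–Smirnov
check of the standardized mean estimator at the 1% level.

Variances follow from σ²_Z = σ²_X + Aγ² + A(1−A)θ² per response:

* split: Var(μ̂) = [θ₂²σ²_Z1/n₁ + θ₁²σ²_Z2/n₂]/(θ₁+θ₂)²,
  Var(Ŵ) = [σ²_Z1/n₁ + σ²_Z2/n₂]/[(θ₁+θ₂)²(1−T−F)²];
* additive-additive: the same with (θ₂−θ₁)² in place of (θ₁+θ₂)²;
* double (shared indicator): Var(μ̂) = σ²_X/n + A(θ₂²γ₁²+θ₁²γ₂²)/[n(θ₁+θ₂)²]
  and Var(Ŵ) = [A(γ₁²+γ₂²) + A(1−A)(θ₁+θ₂)²]/[n(θ₁+θ₂)²(1−T−F)²]: pairing
  cancels X in Y₁−Y₂ and the Bernoulli term in the μ̂ combination.

Every variance formula in the package is validated against the empirical
variance of simulated replicates (5% relative tolerance at 10⁴
replicates); this simulation oracle is part of the acceptance suite, not
an optional extra, because the formulas are reconstructions from the model
structure.

Data-based variance estimates substitute the (n−1)-divisor sample
variances for σ²_Zi; the formulas are linear in σ²_Zi, so plug-in
preserves unbiasedness. The population-variance estimator inverts
σ²_Zi = σ²_X + Aγ²_i + A(1−A)θ²_i per subsample using the bias-corrected
moments Â² − V̂(Â) (for A²) and Â − Â² + V̂(Â) (for A(1−A)), then combines
the two components with a fixed weight k ∈ [0,1] (default ½, which is the
natural pooled choice when the two scramblers share moments). Raw values
are reported even when Ŵ leaves [0,1] or σ̂²_X is negative, with warning
flags; an optional truncation mode exists but is excluded from all
unbiasedness claims because clipping introduces bias.

The combined-scrambling comparator's moment system is linear in (μ, W)
only through the product Wμ; with a common multiplicative mean the
solution is closed-form but of ratio type, so only consistency is claimed
(and tested). With unequal multiplicative means W is eliminated, leaving a
quadratic in μ; the real root whose implied W is closest to [0,1] is
taken, and an absence of real roots raises an error with the offending
moments.

## Privacy and allocation

Privacy is measured by Δ = E(Z−X)², the expected squared perturbation: 0
when the design never scrambles, increasing in both the scramble
probability and the scrambler's moments. For signed additive scrambling
Δ = A(θ²+γ²) — identical for additive and subtractive subsamples, so the
split design inherits the additive-additive design's privacy exactly.
Because A increases with F, the two-stage (F=0) variant is never more
protective than the three-stage one at the same T, W; the suite asserts
this ordering. For the double design two conventions are offered behind a
flag, both validated against their simulated definitions: the average
per-response measure ½A(θ₁²+γ₁²+θ₂²+γ₂²) (default), and a pair-midpoint
intruder measure A(γ₁²+γ₂²+(θ₁−θ₂)²)/4 describing an attacker who
averages the two responses. They coincide only in degenerate cases (e.g.
A = 0); the package reports whichever is requested rather than asserting a
single "correct" algebra.

Allocation minimises k·Var(μ̂) + (1−k)·Var(Ŵ) = C₁/n₁ + C₂/n₂ under
n₁+n₂ = n, giving the square-root rule n₁* = n√C₁/(√C₁+√C₂) with minimum
(√C₁+√C₂)²/n. The continuous optimum is rounded half-up toward n₁ and both
subsamples are kept nonempty; the reported v_min is the continuous floor.
Since C_i depends on the unknown W, `allocation_with_guess` evaluates the
rule at a pilot/guessed W and reports the allocation at W ± 0.1 (clipped
to [0,1]) so the user can see how sensitive the split is to the guess.

## Synthetic-data defaults and what they do (not) show

The population defaults to a gamma distribution parameterised by
(mean, variance) — mean 10, variance 4 — and scramblers default to gamma
as well, matching the requirement that scrambling values be strictly
positive; normal and uniform populations and uniform/point-mass scramblers
are available (a uniform scrambler must satisfy θ > √(3γ²) to stay
positive). Default study sizes are n₁ = n₂ = 100 respondents per replicate
and 5000 Monte Carlo replicates; the normality diagnostic uses 2000
replicates of 5000 respondents, and the population-variance check 10⁵
replicates. The relative-efficiency study grid defaults to
W ∈ {0, 0.05, …, 1}, T ∈ {0.2, 0.4}, F ∈ {0.1, 0.2} and θ-pairs
{(1,2), (1,3), (2,5)} with γ² = 0.5. These are package defaults chosen as
representative survey conditions, not canonical values.

The simulators implement the model exactly — indicator independent of X
and S, independent subsample streams spawned deterministically from the
master seed (`numpy SeedSequence.spawn`), draw order X → S → J fixed. Real
survey data additionally contain nonresponse, lying beyond the model
(scrambling is the only perturbation), interviewer effects and
finite-population structure (sampling here is with replacement); passing
tests therefore certify the estimators' properties under the model, not
robustness to such violations. Relative efficiencies are invariant to μ_X
(it cancels in every variance ratio), which the study engine checks
exactly for the analytic forms and within noise for the empirical ones.

## Design notes and limitations

* Under the default double-response conventions the reconstructed
  variances make the double design *more* efficient than the split design
  at equal total sample size (pairing removes σ²_X from Var(Ŵ) entirely
  and the Bernoulli term from Var(μ̂)). A widely-made claim for this
  family of designs orders them the other way; the study engine therefore
  computes the split-vs-double comparison and reports it rather than
  asserting either direction. Users can flip `shared_indicator` /
  `shared_scramble_value` to explore the other conventions.
* The comparator design's default multiplicative scrambler has mean 1
  (variance 0.25): this keeps its moment system linear while still adding
  multiplicative noise. Set unequal means to exercise the quadratic
  solver.
* Estimates of W outside [0,1] are legitimate under the model (Â is a
  difference of noisy means) and are the flagged-but-raw default;
  downstream consumers needing a probability should truncate explicitly
  and accept the bias.
* All Monte Carlo tolerances are stated in the tests as multiples of the
  replicate-level standard error (4·SE for means, 5% relative for
  variances at 10⁴ replicates), so they scale correctly if replicate
  counts are changed.
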
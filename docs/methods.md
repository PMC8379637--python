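# Methods

## Model

Each individual's infection status is an independent Bernoulli(p) variable;
p may differ between subpopulations but not within one. A testing strategy
assigns every individual a binary status (no abstentions). Wrong assignments
are penalised per individual: a false positive costs b > 0, a false negative
c > 0, correct assignments cost nothing; only the ratio a = c/b and the
scale b matter. Pooled tests are perfect: a pool is positive if and only if
it contains at least one infected member, regardless of pool size. All
results are expressed in the common currency of a rate R in tests per
individual (TpI) and an expected cost per individual D.

The perfect-test assumption is the strongest one. It implies that the kSG
decision rule (declare the members of positive final subpools infected)
never produces a false negative, so the closed-form cost
b(1 − p − (1−p)^{u_k}) counts false positives only. Dilution effects,
test error, correlated infections, and behavioural responses (compliance)
are all outside the model.

## The parametric lower bound

The minimum expected cost achievable at rate R is bounded below by the
distortion-rate function of the Bernoulli source under the asymmetric cost.
For a single population it is the parametric pair (R̄(p,a,v), D̄(p,a,v)),
where the parameter v ∈ [0, 1] is 2 to the power of the curve's slope:
dD/dR = 1/log₂ v. The pair is obtained from the variational
(Lagrangian) solution for the optimal test channel: writing λ₀, λ₁ for the
two input normalisers,

    λ₀ = (1−p)(1−v^{a+1})/(1−v^a),   λ₁ = p(1−v^{a+1})/(1−v),

the rate is R̄ = D̄·log₂ v + H₂(p) − log₂[(1−v^{a+1})/(1−v^a)] +
p·log₂[(1−v)/(1−v^a)] and D̄ follows from the induced output distribution.
The curve is valid while both output letters of the optimal channel have
positive probability; the critical parameter v₀ is the smallest positive v
at which one of them vanishes, i.e. the smallest root of

    (p v^{a+1} + 1 − p − v)(p v^{−a−1} + 1 − p − v^{−1}) = 0.

Beyond v₀ the bound clamps at the better blanket assignment,
(R, D) = (0, min(1−p, a·p)). Useful analytic anchors, all enforced in the
test suite: R̄(p,a,0) = H₂(p) and D̄(p,a,0) = 0; for the symmetric case
a = 1 the curve is the Hamming distortion-rate function
R = H₂(p) − H₂(D) with v₀ = p/(1−p) for p < 1/2; and the numerical slope of
the curve equals 1/log₂ v in the interior.

For a population split into subpopulations with parameters (Nᵢ, pᵢ, bᵢ, cᵢ)
the aggregate bound is the population-weighted combination evaluated at
v^{bᵢ} per subpopulation — a common slope in the *unscaled* cost means each
subpopulation sits at its own point of its own curve, and subpopulations
clamp (stop contributing rate) one after another as v grows.

### Numerics

* Root finding for v₀: each factor is scanned for sign changes on 10⁴
  log-spaced points and refined by Brent's method (xtol 1e−15). The second
  factor's root can lie at v ≈ 2^{−const/a}, arbitrarily close to zero for
  small a, so it is scanned in the substituted variable t = v^a (its root
  always satisfies t ≥ p) and mapped back with v = t^{1/a}. v = 1 solves
  both factors and is the fallback when no interior root exists.
* v = 0 and v = 1 are handled by explicit limit branches; no 0⁰ or log 0 is
  ever evaluated. Powers v^b use exp(b·ln v).
* Budget and target-cost queries invert R(v) and D(v) by bisection
  (xtol 1e−12) after an empirical monotonicity check of the aggregate R on
  a 1000-point grid; monotonicity of the mixture is not guaranteed a priori
  for arbitrary bᵢ, and a failed check falls back to a conservative grid
  search with a warning rather than returning a wrong bound silently.
* Curve sampling concentrates points near both endpoints (R is steep near
  v = 0, D moves fastest near v = 1) plus each subpopulation's clamp
  transition.

## Strategies and the achievable frontier

Strategy enumeration covers all kSG chains with at most `max_k` stages
(default 2) and first pool size at most `max_group` (default 100), with each
stage size dividing its parent so pools always split into equal subpools.
The defaults are package choices: two stages because additional stages add
bookkeeping for marginal gains at these prevalences, and a pool cap of 100
comfortably above the largest pool any optimal plan in the shipped scenarios
uses (66). Both are arguments everywhere, including the CLI.

Partial coverage (test only a fraction, give the rest the cost-optimal
default status, healthy iff p·c ≤ (1−p)·b with ties to healthy) makes any
convex combination of two strategy points achievable, so the per-
subpopulation frontier is the lower convex hull of the enumerated points
anchored at the no-test point (0, min(p·c, (1−p)·b)), trimmed at its cost
minimum. Budget allocation across subpopulations walks all hull segments in
decreasing cost-reduction-per-test order; convexity makes the greedy walk
optimal among frontier mixtures, which the tests confirm against an
independent linear-programming oracle on random small scenarios. Coverage
fractions are continuous — populations here are 10⁵–10⁷, so integrality
errors are O(u/N) — and reported test counts are rounded up. Equal-slope
ties break by subpopulation order, then smaller first pool size, for
deterministic output. Mixtures arise only between adjacent hull vertices;
by convexity no three-way mixture is ever needed.

One caveat the tests document: the kSG rate is *not* monotone in u₁ with
later stages fixed — the 1/u₁ saving is eventually overtaken by the extra
splitting of the many positive pools — so enumeration cannot be pruned by
assuming larger first pools are always cheaper.

## Monte-Carlo simulator

The simulator draws Bernoulli statuses from a seeded `numpy` generator and
executes the adaptive pooling tree exactly: full blocks vectorised by
reshaping, the remainder block (when N is not a multiple of u₁) pooled as
its own smaller group and split into chunks of the next stage size. The
closed forms ignore remainders, so empirical rates may differ by up to one
test per remainder group — the tests allow exactly that margin. Every
simulation records its seed and identical seeds reproduce identical results.

Agreement between simulation and closed forms is asserted within four
standard errors, with standard errors estimated across independent seeded
replicates (individuals within a pool are correlated, so a per-individual
binomial variance would understate the sampling error; the replicate
estimate is exact for the quantity actually simulated). Typical test sizes
are 8–10 replicates of 2·10⁴–10⁵ individuals, with one 10⁶-individual run;
the whole suite runs in a few seconds.

What the simulator does and does not establish: it validates the rate and
cost algebra, the allocation bookkeeping, and the zero-false-negative
property of the decision rule under the model's assumptions — independent
statuses and perfect tests. It does not probe robustness to test error,
dilution in large pools, or correlated infections, so passing simulations
say nothing about those real-data effects.

## Scenario configuration

Scenarios are YAML/JSON mappings with explicit semantic keys (`size`,
`prevalence`, `fp_cost`, `fn_cost`); unknown keys are rejected and every
invariant violation names the offending field. Cost units are arbitrary but
must be consistent across subpopulations within a scenario: both the bound
and the optimizer sum bᵢ-scaled terms. The packaged `austria_nov2020`
scenario encodes the November-2020 Austrian situation (8 916 845
individuals in four subpopulations, budget 103 621 tests); its cost choice
c = 33b for the general population comes from reading the contemporaneous
lockdown as the indifference point (1−p)b ≈ p·c at p = 0.029, and b = 6
for health-care workers expresses the higher price of wrongly quarantining
them.

## Known limitations

* The bound is generally not achievable — at the threshold prevalence
  (3−√5)/2 it promises zero cost at H₂(p) ≈ 0.959 TpI although only
  individual testing (1 TpI) attains zero cost — so the gap between the
  optimized frontier and the bound overstates the true room for
  improvement by an unknown amount.
* Pools never mix subpopulations; allowing that could only improve plans
  and is not modelled.
* Non-adaptive designs testing individuals in several first-stage pools
  (array testing) are outside the strategy family.
* The reported expected-declared-infected counts inherit the rounding of
  the scenario prevalences (three significant digits), which moves the
  large counts by parts in 10⁴.
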
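# Methods

## Model and assumptions

Observations `X_1, ..., X_N` are i.i.d. normal with mean `theta` and known
variance 1; the one-sided test rejects when `Z^(N) = sum_i X_i / sqrt(N)`
exceeds `z_alpha`. A single pre-planned interim look happens after `n`
observations; no sequential testing, no p-value combination or weighting is
involved — the final statistic always weights all observations equally,
which is precisely why an unrestricted raise needs justification. The
interim statistic is assumed already standardized; with an estimated
variance (t-statistic) the theory is approximate only and no adjustment is
made.

Interim and final statistics are jointly normal with correlation
`rho = sqrt(n/N)`, so conditionally on `Z^(n) = z` under the null,
`Z^(N) ~ N(rho z, 1 - rho^2)`. The change in conditional type-I error from
raising `N0` to `N0 + r`,

    G(r) = Phi((sqrt(q) z - z_alpha)/sqrt(1-q)) - Phi((sqrt(qV) z - z_alpha)/sqrt(1-qV)),

with `q = n/(N0+r)`, `V = (N0+r)/N0`, is non-positive exactly when
`z >= z_alpha * b(q,V)`; `b` is obtained by setting the difference of the
two arguments to zero and solving for `z`. The package treats `r` as a
positive real: the bound is continuous in `r` and its `r -> 0` limit
`sqrt(n/N0)` and `r -> inf` limit `(1-sqrt(1-qV))/sqrt(qV)` are exposed as
separate accessors because the defining expression is a 0/0 form at `r = 0`.
Ties at the threshold permit the raise (`G = 0` there).

### Conditional versus unconditional control

The guarantee proved by the zone criterion is **conditional**: inside the
zone the raise cannot increase the conditional error, and integrating the
conditional error over the null law of `z` then controls the unconditional
level. The converse direction deserves care, and the test suite pins it
down exactly:

* any one-sided threshold rule "raise iff `z >= t`" has unconditional level
  `alpha + int_t^inf G phi dz <= alpha`, with equality only in the
  degenerate limits `t -> +-inf`. In particular a raise applied regardless
  of the interim data is simply a fixed design at `N0 + r` and has level
  exactly `alpha`;
* the bound is nevertheless optimal in the conditional sense: below
  `z_alpha * b` the conditional error strictly increases (`G > 0`), so the
  conditional-error-function principle that licenses mid-trial redesigns no
  longer applies there;
* the restriction has unconditional teeth only against adversarial
  behaviour: the rule "raise iff `z < z_alpha * b`" — raising exactly where
  it hurts — has level `alpha + int_{-inf}^{bound} G phi dz > alpha`.

The minimum conditional power over the permitted zone evaluates conditional
power (drift set to the interim estimate `z/sqrt(n)`) at the zone's left
edge with the planned final size; it equals 1/2 at the simple criterion and
decreases in `r`.

## Tunable parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `n`, `N0` | interim / planned sample size | count | required |
| `r` | offered raise | count (real accepted) | required |
| `alpha` | one-sided level, in (0, 0.5) | probability | required (0.025 in examples) |
| `futility_threshold` | `z` below it stops the trial | z-scale | `-inf` (disabled) |
| `p0` | binomial null proportion | probability | required |
| `lam`, `beta`, `mu` | Weibull rate/shape, censoring rate | 1/time^beta, –, 1/time | required; `mu = 0` = no censoring |
| `n_sims`, `seed` | Monte-Carlo size and seed | – | explicit everywhere |

The futility threshold is user-supplied because stopping for futility can
only reduce the type-I error; no rule is imposed. How the DMC should choose
`r` inside the permitted zone is likewise left open — the package evaluates
a supplied `r` (or a grid via `g-curve`) without recommending one.

## Binomial endpoint

Percentile convention: `q_{a,m}` is the smallest integer `t` with
`Pr(Bin(m,p0) <= t) >= 1-alpha`, and the test rejects on `X > t` — the only
pairing under which the fixed design's size never exceeds `alpha`.
Conditionally on the interim count `k`, the remainder of the trial is an
independent shifted binomial, so `G(r)` is exact; tail arguments outside
the remaining support resolve through the distribution itself (tail 1 below
0, tail 0 beyond the remaining size), not through clamping code.

The Cornish–Fisher percentile
`m p0 + sqrt(m) sigma0 (z_a + gamma0 (z_a^2-1)/(6 sqrt(m)))` feeds the
remaining-trial pivots and normal tails; its sign flips exactly at the
derived count threshold

    k* = n p0 + gamma0 sigma0 (z_a^2 - 1)/6
         + (sqrt(n2-n) sqrt(n1) - sqrt(n1-n) sqrt(n2)) z_a sigma0
           / (sqrt(n2-n) - sqrt(n1-n)),

with `n1 = N0 + r`, `n2 = N0`. Note on signs: the drift term's numerator
and denominator are each negative, so the term itself is **positive** — it
is what lifts `k*` above the null mean; the skewness term is negative
exactly when `p0 > 1/2`. Because the exact `G` is a step function, it can
remain slightly positive for the first count above `k*`; the rule is exact
for the approximated `G`, approximate for the exact one. Averaged over the
null law of `k` the retained-set error change is negative for the typical
design, but small positive excursions (of order 0.01 at worst in the
regimes tested) do occur — the preservation claim for the binomial endpoint
is an average, not a uniform, statement, and the test suite asserts exactly
that.

The randomized-design study (`replicate_simulation_study`) draws, per
replicate, an interim size `n` uniform on the integers 20..100, sets
`N0 = 2n` and `r = n`, draws `p0` uniform on `[5/n, 1-5/n]` (keeping the
normal-approximation rule of thumb attainable) and `k ~ Bin(n, p0)`, then
evaluates the exact `G` over the replicates whose `k` strictly exceeds the
chosen criterion's threshold at `alpha = 0.025`. Draws depend only on the
seed, so running both criteria with one seed compares them on common random
numbers. The study emulates design heterogeneity, not any particular trial:
it says how the two retention rules behave across a family of balanced
two-stage binomial designs, nothing about covariates, overdispersion or
drifting event rates in real data. The acceptance script runs it at 900,000
replicates; the test suite at 100,000 (Monte-Carlo SE of the summaries
well below 0.001 already at that size).

## Survival endpoint

Lifetimes are `Weibull(lam, beta)` (survival `exp(-lam y^beta)`) with
independent `Exp(mu)` right censoring and no left truncation. All
integrals — the event sub-distribution `W1`, the variance functional
`sigma1 = int dW1/C^2` and the third-moment integral `int C^-3 dW1` — are
evaluated by adaptive quadrature at absolute tolerance 1e-10 on the
substituted scale `u = x^beta`, which removes the integrable singularity of
`dW1` at 0 for `beta < 1` and leaves smooth integrands everywhere else.
`sigma1` refuses evaluation where the at-risk probability falls below 1e-8
(the integrand diverges as the risk set empties).

The Edgeworth correction to the standardized product-limit estimator's CDF
is implemented in two variants that differ by a `+3 sigma1` inside the
polynomial: `results` (default) uses
`Phi(x) - phi(x) kappa3 (x^2-1)/(6 sqrt(n))`, `methods` adds the extra
term. Both are exposed because the two forms circulate and they are *not*
numerically interchangeable at small `n`; the difference is exactly
`phi(x) sigma1 / (2 sqrt(n))`. The grouping of the skewness constant is
itself reconstructed as `kappa3 = (-7.5 sigma1^4 + int_0^z C^-3 dW1) /
sigma1` from a typographically ambiguous source; treat its absolute value
with caution and prefer the simulation route when the constant matters.
The raw expansion can exit `[0,1]` for extreme abscissae or heavy skewness;
values are clipped with a warning.

The logrank statistic follows the at-risk/event-table sums
`T = sum (r_iA o_iC - r_iC o_iA)/r_i` and
`V = sum o_i (r_i-o_i) r_iA r_iC / ((r_i-1) r_i^2)`; rows are keyed by
distinct ordered event times (the `o(r-o)` and `(r-1)` factors already
handle ties), rows with `r_i < 2` contribute no variance, and positive `z`
favours the active arm. Tables are read and written as CSV with columns
`time, r_A, r_C, o_A, o_C`. `simulate_remainder` adds a supplied interim
table's `(T, V)` sums to those of simulated future subjects — legitimate
because the statistic is a sum of per-event-time increments over disjoint
subject sets — and rejects on the merged `z`; time units are caller-defined
throughout.

## Monte-Carlo engine and numerical choices

`simulate_type1` draws, per trial, the interim block sum, the planned
remainder sum and the raise increment sum as exact normal sufficient
statistics (block sums of i.i.d. unit normals are exactly normal, so no
per-observation array is needed); the raise increment enters the final
statistic only when the rule fires, which keeps one common random stream
across rules. Draws are chunked at a frozen size of 2^19 so results depend
only on the seed. Its deterministic twin `exact_type1_by_quadrature`
integrates the conditional error function against the null density on the
two sides of the rule threshold (absolute tolerance 1e-10), and every
simulated level is tested against it within three binomial Monte-Carlo
standard errors. `generate_trial_fixture` materialises full observation
vectors for consumers who need raw data.

Boundary assertions on `G` use an absolute tolerance of 1e-9: all
quantities are compositions of `Phi` evaluations, well-conditioned away
from the extreme tails. Problem sizes used in the checked properties:
2×10^6 null trials for the Monte-Carlo level, 10^4 random designs for the
bound inequalities, 10^3 for the quadrature-level sweep, full enumeration
for every binomial design with `N0 + r <= 40`, and 10^4 simulated tables
for the logrank null distribution.

## Known limitations

* Known-variance normal theory; t-statistics are treated as approximately
  normal without small-sample adjustment.
* One interim look only; no group-sequential alpha spending, no repeated
  testing, no sample-size decrease rule.
* Binomial: one-sample tests only; the count threshold certifies the
  approximated conditional error change, and exact conditional control can
  fail marginally just above the threshold (see above).
* Survival: no Kaplan–Meier estimation or Cox regression; no left
  truncation or interval censoring; the Edgeworth constant's grouping is a
  documented reconstruction.
* The package evaluates decision rules; it does not optimize the raise or
  the zone.
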
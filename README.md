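# ssrzone

Promising-zone bounds for **sample-size-adjustable (SSA) clinical trial
designs**: how far below "conditional power ≥ 50%" an interim result may
fall while a sample-size raise still preserves the one-sided type-I error
rate.

The package is aimed at trial statisticians and Data Monitoring Committee
(DMC) support work: it evaluates the bound and the associated minimum
conditional power for normal endpoints, provides exact and
skewness-corrected machinery for a one-sample binomial endpoint, supports
survival endpoints through the logrank statistic and the Edgeworth
ingredients of the censored-Weibull product-limit estimator, and verifies
every claim by quadrature and Monte Carlo.

## The criterion

A trial plans `N0` observations with a one-sided test `Z^(N) > z_alpha` and
looks once, after `n` observations, at the standardized interim statistic
`z`. If the DMC may raise the final size to `N = N0 + r`, put

    q = n / (N0 + r),    V = (N0 + r) / N0      (so  qV = n/N0),

    b(q, V) = (sqrt(1-q) - sqrt(1-qV)) / (sqrt(qV) sqrt(1-q) - sqrt(q) sqrt(1-qV)).

Raising the sample size cannot increase the conditional (hence also the
unconditional) type-I error exactly when

    z >= z_alpha * b(q, V).

Because `b(q,V) <= sqrt(n/N0)`, this is weaker than the classical *simple
criterion* `z >= z_alpha * sqrt(n/N0)` (equivalent to conditional power
≥ 50%). The minimum conditional power over the permitted zone is

    Phi( z_alpha * (b/sqrt(qV) - 1) / sqrt(1 - qV) ),

which is below 50% and decreases as the offered raise `r` grows, down to
the limit implied by `b -> (1 - sqrt(1-qV))/sqrt(qV)` as `r -> inf`.

For a binomial endpoint (`H0: p = p0`, reject when the final count exceeds
the exact binomial percentile), the same comparison is available *exactly*
through the conditional remaining-trial distribution, and approximately
through Cornish–Fisher percentiles, which yield a closed-form interim count
threshold `k*` playing the role of `z_alpha * b`. For survival endpoints
the logrank statistic is the interim `z`.

## Worked example

The reference design `n = 55`, `N0 = 110`, `alpha = 0.025` with an offered
raise of `r = 40`:

```sh
$ ssrzone bound --n 55 --n0 110 --r 40 --alpha 0.025
{
  "config": { "n": 55, "N0": 110, "r": 40.0, "alpha": 0.025 },
  "b": 0.6593164,
  "z_threshold": 1.292236,
  "simple_threshold": 1.385904,
  "min_conditional_power": 0.425699
}
```

The raise is permitted for any interim `z >= 1.292` — noticeably below the
simple criterion's `1.386` — and the conditional power there may be as low
as **43%** while the type-I error stays protected. For small raises the
bound approaches `sqrt(55/110)`: `b(55, 110, 0.01) = 0.7070907` versus
`sqrt(0.5) = 0.7071068`; for `r = 110` the minimum conditional power drops
to `0.3575873`.

An interim decision at an observed statistic:

```sh
$ ssrzone decide --z 1.5 --n 55 --n0 110 --r 40 --alpha 0.025
{ ... "verdict": "raise_permitted", "g_value": -0.008551195, ... }
```

`g_value` is the change `G(r)` in conditional type-I error the raise would
cause — non-positive inside the permitted zone. Other subcommands:
`g-curve` (CSV of `G` versus `r`), `binom-check` / `binom-sim` (binomial
endpoint), `logrank` / `surv-cp` (survival endpoint), and `simulate`
(trial-level Monte-Carlo verification of the unconditional level). Every
subcommand also accepts a `key = value` config file; flags win on conflict.

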
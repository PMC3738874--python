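"""Normal-endpoint analytics for sample-size-adjustable (SSA) designs.

A trial plans ``N0`` observations and looks at the data once, after ``n`` of
them, through the standardized statistic ``Z^(n)``.  At that interim the Data
Monitoring Committee may stop for futility, continue as planned, or raise the
final sample size to ``N0 + r``.  With i.i.d. unit-variance normal
observations the interim and final statistics are jointly normal with
correlation ``sqrt(n/N)``, which makes the change in conditional type-I error
caused by the raise,

    G(r) = Pr(Z^(N0+r) > z_a | Z^(n) = z, theta=0)
         - Pr(Z^(N0)   > z_a | Z^(n) = z, theta=0),

an explicit difference of two normal tail probabilities.  ``G(r) <= 0`` —
i.e. the raise cannot inflate the error rate — exactly when the interim
statistic clears the *promising-zone bound*

    z >= z_a * b(q, V),
    q = n/(N0+r),  V = (N0+r)/N0,
    b(q, V) = (sqrt(1-q) - sqrt(1-qV)) / (sqrt(qV)sqrt(1-q) - sqrt(q)sqrt(1-qV)).

``b`` is sandwiched between ``(1-sqrt(1-qV))/sqrt(qV)`` (its limit as
``r -> inf``) and ``sqrt(qV) = sqrt(n/N0)`` (its limit as ``r -> 0``), so the
classical "conditional power >= 50%" rule — equivalent to
``z >= z_a*sqrt(n/N0)``, the *simple criterion* — is sufficient but not
necessary.  The corresponding minimum conditional power over the permitted
zone is below 50% and decreases with ``r``.

All functions accept scalars or numpy arrays (broadcasting) and consume an
already-standardized interim statistic; the observations' variance is a
contract on the caller (see :func:`standardize_mean_difference`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigurationError, DesignError

__all__ = [
    "DesignSpec",
    "DerivedRatios",
    "InterimResult",
    "BoundResult",
    "DecisionOutcome",
    "bound_b",
    "bound_b_limit_r_to_infinity",
    "conditional_error",
    "g_normal",
    "conditional_power",
    "min_conditional_power",
    "bound_result",
    "decide",
    "standardize_mean_difference",
]


def _check_interim_vs_final(n, N_final) -> None:
    if np.any(np.asarray(n) <= 0) or np.any(np.asarray(n) >= np.asarray(N_final)):
        raise DesignError(f"require 0 < n < N_final, got n={n}, N_final={N_final}")


def _check_alpha(alpha) -> None:
    if np.any(np.asarray(alpha) <= 0) or np.any(np.asarray(alpha) >= 0.5):
        raise DesignError(f"one-sided alpha must lie in (0, 0.5), got {alpha}")


def _check_raise(r) -> None:
    if np.any(np.asarray(r) <= 0):
        raise DesignError(
            f"raise r must be > 0 (the bound is a 0/0 form at r=0; "
            f"use bound_b_limit_r_to_infinity / sqrt(n/N0) accessors for the limits), got r={r}"
        )


@dataclass(frozen=True)
class DesignSpec:
    """Frozen SSA design: interim size ``n``, planned size ``N0``, one-sided
    level ``alpha`` and a candidate raise ``r`` (a positive real; fractional
    raises are accepted because the bound is continuous in ``r``)."""

    n: int
    N0: int
    alpha: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.n < self.N0:
            raise DesignError(f"require 0 < n < N0, got n={self.n}, N0={self.N0}")
        _check_alpha(self.alpha)
        if self.r < 0:
            raise DesignError(f"raise r must be non-negative, got {self.r}")

    @property
    def z_alpha(self) -> float:
        return float(norm.ppf(1.0 - self.alpha))

    @property
    def N(self) -> float:
        """Raised final size ``N0 + r``."""
        return self.N0 + self.r

    def ratios(self) -> "DerivedRatios":
        return DerivedRatios.from_design(self.n, self.N0, self.r)


@dataclass(frozen=True)
class DerivedRatios:
    """Information ratios of a design: ``q = n/(N0+r)``, inflation
    ``V = (N0+r)/N0``, their product ``qV = n/N0`` (independent of r) and the
    interim/final correlation ``rho = sqrt(n/N)``."""

    q: float
    V: float
    qV: float
    rho: float

    @classmethod
    def from_design(cls, n: int, N0: int, r: float) -> "DerivedRatios":
        _check_interim_vs_final(n, N0)
        if r < 0:
            raise DesignError(f"raise r must be non-negative, got {r}")
        N = N0 + r
        return cls(q=n / N, V=N / N0, qV=n / N0, rho=math.sqrt(n / N))


@dataclass(frozen=True)
class InterimResult:
    """The standardized interim statistic and the sample size it rests on.

    Under the null ``z`` is standard normal; that standardization is the
    caller's responsibility."""

    z: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise DesignError(f"interim statistic must be finite, got {self.z}")
        if self.n <= 0:
            raise DesignError(f"interim sample size must be positive, got {self.n}")

    @property
    def theta_hat(self) -> float:
        """Interim drift estimate ``z / sqrt(n)`` (the per-observation mean)."""
        return self.z / math.sqrt(self.n)


@dataclass(frozen=True)
class BoundResult:
    """The promising-zone bound for one design, on both scales, plus the
    minimum conditional power over the permitted zone."""

    b: float
    z_threshold: float
    simple_threshold: float
    min_conditional_power: float


@dataclass(frozen=True)
class DecisionOutcome:
    """Three-way interim verdict with the conditional-error change ``G(r)``
    at the observed statistic."""

    verdict: str  # "futility" | "continue" | "raise_permitted"
    g_value: float
    rationale: str = field(compare=False)


def bound_b(n: int, N0: int, r):
    """Promising-zone bound ``b(q, V)`` for a raise of ``r`` on an
    ``(n, N0)`` design.

    The raise keeps the conditional type-I error at or below the no-adaptation
    level precisely for interim statistics ``z >= z_alpha * b``.  ``b`` is
    strictly decreasing in ``r``, tends to ``sqrt(n/N0)`` as ``r -> 0`` and to
    ``(1 - sqrt(1-n/N0))/sqrt(n/N0)`` as ``r -> inf``.
    """
    _check_interim_vs_final(n, N0)
    _check_raise(r)
    r = np.asarray(r, dtype=float)
    N = N0 + r
    q = n / N
    V = N / N0
    qV = n / N0
    num = np.sqrt(1.0 - q) - np.sqrt(1.0 - qV)
    den = np.sqrt(qV) * np.sqrt(1.0 - q) - np.sqrt(q) * np.sqrt(1.0 - qV)
    return (num / den)[()]


def bound_b_limit_r_to_infinity(n: int, N0: int) -> float:
    """Infimum of ``b`` over raises: ``(1 - sqrt(1-n/N0)) / sqrt(n/N0)``.

    ``bound_b(n, N0, r)`` decreases to this value as ``r`` grows."""
    _check_interim_vs_final(n, N0)
    qV = n / N0
    return (1.0 - math.sqrt(1.0 - qV)) / math.sqrt(qV)


def conditional_error(z, n: int, N_final: int, alpha: float):
    """Conditional type-I error ``Pr(Z^(N_final) > z_alpha | Z^(n)=z, theta=0)``.

    Uses the exact conditional law ``N(rho*z, 1-rho^2)`` with
    ``rho = sqrt(n/N_final)``.  Integrating this function against the standard
    normal density of ``z`` returns ``alpha`` (law of total probability), which
    is what makes it a proper conditional error function.
    """
    _check_interim_vs_final(n, N_final)
    _check_alpha(alpha)
    z = np.asarray(z, dtype=float)
    frac = n / N_final
    z_a = norm.ppf(1.0 - alpha)
    return norm.sf((z_a - np.sqrt(frac) * z) / np.sqrt(1.0 - frac))[()]


def g_normal(z, n: int, N0: int, r, alpha: float):
    """Change in conditional type-I error ``G(r)`` caused by raising the final
    size from ``N0`` to ``N0 + r`` at interim statistic ``z``.

    ``G(r) <= 0`` iff ``z >= z_alpha * bound_b(n, N0, r)``.
    """
    _check_raise(r)
    return np.asarray(
        conditional_error_raised(z, n, N0, r, alpha)
        - conditional_error(z, n, N0, alpha)
    )[()]


def conditional_error_raised(z, n: int, N0: int, r, alpha: float):
    """Conditional error of the raised design, continuous in a real ``r``."""
    _check_interim_vs_final(n, N0)
    _check_alpha(alpha)
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    frac = n / (N0 + r)
    z_a = norm.ppf(1.0 - alpha)
    return norm.sf((z_a - np.sqrt(frac) * z) / np.sqrt(1.0 - frac))[()]


def conditional_power(z, n: int, N_final: int, alpha: float):
    """Conditional power: rejection probability at final size ``N_final``
    given ``Z^(n)=z``, evaluated at the interim drift estimate
    ``theta = z/sqrt(n)``.

    Equals exactly 1/2 at ``z = z_alpha*sqrt(n/N_final)`` — the simple
    criterion — and is strictly increasing in ``z``.
    """
    _check_interim_vs_final(n, N_final)
    _check_alpha(alpha)
    z = np.asarray(z, dtype=float)
    frac = n / N_final
    z_a = norm.ppf(1.0 - alpha)
    return norm.sf((z_a - z / np.sqrt(frac)) / np.sqrt(1.0 - frac))[()]


def min_conditional_power(n: int, N0: int, r, alpha: float):
    """Minimum conditional power over the permitted zone
    ``z >= z_alpha * b(q,V)``:

        Phi( z_alpha * (b/sqrt(qV) - 1) / sqrt(1 - qV) ).

    Lies in (0, 1/2], tends to 1/2 as ``r -> 0`` and decreases in ``r``: the
    larger the raise on offer, the less promising the interim may look while
    still protecting the type-I error.
    """
    b = bound_b(n, N0, r)
    qV = n / N0
    z_a = norm.ppf(1.0 - alpha)
    return norm.cdf(z_a * (b / np.sqrt(qV) - 1.0) / np.sqrt(1.0 - qV))[()]


def bound_result(design: DesignSpec) -> BoundResult:
    """Evaluate the bound, both z-scale thresholds and the minimum conditional
    power for one design (requires ``design.r > 0``)."""
    b = float(bound_b(design.n, design.N0, design.r))
    z_a = design.z_alpha
    return BoundResult(
        b=b,
        z_threshold=z_a * b,
        simple_threshold=z_a * math.sqrt(design.n / design.N0),
        min_conditional_power=float(
            min_conditional_power(design.n, design.N0, design.r, design.alpha)
        ),
    )


def decide(
    interim: InterimResult,
    design: DesignSpec,
    futility_threshold: float = -math.inf,
) -> DecisionOutcome:
    """Three-way interim decision.

    * ``z < futility_threshold``              -> ``futility``
    * ``z >= z_alpha*b(q,V)`` (tie included)  -> ``raise_permitted`` (G <= 0)
    * otherwise                               -> ``continue``

    The futility threshold defaults to ``-inf`` (disabled); stopping for
    futility can only lower the type-I error so no rule is imposed.  A tie at
    the bound permits the raise: ``G`` vanishes there.
    """
    if interim.n != design.n:
        raise ConfigurationError(
            f"interim rests on n={interim.n} but the design specifies n={design.n}"
        )
    res = bound_result(design)
    if futility_threshold >= res.z_threshold:
        raise ConfigurationError(
            f"futility threshold {futility_threshold} must lie below the raise "
            f"threshold z_alpha*b = {res.z_threshold:.7g}"
        )
    g = float(g_normal(interim.z, design.n, design.N0, design.r, design.alpha))
    if interim.z < futility_threshold:
        verdict = "futility"
        rationale = (
            f"z = {interim.z:.7g} < futility threshold {futility_threshold:.7g}"
        )
    elif interim.z >= res.z_threshold:
        verdict = "raise_permitted"
        rationale = (
            f"z = {interim.z:.7g} >= z_alpha*b = {res.z_threshold:.7g}; "
            f"raising by r = {design.r:g} cannot inflate the conditional "
            f"type-I error (G = {g:.3g})"
        )
    else:
        verdict = "continue"
        rationale = (
            f"futility threshold {futility_threshold:.7g} <= z = {interim.z:.7g} "
            f"< z_alpha*b = {res.z_threshold:.7g}; a raise of r = {design.r:g} "
            f"would change the conditional type-I error by G = {g:.3g} > 0"
        )
    return DecisionOutcome(verdict=verdict, g_value=g, rationale=rationale)


def standardize_mean_difference(
    mean: float, sigma: float, n: int, null_mean: float = 0.0
) -> float:
    """Standardize an observed mean into the interim statistic
    ``z = sqrt(n) (mean - null_mean) / sigma`` for a KNOWN sigma.

    With sigma estimated (a t-statistic) the normal theory is approximate
    only; no small-sample adjustment is applied here.
    """
    if sigma <= 0:
        raise DesignError(f"sigma must be positive, got {sigma}")
    if n <= 0:
        raise DesignError(f"n must be positive, got {n}")
    return math.sqrt(n) * (mean - null_mean) / sigma
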
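"""Trial-level Monte-Carlo engine for normal endpoints.

Verifies the unconditional type-I error of sample-size-adjustable rules by
simulation and, for deterministic rules, by quadrature of the conditional
error function against the null density of the interim statistic — the
deterministic twin every simulation here is cross-checked against.

The final statistic under a raise weights all ``N0 + r`` observations
equally (plain ``Z^(N)``, no combination test); that is exactly why the raise
must be restricted to the promising zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .core_normal import (
    DesignSpec,
    bound_b,
    conditional_error,
    conditional_error_raised,
    g_normal,
)
from .exceptions import ConfigurationError

__all__ = [
    "SsaRule",
    "SimulationReport",
    "TrialFixture",
    "simulate_type1",
    "exact_type1_by_quadrature",
    "generate_trial_fixture",
]

_CHUNK = 1 << 19  # frozen chunk size keeps draws reproducible for a given seed

_RULE_KINDS = (
    "derived_bound",
    "simple_criterion",
    "always_raise",
    "never_raise",
    "custom_threshold",
)


@dataclass(frozen=True)
class SsaRule:
    """Deterministic raise policy: raise by ``r`` iff the interim statistic
    reaches the rule's threshold.

    * ``derived_bound``    — threshold ``z_alpha * b(q, V)`` (promising zone)
    * ``simple_criterion`` — threshold ``z_alpha * sqrt(n/N0)`` (CP = 50%)
    * ``always_raise``     — threshold ``-inf``
    * ``never_raise``      — never raises (fixed design)
    * ``custom_threshold`` — user-supplied ``custom_z``
    """

    rule_kind: str
    r: float = 0.0
    custom_z: float | None = None

    def __post_init__(self) -> None:
        if self.rule_kind not in _RULE_KINDS:
            raise ConfigurationError(
                f"rule_kind must be one of {_RULE_KINDS}, got {self.rule_kind!r}"
            )
        if self.rule_kind != "never_raise" and self.r <= 0:
            raise ConfigurationError(
                f"raising rule {self.rule_kind!r} needs r > 0, got r={self.r}"
            )
        if self.rule_kind == "custom_threshold" and self.custom_z is None:
            raise ConfigurationError("custom_threshold rule needs custom_z")

    def threshold(self, design: DesignSpec) -> float:
        """Raise iff ``z >= threshold`` (``+inf`` for never_raise)."""
        if self.rule_kind == "never_raise":
            return math.inf
        if self.rule_kind == "always_raise":
            return -math.inf
        if self.rule_kind == "custom_threshold":
            return float(self.custom_z)
        z_a = design.z_alpha
        if self.rule_kind == "simple_criterion":
            return z_a * math.sqrt(design.n / design.N0)
        return z_a * float(bound_b(design.n, design.N0, self.r))


@dataclass(frozen=True)
class SimulationReport:
    n_sims: int
    seed: int
    rejection_rate: float
    mc_se: float
    raise_fraction: float
    mean_G_over_raised: float


def simulate_type1(
    design: DesignSpec,
    rule: SsaRule,
    theta: float,
    n_sims: int,
    seed: int,
) -> SimulationReport:
    """Simulate ``n_sims`` trials of i.i.d. unit-variance normal observations
    with mean ``theta`` under the given raise rule; report the final
    rejection rate (type-I error at ``theta = 0``, power otherwise).

    Per trial the interim block sum, the planned remainder sum and the raise
    increment sum are drawn as exact normal sufficient statistics of the
    underlying observations; the raise increment enters the final statistic
    only when the rule fires.  Draws are chunked at a frozen size so results
    depend only on the seed.
    """
    if n_sims < 10_000:
        raise ConfigurationError(f"n_sims must be >= 10^4, got {n_sims}")
    n, N0 = design.n, design.N0
    r = rule.r if rule.rule_kind != "never_raise" else 0.0
    thr = rule.threshold(design)
    z_a = design.z_alpha
    rng = np.random.default_rng(seed)

    rejections = 0
    n_raised = 0
    g_sum = 0.0
    done = 0
    while done < n_sims:
        m = min(_CHUNK, n_sims - done)
        s_interim = rng.normal(n * theta, math.sqrt(n), m)
        s_planned = rng.normal((N0 - n) * theta, math.sqrt(N0 - n), m)
        s_extra = (
            rng.normal(r * theta, math.sqrt(r), m) if r > 0 else np.zeros(m)
        )
        z_interim = s_interim / math.sqrt(n)
        raised = z_interim >= thr
        n_final = np.where(raised, N0 + r, N0)
        z_final = (s_interim + s_planned + np.where(raised, s_extra, 0.0)) / np.sqrt(
            n_final
        )
        rejections += int(np.sum(z_final > z_a))
        n_raised += int(np.sum(raised))
        if r > 0 and raised.any():
            g_sum += float(
                np.sum(g_normal(z_interim[raised], n, N0, r, design.alpha))
            )
        done += m

    p = rejections / n_sims
    return SimulationReport(
        n_sims=n_sims,
        seed=seed,
        rejection_rate=p,
        mc_se=math.sqrt(p * (1.0 - p) / n_sims),
        raise_fraction=n_raised / n_sims,
        mean_G_over_raised=(g_sum / n_raised) if n_raised else float("nan"),
    )


def exact_type1_by_quadrature(design: DesignSpec, rule: SsaRule) -> float:
    """Exact unconditional level of a deterministic threshold rule:
    ``int A(z) phi(z) dz`` where ``A`` is the conditional error of the final
    size the rule selects at ``z``.  ``never_raise`` returns ``alpha`` to
    quadrature tolerance; ``derived_bound`` never exceeds it."""
    thr = rule.threshold(design)
    n, N0, alpha = design.n, design.N0, design.alpha
    opts = dict(epsabs=1e-10, epsrel=1e-10, limit=200)

    def below(z):
        return conditional_error(z, n, N0, alpha) * norm.pdf(z)

    def above(z):
        return conditional_error_raised(z, n, N0, rule.r, alpha) * norm.pdf(z)

    total = 0.0
    if thr > -math.inf:  # region where the design stays at N0
        hi = thr if thr < math.inf else math.inf
        total += integrate.quad(below, -math.inf, hi, **opts)[0]
    if thr < math.inf:  # region where the rule raises to N0 + r
        lo = thr if thr > -math.inf else -math.inf
        total += integrate.quad(above, lo, math.inf, **opts)[0]
    return total


@dataclass(frozen=True)
class TrialFixture:
    """Raw synthetic trial: all N0 + r observations plus the statistics a
    test needs — reproducible from the seed."""

    observations: np.ndarray
    z_interim: float
    z_final_planned: float
    z_final_raised: float
    design: DesignSpec
    theta: float
    seed: int


def generate_trial_fixture(design: DesignSpec, theta: float, seed: int) -> TrialFixture:
    """Draw one full synthetic trial (``N0 + r`` observations, ``r`` must be a
    whole number here) and precompute the interim and both final statistics."""
    r = design.r
    if r != int(r) or r <= 0:
        raise ConfigurationError(
            f"fixture generation needs a whole-number raise r >= 1, got {r}"
        )
    r = int(r)
    rng = np.random.default_rng(seed)
    obs = rng.normal(theta, 1.0, design.N0 + r)
    n, N0 = design.n, design.N0
    return TrialFixture(
        observations=obs,
        z_interim=float(obs[:n].sum() / math.sqrt(n)),
        z_final_planned=float(obs[:N0].sum() / math.sqrt(N0)),
        z_final_raised=float(obs.sum() / math.sqrt(N0 + r)),
        design=design,
        theta=theta,
        seed=seed,
    )
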
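"""Survival-endpoint support: Weibull lifetimes under exponential right
censoring, the Edgeworth-expansion ingredients for the standardized
product-limit (Kaplan-Meier) estimator, and the logrank interim statistic.

The lifetime is ``X ~ Weibull(lam, beta)`` with survival ``exp(-lam y^beta)``
and the censoring time ``Y ~ Exp(mu)`` (no left truncation).  With
``Z = min(X, Y)`` and the event indicator ``delta = 1{X <= Y}``:

* ``C(y)  = Pr(Z >= y) = exp(-mu y - lam y^beta)`` — the at-risk probability,
* ``W1(y) = Pr(Z <= y, delta = 1)`` — the sub-distribution of observed events,
* ``sigma1(z) = int_0^z dW1/C^2`` — the asymptotic variance functional,
* ``kappa3 = (-7.5 sigma1^4 + int_0^z C^-3 dW1) / sigma1`` — the skewness
  constant of the one-term Edgeworth correction

    Phi(x) - phi(x) * kappa3 (x^2 - 1) / (6 sqrt(n)),

  which quantifies how far the standardized estimator's law sits from the
  normal at interim size ``n``; the correction vanishes at rate 1/sqrt(n), so
  the normal-theory promising-zone criterion applies asymptotically.  An
  alternative form of the correction carries an extra ``+3 sigma1`` inside the
  polynomial; both are exposed through the ``variant`` flag ("results" — the
  default — omits it, "methods" includes it).  The grouping of the kappa3
  expression is itself reconstructed from an ambiguous source; see
  docs/methods.md before leaning on its absolute value.

For two-arm comparisons the interim statistic is the logrank z computed from
an at-risk/event table, asymptotically standard normal under equal hazards —
feed it to :func:`ssrzone.core_normal.decide`.  The remainder of a trial can
also be simulated outright (:func:`simulate_remainder`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

from .exceptions import DegenerateTableError, DesignError

__all__ = [
    "SurvivalModel",
    "LogrankTable",
    "RemainderSimReport",
    "c_func",
    "w1_func",
    "w0_func",
    "sigma1_func",
    "kappa3_tilde",
    "edgeworth_cdf",
    "logrank_z",
    "simulate_remainder",
]

_QUAD_OPTS = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


@dataclass(frozen=True)
class SurvivalModel:
    """Weibull(lam, beta) lifetime with Exp(mu) right censoring."""

    lam: float
    beta: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.beta <= 0:
            raise DesignError(
                f"Weibull parameters must be positive, got lam={self.lam}, beta={self.beta}"
            )
        if self.mu < 0:
            raise DesignError(f"censoring rate mu must be >= 0, got {self.mu}")

    def sample_lifetimes(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draw: X = (E/lam)^(1/beta), E ~ Exp(1)."""
        return (rng.exponential(1.0, size) / self.lam) ** (1.0 / self.beta)

    def sample_censoring(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.mu == 0.0:
            return np.full(size, np.inf)
        return rng.exponential(1.0 / self.mu, size)


def _check_time(y) -> None:
    if np.any(np.asarray(y) < 0):
        raise DesignError(f"time must be >= 0, got {y}")


def c_func(y, model: SurvivalModel):
    """At-risk probability ``C(y) = Pr(Z >= y) = exp(-mu y - lam y^beta)``."""
    _check_time(y)
    y = np.asarray(y, dtype=float)
    return np.exp(-model.mu * y - model.lam * y**model.beta)[()]


def _quad_sub(f, upper: float) -> float:
    """Integrate f(u) du on [0, upper] with the quadrature tolerances fixed
    for the package."""
    if upper == 0.0:
        return 0.0
    val, _ = integrate.quad(f, 0.0, upper, **_QUAD_OPTS)
    return val


def w1_func(y, model: SurvivalModel) -> float:
    """Observed-event sub-distribution ``W1(y) = Pr(Z <= y, delta = 1)``.

    Computed on the substituted scale ``u = x^beta`` so the integrand is
    bounded at 0 for every ``beta`` (the raw integrand has an integrable
    singularity there when ``beta < 1``)::

        W1(y) = int_0^{y^beta} lam exp(-mu u^{1/beta} - lam u) du
    """
    _check_time(y)
    lam, beta, mu = model.lam, model.beta, model.mu
    return _quad_sub(
        lambda u: lam * math.exp(-mu * u ** (1.0 / beta) - lam * u),
        float(y) ** beta,
    )


def w0_func(y, model: SurvivalModel) -> float:
    """Censored-mass counterpart ``Pr(Z <= y, delta = 0)``; together with
    ``W1`` it accounts for everything that has left the risk set:
    ``W0(y) + W1(y) = 1 - C(y)``."""
    _check_time(y)
    lam, beta, mu = model.lam, model.beta, model.mu
    if mu == 0.0:
        return 0.0
    val, _ = integrate.quad(
        lambda x: mu * math.exp(-mu * x - lam * x**beta), 0.0, float(y), **_QUAD_OPTS
    )
    return val


def sigma1_func(z, model: SurvivalModel) -> float:
    """Variance functional ``sigma1(z) = int_0^z dW1/C^2``; non-decreasing,
    zero at zero.  Refuses tail evaluation where ``C(z) < 1e-8`` — the
    integrand blows up as the risk set empties."""
    _check_time(z)
    if c_func(z, model) < 1e-8:
        raise DesignError(
            f"sigma1 is numerically unstable at z={z}: at-risk probability "
            f"C(z) < 1e-8"
        )
    lam, beta, mu = model.lam, model.beta, model.mu
    # dW1/C^2 = lam*beta*x^(beta-1) exp(mu x + lam x^beta) dx; u = x^beta
    return _quad_sub(
        lambda u: lam * math.exp(mu * u ** (1.0 / beta) + lam * u),
        float(z) ** beta,
    )


def _c3_integral(z, model: SurvivalModel) -> float:
    """``int_0^z C^-3 dW1`` on the substituted scale."""
    lam, beta, mu = model.lam, model.beta, model.mu
    return _quad_sub(
        lambda u: lam * math.exp(2.0 * mu * u ** (1.0 / beta) + 2.0 * lam * u),
        float(z) ** beta,
    )


def kappa3_tilde(z, model: SurvivalModel, variant: str = "results") -> float:
    """Skewness constant ``(-7.5 sigma1(z)^4 + int_0^z C^-3 dW1) / sigma1(z)``.

    ``variant`` is accepted for interface symmetry with
    :func:`edgeworth_cdf`; it does not change this value — the two expansion
    variants differ only inside the Edgeworth polynomial."""
    _variant_check(variant)
    _check_time(z)
    s1 = sigma1_func(z, model)
    if s1 <= 0.0:
        raise DesignError(f"kappa3 undefined where sigma1(z) = 0 (z={z})")
    return (-7.5 * s1**4 + _c3_integral(z, model)) / s1


def _variant_check(variant: str) -> None:
    if variant not in ("results", "methods"):
        raise DesignError(f"variant must be 'results' or 'methods', got {variant!r}")


def edgeworth_cdf(x, n: int, z, model: SurvivalModel, variant: str = "results"):
    """One-term Edgeworth approximation to the CDF of the standardized
    product-limit estimator at interim size ``n``.

    * ``variant="results"`` (default): ``Phi(x) - phi(x) kappa3 (x^2-1)/(6 sqrt(n))``
    * ``variant="methods"``: the same with ``kappa3 (x^2-1) + 3 sigma1(z)``
      inside the bracket.

    The raw expansion can exit [0, 1] for extreme ``x`` or heavy skewness; the
    return value is clipped there with a warning."""
    _variant_check(variant)
    if n < 1:
        raise DesignError(f"n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    k3 = kappa3_tilde(z, model)
    bracket = k3 * (x**2 - 1.0)
    if variant == "methods":
        bracket = bracket + 3.0 * sigma1_func(z, model)
    raw = norm.cdf(x) - norm.pdf(x) * bracket / (6.0 * math.sqrt(n))
    if np.any(raw < 0.0) or np.any(raw > 1.0):
        import warnings

        warnings.warn(
            "Edgeworth expansion left [0, 1]; value clipped", stacklevel=2
        )
    return np.clip(raw, 0.0, 1.0)[()]


# ---------------------------------------------------------------------------
# logrank machinery


@dataclass(frozen=True)
class LogrankTable:
    """Per-event-time at-risk and event counts for a two-arm comparison.

    One row per distinct event time, ascending: at-risk counts ``r_A``,
    ``r_C`` and event counts ``o_A``, ``o_C`` for the active and control arms.
    Tied events at one time stay in one row — the variance term
    ``o(r-o) r_A r_C / ((r-1) r^2)`` is the tie-corrected form."""

    time: np.ndarray
    r_A: np.ndarray
    r_C: np.ndarray
    o_A: np.ndarray
    o_C: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            name: np.asarray(getattr(self, name))
            for name in ("time", "r_A", "r_C", "o_A", "o_C")
        }
        sizes = {a.shape for a in arrays.values()}
        if len(sizes) != 1 or arrays["time"].ndim != 1:
            raise DegenerateTableError("table columns must be equal-length 1-D arrays")
        for name, arr in arrays.items():
            object.__setattr__(
                self, name, arr.astype(float if name == "time" else int)
            )
        if np.any(np.diff(self.time) <= 0):
            raise DegenerateTableError("event times must be strictly ascending")
        for arm in ("A", "C"):
            o = getattr(self, f"o_{arm}")
            r = getattr(self, f"r_{arm}")
            if np.any(o < 0) or np.any(o > r):
                raise DegenerateTableError(f"need 0 <= o_{arm} <= r_{arm} per row")
            if np.any(np.diff(r) > 0):
                raise DegenerateTableError(
                    f"at-risk counts r_{arm} must be non-increasing over time"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LogrankTable":
        cols = ["time", "r_A", "r_C", "o_A", "o_C"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DegenerateTableError(f"table is missing columns {missing}")
        df = df.sort_values("time")
        return cls(*(df[c].to_numpy() for c in cols))

    @classmethod
    def from_csv(cls, path) -> "LogrankTable":
        return cls.from_dataframe(pd.read_csv(path))

    @classmethod
    def from_raw(
        cls, time: np.ndarray, event: np.ndarray, is_active: np.ndarray
    ) -> "LogrankTable":
        """Build the table from subject-level data: observation times, event
        indicators (1 = event, 0 = censored) and arm membership."""
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        is_active = np.asarray(is_active, dtype=bool)
        t, rA, rC, oA, oC = _table_arrays(time, event, is_active)
        if len(t) == 0:
            raise DegenerateTableError("no events observed")
        return cls(t, rA, rC, oA, oC)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "r_A": self.r_A,
                "r_C": self.r_C,
                "o_A": self.o_A,
                "o_C": self.o_C,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _table_arrays(time, event, is_active):
    """Distinct event times with per-arm at-risk and event counts (numpy only,
    shared by the table constructor and the trial simulator)."""
    evt_times = np.unique(time[event])
    tA = np.sort(time[is_active])
    tC = np.sort(time[~is_active])
    rA = len(tA) - np.searchsorted(tA, evt_times, side="left")
    rC = len(tC) - np.searchsorted(tC, evt_times, side="left")
    eA = time[event & is_active]
    eC = time[event & ~is_active]
    oA = np.searchsorted(np.sort(eA), evt_times, side="right") - np.searchsorted(
        np.sort(eA), evt_times, side="left"
    )
    oC = np.searchsorted(np.sort(eC), evt_times, side="right") - np.searchsorted(
        np.sort(eC), evt_times, side="left"
    )
    return evt_times, rA, rC, oA, oC


def _logrank_components(rA, rC, oA, oC) -> tuple[float, float]:
    r = rA + rC
    o = oA + oC
    T = float(np.sum((rA * oC - rC * oA) / r))
    # rows with r < 2 carry no variance information (o(r-o) = 0 there anyway)
    denom_ok = r >= 2
    V = float(
        np.sum(
            (o * (r - o) * rA * rC)[denom_ok]
            / ((r - 1.0) * r**2)[denom_ok]
        )
    )
    return T, V


def logrank_z(table: LogrankTable) -> float:
    """Standardized logrank statistic ``z = T / sqrt(V)`` with

        T = sum_i (r_iA o_iC - r_iC o_iA) / r_i,
        V = sum_i o_i (r_i - o_i) r_iA r_iC / ((r_i - 1) r_i^2).

    Positive values favour the active arm (fewer events than expected there).
    Asymptotically standard normal under equal hazards; feed it to the
    promising-zone criterion as the interim statistic."""
    T, V = _logrank_components(table.r_A, table.r_C, table.o_A, table.o_C)
    if V <= 0.0:
        raise DegenerateTableError(
            "logrank variance is zero — no informative event time in the table"
        )
    return T / math.sqrt(V)


@dataclass(frozen=True)
class RemainderSimReport:
    """Monte-Carlo estimate of the probability the final logrank test rejects."""

    rejection_rate: float
    mc_se: float
    n_sims: int
    seed: int


def simulate_remainder(
    model_active: SurvivalModel,
    model_control: SurvivalModel,
    n_per_arm: int,
    n_sims: int,
    seed: int,
    alpha: float = 0.025,
    interim_table: LogrankTable | None = None,
) -> RemainderSimReport:
    """Simulate the remainder of a survival trial and estimate the
    probability that the final logrank test rejects at one-sided ``alpha``.

    Each replicate enrols ``n_per_arm`` fresh subjects per arm from the given
    lifetime/censoring models and computes the logrank ``(T, V)`` sums.  When
    an interim table is supplied its sums are added to the simulated ones —
    the logrank statistic is a sum of per-event-time increments, so interim
    and future contributions combine additively — and the merged statistic is
    compared with ``z_alpha``.  Without a table this is a fresh-trial power
    (or, with identical arms, size) estimate.
    """
    if n_per_arm < 1 or n_sims < 1:
        raise DesignError("n_per_arm and n_sims must be >= 1")
    if not 0.0 < alpha < 0.5:
        raise DesignError(f"one-sided alpha must lie in (0, 0.5), got {alpha}")
    T0, V0 = (0.0, 0.0)
    if interim_table is not None:
        T0, V0 = _logrank_components(
            interim_table.r_A, interim_table.r_C, interim_table.o_A, interim_table.o_C
        )
    z_a = float(norm.ppf(1.0 - alpha))
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        xA = model_active.sample_lifetimes(n_per_arm, rng)
        yA = model_active.sample_censoring(n_per_arm, rng)
        xC = model_control.sample_lifetimes(n_per_arm, rng)
        yC = model_control.sample_censoring(n_per_arm, rng)
        time = np.concatenate([np.minimum(xA, yA), np.minimum(xC, yC)])
        event = np.concatenate([xA <= yA, xC <= yC])
        is_active = np.zeros(2 * n_per_arm, dtype=bool)
        is_active[:n_per_arm] = True
        t, rA, rC, oA, oC = _table_arrays(time, event, is_active)
        if len(t) == 0 and V0 == 0.0:
            continue  # no information at all: cannot reject
        T, V = _logrank_components(rA, rC, oA, oC) if len(t) else (0.0, 0.0)
        Vtot = V + V0
        if Vtot <= 0.0:
            continue
        if (T + T0) / math.sqrt(Vtot) > z_a:
            rejections += 1
    p = rejections / n_sims
    return RemainderSimReport(
        rejection_rate=p,
        mc_se=math.sqrt(p * (1.0 - p) / n_sims),
        n_sims=n_sims,
        seed=seed,
    )
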
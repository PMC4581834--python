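"""Expected ℓ-HAF scores under neutral and sweep models.

Three regimes are covered:

* constant population size — closed form E[ℓ-HAF] = (θ/n) Σ_{w=1}^{n-1} w^ℓ,
  which follows from E[ξ_w] = θ/w, plus an independent epoch/rising-factorial
  derivation used as an exact rational cross-check;
* exponential growth — epoch durations solved by a backward conditional-
  expectation recursion involving the exponential integral E₁, combined with
  clade-size moments through Stirling numbers of the second kind;
* an ongoing hard sweep — carrier and non-carrier 1-HAF expectations as a
  function of the carrier fraction ν, and the pre-fixation peak.

Clade-size moments: during the epoch with k ancestral lineages, the sample is
partitioned into k clades whose sizes W_{k,i} satisfy
E[(W_{k,i})^{(ℓ)}] = ℓ! n^{(ℓ)} / k^{(ℓ)} (rising factorials), from which
ordinary moments follow via w^ℓ = Σ_q (-1)^{ℓ-q} S(ℓ,q) w^{(q)}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import exp1

from .params import DemographyParams, WrongRegimeError

__all__ = [
    "rising_factorial",
    "stirling2",
    "expected_w_rising",
    "expected_w_power",
    "expected_ell_haf_constant",
    "expected_ell_haf_constant_epoch",
    "EpochTimes",
    "epoch_times_exponential",
    "expected_ell_haf_exponential",
    "SweepState",
    "expected_haf_carrier",
    "expected_haf_noncarrier",
    "haf_peak",
    "expx_e1",
]


# ---------------------------------------------------------------- combinatorics

def rising_factorial(w: int, ell: int) -> int:
    """w^(ℓ) = w (w+1) ... (w+ℓ-1), with w^(0) = 1."""
    if ell < 0:
        raise ValueError(f"ell must be >= 0, got {ell}")
    out = 1
    for i in range(ell):
        out *= w + i
    return out


@lru_cache(maxsize=None)
def stirling2(ell: int, q: int) -> int:
    """Stirling number of the second kind S(ℓ, q), by recurrence."""
    if ell < 0 or q < 0:
        raise ValueError("arguments must be non-negative")
    if ell == q:
        return 1
    if q == 0 or q > ell:
        return 0
    return q * stirling2(ell - 1, q) + stirling2(ell - 1, q - 1)


def _check_epoch(n: int, k: int) -> None:
    if not 2 <= k <= n:
        raise ValueError(f"epoch index k must satisfy 2 <= k <= n, got k={k}, n={n}")


def expected_w_rising(n: int, k: int, ell: int) -> Fraction:
    """E[(W_{k,i})^(ℓ)] = ℓ! n^(ℓ) / k^(ℓ) — rising-factorial clade-size moment."""
    _check_epoch(n, k)
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    return Fraction(
        math.factorial(ell) * rising_factorial(n, ell), rising_factorial(k, ell)
    )


def expected_w_power(n: int, k: int, ell: int) -> Fraction:
    """Ordinary moment E[(W_{k,i})^ℓ] via the Stirling-number conversion."""
    _check_epoch(n, k)
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    total = Fraction(0)
    for q in range(1, ell + 1):
        total += (-1) ** (ell - q) * stirling2(ell, q) * expected_w_rising(n, k, q)
    return total


# ------------------------------------------------------- constant-size neutral

def expected_ell_haf_constant(params: DemographyParams, ell: int = 1) -> float:
    """E[ℓ-HAF] = (θ/n) Σ_{w=1}^{n-1} w^ℓ under neutrality, constant size.

    For ℓ=1 this is θ(n-1)/2; for ℓ=2, θ(n-1)(2n-1)/6.
    """
    if params.alpha != 0:
        raise WrongRegimeError(
            "alpha != 0: use expected_ell_haf_exponential for growing populations"
        )
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    n = params.n
    return params.theta / n * sum(w**ell for w in range(1, n))


def expected_ell_haf_constant_epoch(theta, n: int, ell: int = 1) -> Fraction:
    """Constant-size E[ℓ-HAF] by the epoch decomposition, exact rationals.

    Sums (1/n) Σ_k k · E[M_{k,i}] · E[W_{k,i}^{ℓ+1}] with
    E[M_{k,i}] = θ/(k(k-1)) (constant-size epoch durations).  Independent of
    the SFS route; agrees with ``expected_ell_haf_constant`` exactly.
    """
    th = Fraction(theta)
    total = Fraction(0)
    for k in range(2, n + 1):
        total += k * Fraction(th, k * (k - 1)) * expected_w_power(n, k, ell + 1)
    return total / n


# ------------------------------------------------------------ exponential E1

def expx_e1(x: float) -> float:
    """e^x · E1(x), overflow-safe for large x.

    scipy's exp1 underflows beyond x ~ 700; for x >= 500 a Lentz-style
    continued fraction for e^x E1(x) = 1/(x+1- 1/(x+3- 4/(x+5- 9/(...))))
    is evaluated directly.  Relative accuracy ~1e-14 across the switchover.
    """
    if x <= 0:
        raise ValueError(f"x must be > 0, got {x}")
    if x < 500.0:
        return float(np.exp(x) * exp1(x))
    b = x + 1.0
    c = 1e308
    d = 1.0 / b
    h = d
    for i in range(1, 500):
        a = -float(i * i)
        b += 2.0
        d = 1.0 / (b + a * d)
        c = b + a / c
        delta = c * d
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return h


@dataclass
class EpochTimes:
    """Expected epoch durations under exponential growth.

    ``t[k]`` is the expected span (in generations) of the epoch with exactly
    k lineages, k = 2..n; ``tau[k]`` = t_{k+1} + ... + t_n is the cumulative
    time from the present back to the start of epoch k (tau[n] = 0).
    ``scaled`` holds the dimensionless products r·t_k actually used by the
    ℓ-HAF expectation (independent of N₀).
    """

    t: dict[int, float]
    tau: dict[int, float]
    scaled: dict[int, float]


def epoch_times_exponential(params: DemographyParams) -> EpochTimes:
    """Conditional-expectation epoch durations under exponential growth.

    Evaluated in order k = n, n-1, ..., 2:
        r·t_k = e^{x_k} E1(x_k),   x_k = k(k-1) e^{r·τ_k} / α,
    where τ_k accumulates the younger epochs.  The population shrinks
    backward in time, so the late (small-k) epochs are short.
    """
    if params.alpha <= 0:
        raise WrongRegimeError("alpha <= 0: constant-size epochs are 2N/(k(k-1))")
    n, alpha = params.n, params.alpha
    r = params.growth_rate
    scaled: dict[int, float] = {}
    t: dict[int, float] = {}
    tau: dict[int, float] = {}
    rtau = 0.0
    for k in range(n, 1, -1):
        tau[k] = rtau / r
        x = k * (k - 1) * math.exp(rtau) / alpha
        u = expx_e1(x)
        scaled[k] = u
        t[k] = u / r
        rtau += u
    return EpochTimes(t=t, tau=tau, scaled=scaled)


def expected_ell_haf_exponential(params: DemographyParams, ell: int = 1) -> float:
    """E[ℓ-HAF] under neutral exponential growth (scaled rate α = 2N₀r).

    (θ/α) Σ_{k=2}^{n} (r t_k) Σ_{q=0}^{ℓ} (-1)^{ℓ-q} S(ℓ,q)
        [ (q+1)! (n+1)^(q)/(k+1)^(q)  -  q·q! (n+1)^(q-1)/(k+1)^(q-1) ].

    Stirling numbers and rising factorials are exact; only the E₁ evaluation
    is floating point.  For θ=48, n=200, α=80, ℓ=1 this gives 126.9.
    """
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    epochs = epoch_times_exponential(params)
    n = params.n
    # inner combinatorial factor depends on k only
    total = 0.0
    for k in range(2, n + 1):
        inner = 0.0
        for q in range(0, ell + 1):
            s = stirling2(ell, q)
            if s == 0:
                continue
            t1 = Fraction(
                math.factorial(q + 1) * rising_factorial(n + 1, q),
                rising_factorial(k + 1, q),
            )
            if q >= 1:
                t2 = Fraction(
                    q * math.factorial(q) * rising_factorial(n + 1, q - 1),
                    rising_factorial(k + 1, q - 1),
                )
            else:
                t2 = Fraction(0)
            inner += (-1) ** (ell - q) * s * float(t1 - t2)
        total += epochs.scaled[k] * inner
    return params.theta / params.alpha * total


# ------------------------------------------------------------------ sweep phase

@dataclass
class SweepState:
    """Sample state mid-sweep: carrier fraction ν and selection strength."""

    nu: float
    s: float
    params: DemographyParams

    def __post_init__(self):
        if not 0 <= self.nu <= 1:
            raise ValueError(f"nu must be in [0, 1], got {self.nu}")
        if self.params.N * self.s < 10:
            warnings.warn(
                f"Ns = {self.params.N * self.s:.1f} < 10: the strong-selection "
                "approximation for sweep-phase HAF expectations may be poor",
                stacklevel=2,
            )


def expected_haf_carrier(state: SweepState) -> float:
    """E[1-HAF] of a random carrier at carrier fraction ν (strong selection).

    θn( (ν+1)/2 − 1/((1−ν)n + 1) ).  At ν = 1/n this reduces exactly to the
    neutral mean θ(n−1)/2: with a single carrier there is no information
    separating it from the rest of the sample.
    """
    n, theta, nu = state.params.n, state.params.theta, state.nu
    return theta * n * ((nu + 1.0) / 2.0 - 1.0 / ((1.0 - nu) * n + 1.0))


def expected_haf_noncarrier(state: SweepState) -> float:
    """E[1-HAF] of a random non-carrier at carrier fraction ν.

    θn( 1/2 + 1/(2n) − 1/((1−ν)n + 1) ); equals the carrier expectation at
    ν = 1/n and stays near the neutral mean throughout the sweep.
    """
    n, theta, nu = state.params.n, state.params.theta, state.nu
    if nu > (n - 1) / n:
        warnings.warn(
            f"nu = {nu:.4f} > (n-1)/n: essentially no non-carriers remain "
            "in a sample of this size",
            stacklevel=2,
        )
    return theta * n * (0.5 + 1.0 / (2.0 * n) - 1.0 / ((1.0 - nu) * n + 1.0))


def haf_peak(params: DemographyParams) -> float:
    """Peak of E[1-HAF^car(ν)] over ν ∈ [0,1]: θn (1 − 1/√(2n))² ≈ θn.

    The maximizing carrier fraction is ν* = 1 − (√(2n) − 1)/n, just short of
    fixation; the peak height does not depend on the selection coefficient.
    """
    n = params.n
    return params.theta * n * (1.0 - 1.0 / math.sqrt(2.0 * n)) ** 2
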
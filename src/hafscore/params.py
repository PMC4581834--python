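"""Population-genetic parameter containers.

Conventions (haploid population of size N):
  theta = 2*N*mu*L   population-scaled mutation rate of the whole region
  alpha = 2*N0*r     population-scaled exponential growth rate (0 = constant)
  rho   = 2*N*c*L    population-scaled recombination rate of the region
One coalescent time unit equals N generations; mutations fall on the
genealogy at rate theta/2 per lineage per unit.  Growth-rate conversions
(r = alpha / (2*N0), per generation) are centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass


class WrongRegimeError(ValueError):
    """A constant-size routine was called with growth parameters, or vice versa."""


@dataclass
class DemographyParams:
    theta: float
    n: int
    alpha: float = 0.0
    rho: float = 0.0
    N: int = 20_000
    window_length: float = 50_000.0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")

    @property
    def growth_rate(self) -> float:
        """Per-generation growth rate r = alpha / (2 N)."""
        return self.alpha / (2.0 * self.N)

    @property
    def mu_per_bp(self) -> float:
        """Per-bp per-generation mutation rate implied by theta."""
        return self.theta / (2.0 * self.N * self.window_length)

    @property
    def recomb_per_bp(self) -> float:
        """Per-bp per-generation crossover rate implied by rho."""
        return self.rho / (2.0 * self.N * self.window_length)


@dataclass
class SweepParams:
    """Selection parameters for forward Wright-Fisher sweep simulation.

    Haploid carriers receive half the diploid homozygote advantage: relative
    fitness 1 + s/2 (heterozygosity-0.5 convention).  nu0 is the favored
    allele's frequency at selection onset: 1/N gives a hard sweep (de novo
    single copy); larger values give a soft sweep from standing variation.
    """

    s: float
    nu0: float | None = None          # None -> hard sweep at 1/N
    favored_position: float | None = None   # bp; None -> window center
    max_restarts: int = 100_000

    def __post_init__(self):
        if not 0 <= self.s <= 1:
            raise ValueError(f"selection coefficient s must be in [0, 1], got {self.s}")
        if self.nu0 is not None and not 0 < self.nu0 < 1:
            raise ValueError(f"nu0 must be in (0, 1), got {self.nu0}")

    @property
    def haploid_advantage(self) -> float:
        return self.s / 2.0
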
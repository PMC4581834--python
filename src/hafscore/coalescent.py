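"""Neutral coalescent sample simulators (constant size and exponential growth).

The internal engine is a standard Kingman coalescent without recombination:
epoch k lasts Exp(k(k-1)/2) coalescent time units (N generations) under
constant size; under exponential growth the waiting times are obtained by
deterministic time rescaling of the same process.  Mutations fall as a
Poisson process at rate theta/2 per lineage per unit time (infinite sites,
positions uniform on the window) — the haploid convention theta = 2*N*mu*L.

Samples with recombination (rho > 0) are delegated to msprime behind the
same interface; those samples carry no single-tree genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .core import HaplotypeMatrix
from .genealogy import Genealogy
from .params import DemographyParams, SweepParams, WrongRegimeError

__all__ = ["SimulatedSample", "simulate_neutral", "simulate_exponential_growth"]


@dataclass
class SimulatedSample:
    """One simulated replicate: matrix plus provenance.

    ``genealogy`` is present only for non-recombining internal-engine runs;
    ``trajectory`` (favored-allele frequency per generation) only for
    forward sweep simulations.
    """

    matrix: HaplotypeMatrix
    params: DemographyParams
    seed: int
    genealogy: Optional[Genealogy] = None
    sweep: Optional[SweepParams] = None
    trajectory: Optional[np.ndarray] = None
    nu_at_sampling: Optional[float] = None
    generation: Optional[int] = None
    replicate: int = 0


def _draw_unique_positions(rng: np.random.Generator, size: int, length: float) -> np.ndarray:
    """Uniform infinite-sites positions; collisions redrawn (vanishingly rare)."""
    pos = rng.random(size) * length
    while len(np.unique(pos)) < size:
        dup = np.ones(size, dtype=bool)
        dup[np.unique(pos, return_index=True)[1]] = False
        pos[dup] = rng.random(int(dup.sum())) * length
    return pos


def _simulate_tree(params: DemographyParams, rng: np.random.Generator) -> Genealogy:
    """One genealogy with mutations under the (possibly rescaled) coalescent."""
    n = params.n
    k_vals = np.arange(n, 1, -1)
    pair_rates = k_vals * (k_vals - 1) / 2.0
    E = rng.exponential(1.0, size=n - 1)
    if params.alpha > 0:
        # deterministic time rescaling: N(t)/N0 = exp(-b t), b = alpha/2
        b = params.alpha / 2.0
        g = 1.0 + b * np.cumsum(E / pair_rates)
        taus = np.log(g) / b                      # epoch end times
    else:
        taus = np.cumsum(E / pair_rates)
    starts = np.concatenate([[0.0], taus[:-1]])
    dts = taus - starts

    # mutation counts per (epoch, lineage) in one flattened Poisson draw
    lam = np.repeat(params.theta / 2.0 * dts, k_vals)
    m_flat = rng.poisson(lam)
    epoch_of = np.repeat(np.arange(n - 1), k_vals)
    offsets = np.concatenate([[0], np.cumsum(k_vals)])

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    mut_nodes: list[int] = []
    mut_times: list[float] = []
    nz = np.flatnonzero(m_flat)
    by_epoch: dict[int, list[int]] = {}
    for f in nz:
        by_epoch.setdefault(int(epoch_of[f]), []).append(int(f))
    for j in range(n - 1):
        k = n - j
        for f in by_epoch.get(j, ()):
            slot = f - offsets[j]
            node = active[slot]
            cnt = int(m_flat[f])
            mut_nodes.extend([node] * cnt)
            mut_times.extend(rng.uniform(starts[j], taus[j], size=cnt))
        a, bidx = rng.choice(k, size=2, replace=False)
        if a > bidx:
            a, bidx = bidx, a
        new = n + j
        parent[active[a]] = new
        parent[active[bidx]] = new
        time[new] = taus[j]
        active[a] = new
        active.pop(bidx)
    positions = _draw_unique_positions(rng, len(mut_nodes), params.window_length)
    return Genealogy(
        n=n,
        parent=parent,
        time=time,
        mut_node=np.asarray(mut_nodes, dtype=np.int64),
        mut_position=positions,
        mut_time=np.asarray(mut_times),
    )


def _internal_stream(
    params: DemographyParams, reps: int, seed: int, record_genealogy: bool
) -> Iterator[SimulatedSample]:
    from .genealogy import genealogy_to_matrix

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for rep in range(reps):
        g = _simulate_tree(params, rng)
        matrix = genealogy_to_matrix(g)
        yield SimulatedSample(
            matrix=matrix,
            params=params,
            seed=seed,
            genealogy=g if record_genealogy else None,
            replicate=rep,
        )


def _msprime_stream(
    params: DemographyParams, reps: int, seed: int
) -> Iterator[SimulatedSample]:
    """Coalescent-with-recombination backend (msprime, haploid time scale)."""
    import msprime

    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(2))
    demography = msprime.Demography()
    demography.add_population(initial_size=params.N, growth_rate=params.growth_rate)
    reps_iter = msprime.sim_ancestry(
        samples=params.n,
        ploidy=1,
        demography=demography,
        sequence_length=params.window_length,
        recombination_rate=params.recomb_per_bp,
        num_replicates=reps,
        random_seed=anc_seed,
    )
    mut_rng = np.random.default_rng(mut_seed)
    n = params.n
    for rep, ts in enumerate(reps_iter):
        mts = msprime.sim_mutations(
            ts,
            rate=params.mu_per_bp,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)),
        )
        G = mts.genotype_matrix().T              # n x S, sites already position-ordered
        pos = np.array([s.position for s in mts.sites()])
        w = G.sum(axis=0)
        keep = (w > 0) & (w < n)
        matrix = HaplotypeMatrix(data=G[:, keep].astype(np.int8), positions=pos[keep])
        yield SimulatedSample(matrix=matrix, params=params, seed=seed, replicate=rep)


def simulate_neutral(
    params: DemographyParams, reps: int, seed: int, record_genealogy: bool = True
) -> Iterator[SimulatedSample]:
    """Stream of neutral constant-size samples.

    rho = 0 uses the internal engine (with full genealogy); rho > 0 delegates
    to msprime.  Reproducible from ``seed``.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if params.alpha != 0:
        raise WrongRegimeError("alpha != 0: use simulate_exponential_growth")
    if params.rho > 0:
        return _msprime_stream(params, reps, seed)
    return _internal_stream(params, reps, seed, record_genealogy)


def simulate_exponential_growth(
    params: DemographyParams, reps: int, seed: int, record_genealogy: bool = True
) -> Iterator[SimulatedSample]:
    """Stream of neutral samples from an exponentially growing population."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if params.alpha <= 0:
        raise WrongRegimeError("alpha must be > 0 for the growth simulator")
    if params.rho > 0:
        return _msprime_stream(params, reps, seed)
    return _internal_stream(params, reps, seed, record_genealogy)
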
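"""Forward Wright-Fisher simulation of selective sweeps with carrier truth.

The population is N haploid genomes evolving in a window of L bp.  Carriers
of the favored allele have relative viability 1 + s/2 (half the diploid
homozygote advantage, the heterozygosity-0.5 convention).  Each generation,
offspring pick a uniformly random parent (two parents and a single uniform
crossover with probability rho/(2N)), mutate at rate theta/(2N) new
infinite-sites mutations per genome, and survive viability selection.

The population starts at mutation-drift equilibrium: standing neutral
variation is seeded from a coalescent sample of all N genomes.  Hard sweeps
place a new favored mutation on one random genome (nu0 = 1/N); soft sweeps
from standing variation promote an existing neutral allele with frequency
closest to nu0.  Trajectories that lose the favored allele are restarted
with a fresh trajectory (the standing variation of the trial is kept); the
restart count is logged.

Genomes are stored as persistent nodes (parent reference plus the private
mutations or a crossover), so copying a genome is O(1) and full mutation
sets are resolved only for sampled individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core import HaplotypeMatrix
from .coalescent import SimulatedSample
from .params import DemographyParams, SweepParams

logger = logging.getLogger("hafscore")

__all__ = ["simulate_sweep_forward", "neutral_trajectory_mean"]

_ROOT = -1


class _GenomeStore:
    """Persistent genome DAG: mutation nodes and crossover nodes."""

    def __init__(self):
        self.parent: list[int] = []        # mutation node: single parent
        self.payload: list = []            # tuple of new positions
        self.xleft: dict[int, tuple[int, int, float]] = {}  # crossover nodes

    def add_mutation(self, parent: int, positions: tuple) -> int:
        self.parent.append(parent)
        self.payload.append(positions)
        return len(self.parent) - 1

    def add_crossover(self, left: int, right: int, breakpoint: float) -> int:
        self.parent.append(_ROOT)
        self.payload.append(None)
        nid = len(self.parent) - 1
        self.xleft[nid] = (left, right, breakpoint)
        return nid

    def resolve(self, ids: Sequence[int]) -> list[frozenset]:
        """Full mutation-position sets for the given genome ids."""
        memo: dict[int, frozenset] = {_ROOT: frozenset()}
        out = []
        for gid in ids:
            stack = [int(gid)]
            while stack:
                v = stack[-1]
                if v in memo:
                    stack.pop()
                    continue
                if v in self.xleft:
                    l, r, bp = self.xleft[v]
                    if l in memo and r in memo:
                        memo[v] = frozenset(
                            p for p in memo[l] if p < bp
                        ) | frozenset(p for p in memo[r] if p >= bp)
                        stack.pop()
                    else:
                        if r not in memo:
                            stack.append(r)
                        if l not in memo:
                            stack.append(l)
                else:
                    p = self.parent[v]
                    if p in memo:
                        memo[v] = memo[p] | frozenset(self.payload[v])
                        stack.pop()
                    else:
                        stack.append(p)
            out.append(memo[int(gid)])
        return out


def _equilibrium_population(dem: DemographyParams, seed: int) -> list[tuple]:
    """Standing variation for all N genomes via a neutral coalescent (msprime)."""
    import msprime

    demography = msprime.Demography()
    demography.add_population(initial_size=dem.N)
    ts = msprime.sim_ancestry(
        samples=dem.N,
        ploidy=1,
        demography=demography,
        sequence_length=dem.window_length,
        recombination_rate=dem.recomb_per_bp,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=dem.mu_per_bp,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    pos = np.array([s.position for s in mts.sites()])
    G = mts.genotype_matrix()                  # S x N
    return [tuple(pos[np.flatnonzero(G[:, i])]) for i in range(dem.N)]


def _sample_to_matrix(
    sets: list[frozenset], fav: np.ndarray, n: int
) -> HaplotypeMatrix:
    allpos = np.array(sorted(set().union(*sets))) if sets else np.zeros(0)
    data = np.zeros((n, len(allpos)), dtype=np.int8)
    for i, s in enumerate(sets):
        if s:
            data[i, np.searchsorted(allpos, np.fromiter(s, dtype=float))] = 1
    w = data.sum(axis=0, dtype=np.int64)
    keep = (w > 0) & (w < n)
    return HaplotypeMatrix(
        data=data[:, keep],
        positions=allpos[keep].astype(float),
        carrier_truth=fav,
    )


@dataclass
class _TrialResult:
    samples: dict[float, tuple[np.ndarray, np.ndarray, float, int]]
    trajectory: np.ndarray
    restarts: int


def _run_trial(
    dem: DemographyParams,
    sweep: SweepParams,
    n: int,
    thresholds: Sequence[float],
    init_genomes: list[tuple],
    rng: np.random.Generator,
    store: _GenomeStore,
    condition: bool,
    max_generations: int | None,
) -> _TrialResult:
    N = dem.N
    u_tot = dem.theta / 2.0 / N                # new mutations per genome per gen
    r_x = dem.rho / (2.0 * N)                  # crossover prob per offspring
    sig = sweep.haploid_advantage
    L = dem.window_length
    fav_pos = sweep.favored_position if sweep.favored_position is not None else L / 2.0
    nu0 = sweep.nu0 if sweep.nu0 is not None else 1.0 / N
    n_init = max(1, round(nu0 * N))
    if nu0 * N < 1:
        raise ValueError(f"nu0*N = {nu0 * N:.3g} < 1: no initial carrier")

    base_ids = np.array(
        [store.add_mutation(_ROOT, t) for t in init_genomes], dtype=np.int64
    )

    for restart in range(sweep.max_restarts):
        genome = base_ids.copy()
        fav = np.zeros(N, dtype=bool)
        if n_init == 1:
            origin = int(rng.integers(N))
            genome[origin] = store.add_mutation(int(genome[origin]), (fav_pos,))
            fav[origin] = True
            fpos = fav_pos
        else:
            # soft sweep: promote the standing neutral allele nearest nu0 in frequency
            counts: dict[float, int] = {}
            for t in init_genomes:
                for p in t:
                    counts[p] = counts.get(p, 0) + 1
            best = min(counts, key=lambda p: (abs(counts[p] - n_init), p))
            fav = np.array([best in t for t in init_genomes])
            fpos = best
        traj = []
        out: dict[float, tuple] = {}
        ti = 0
        gen = 0
        while True:
            k = int(fav.sum())
            nu = k / N
            traj.append(nu)
            if k == 0:
                if condition:
                    break                       # lost -> restart
                return _TrialResult(out, np.asarray(traj), restart)
            while ti < len(thresholds) and nu >= thresholds[ti]:
                idx = rng.choice(N, size=n, replace=False)
                out[thresholds[ti]] = (genome[idx].copy(), fav[idx].copy(), nu, gen)
                ti += 1
            done = ti >= len(thresholds) and (thresholds or k == N)
            if k == N and ti >= len(thresholds):
                done = True
            if max_generations is not None and gen >= max_generations:
                done = True
            if done:
                return _TrialResult(out, np.asarray(traj), restart)

            # --- one generation: random mating + crossover, then viability ---
            kept_parent = np.empty(N, dtype=np.int64)
            kept_fav = np.empty(N, dtype=bool)
            kept_x: dict[int, tuple[int, float]] = {}
            filled = 0
            while filled < N:
                batch = int((N - filled) * (1.0 + sig) * 1.1) + 8
                pa = rng.integers(0, N, size=batch)
                off_fav = fav[pa].copy()
                xmask = rng.random(batch) < r_x
                xsecond = None
                if xmask.any():
                    xi = np.flatnonzero(xmask)
                    pb = rng.integers(0, N, size=len(xi))
                    bps = rng.random(len(xi)) * L
                    take_right = fpos >= bps
                    off_fav[xi] = np.where(take_right, fav[pb], fav[pa[xi]])
                    xsecond = dict(zip(xi.tolist(), zip(pb.tolist(), bps.tolist())))
                accept = rng.random(batch) < (1.0 + sig * off_fav) / (1.0 + sig)
                acc = np.flatnonzero(accept)[: N - filled]
                sl = slice(filled, filled + len(acc))
                kept_parent[sl] = pa[acc]
                kept_fav[sl] = off_fav[acc]
                if xsecond is not None:
                    hits = np.isin(acc, np.fromiter(xsecond, dtype=np.int64))
                    for rank in np.flatnonzero(hits):
                        kept_x[filled + int(rank)] = xsecond[int(acc[rank])]
                filled += len(acc)
            new_genome = genome[kept_parent]
            for slot, (pb, bp) in kept_x.items():
                new_genome[slot] = store.add_crossover(
                    int(genome[kept_parent[slot]]), int(genome[pb]), bp
                )
            nm = rng.poisson(u_tot * N)
            if nm:
                who = rng.integers(0, N, size=nm)
                mpos = rng.random(nm) * L
                for w_, p_ in zip(who, mpos):
                    new_genome[w_] = store.add_mutation(int(new_genome[w_]), (float(p_),))
            genome = new_genome
            fav = kept_fav
            gen += 1
        if not condition:
            return _TrialResult(out, np.asarray(traj), restart)
    raise RuntimeError(
        f"favored allele lost in all {sweep.max_restarts} restarts; "
        "thresholds unreachable under these parameters"
    )


def simulate_sweep_forward(
    dem: DemographyParams,
    sweep: SweepParams,
    sample_times: Sequence[float],
    n: int,
    reps: int,
    seed: int,
    condition_on_growth: bool = True,
    max_generations: int | None = None,
) -> Iterator[SimulatedSample]:
    """Forward sweep samples taken as the favored allele crosses each threshold.

    ``sample_times`` are carrier-fraction thresholds in (0, 1]; each replicate
    yields one SimulatedSample per threshold reached (carrier_truth filled in,
    the trajectory attached to every sample of the replicate).  With
    ``condition_on_growth`` (hard-sweep conditioning), trajectories losing the
    favored allele restart with the trial's standing variation retained.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    thresholds = sorted(sample_times)
    if not all(0 < t <= 1 for t in thresholds):
        raise ValueError("sample thresholds must lie in (0, 1]")
    ss = np.random.SeedSequence(seed)
    total_restarts = 0
    for rep, child in enumerate(ss.spawn(reps)):
        state = child.generate_state(2)
        init_seed = int(state[0] % (2**31 - 2)) + 1
        rng = np.random.default_rng(np.random.SeedSequence(int(state[1] % 2**31)))
        init = _equilibrium_population(dem, init_seed)
        store = _GenomeStore()
        trial = _run_trial(
            dem, sweep, n, thresholds, init, rng, store,
            condition_on_growth, max_generations,
        )
        total_restarts += trial.restarts
        for thr in thresholds:
            if thr not in trial.samples:
                continue
            gids, favs, nu, gen = trial.samples[thr]
            matrix = _sample_to_matrix(store.resolve(gids), favs, n)
            yield SimulatedSample(
                matrix=matrix,
                params=dem,
                sweep=sweep,
                seed=seed,
                trajectory=trial.trajectory,
                nu_at_sampling=nu,
                generation=gen,
                replicate=rep,
            )
    if total_restarts:
        logger.info(
            "simulate_sweep_forward: %d restart(s) after loss of the favored allele "
            "across %d replicate(s)", total_restarts, reps,
        )


def sweep_trajectories(
    dem: DemographyParams,
    sweep: SweepParams,
    reps: int,
    seed: int,
    max_generations: int,
) -> np.ndarray:
    """Unconditioned favored-allele frequency trajectories from the full engine.

    Returns a (reps, max_generations+1) array; trajectories absorbed at loss
    or fixation are padded with 0 or 1.  Useful for drift/selection
    diagnostics (e.g. the s = 0 martingale property).
    """
    ss = np.random.SeedSequence(seed)
    out = np.empty((reps, max_generations + 1))
    for rep, child in enumerate(ss.spawn(reps)):
        state = child.generate_state(2)
        init = _equilibrium_population(dem, int(state[0] % (2**31 - 2)) + 1)
        rng = np.random.default_rng(np.random.SeedSequence(int(state[1] % 2**31)))
        trial = _run_trial(
            dem, sweep, min(dem.N, 2), [], init, rng, _GenomeStore(),
            condition=False, max_generations=max_generations,
        )
        t = trial.trajectory
        pad = 0.0 if t[-1] == 0 else (1.0 if t[-1] == 1.0 else t[-1])
        full = np.full(max_generations + 1, pad)
        full[: len(t)] = t[: max_generations + 1]
        out[rep] = full
    return out


def neutral_trajectory_mean(
    dem: DemographyParams, nu0: float, generations: int, reps: int, seed: int
) -> np.ndarray:
    """Mean favored-allele frequency trajectory with s = 0 (drift martingale).

    A pure frequency-level Wright-Fisher binomial resampling (no genomes),
    used to verify that the reproduction scheme is unbiased without selection.
    """
    rng = np.random.default_rng(seed)
    N = dem.N
    out = np.empty((reps, generations + 1))
    for rtrial in range(reps):
        k = round(nu0 * N)
        out[rtrial, 0] = k / N
        for g in range(1, generations + 1):
            k = rng.binomial(N, k / N)
            out[rtrial, g] = k / N
    return out.mean(axis=0)
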
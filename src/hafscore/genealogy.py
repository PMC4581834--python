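"""Coalescent genealogies with mutations, and their epoch decomposition.

A genealogy over n leaves is stored as a node table: leaves are nodes
0..n-1 at time 0; each coalescence creates a new internal node (n..2n-2) at
a strictly later time.  Mutations are (node, position, time) triples placed
on the edge above ``node``.

Epoch k (k = n..2) is the span during which exactly k ancestral lineages
exist.  The k lineages partition the leaves into k clades; a mutation on
lineage i of epoch k is shared by exactly the w_{k,i} leaves of that clade,
so every leaf's ℓ-HAF score decomposes as Σ_k m_k w_k^ℓ along its root path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Genealogy", "EpochRecord", "genealogy_epoch_decomposition",
           "reconstruct_scores", "genealogy_to_matrix"]


@dataclass
class Genealogy:
    """Binary coalescent tree with mutation placements.

    parent[v] is the parent node id (-1 for the root); time[v] the node time
    in coalescent units of N generations (leaves at 0).  ``mutations`` holds
    (node, position, time) with position in base pairs.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray
    mut_node: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mut_position: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mut_time: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def num_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def coalescence_times(self) -> np.ndarray:
        """The n-1 internal node times, ascending."""
        return np.sort(self.time[self.n:])

    def epoch_durations(self) -> dict[int, float]:
        """T_k for k = 2..n; their sum is the TMRCA."""
        ct = self.coalescence_times()
        bounds = np.concatenate([[0.0], ct])
        return {self.n - j: float(bounds[j + 1] - bounds[j]) for j in range(self.n - 1)}

    def leaf_intervals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Leaf ordering in which every clade is contiguous.

        Returns (order, lo, hi): ``order`` is a permutation of leaves;
        node v's clade is order[lo[v]:hi[v]].
        """
        nn = self.num_nodes
        children: list[list[int]] = [[] for _ in range(nn)]
        root = -1
        for v in range(nn):
            p = self.parent[v]
            if p < 0:
                root = v
            else:
                children[p].append(v)
        order = np.empty(self.n, dtype=np.int64)
        lo = np.zeros(nn, dtype=np.int64)
        hi = np.zeros(nn, dtype=np.int64)
        pos = 0
        stack = [(root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                hi[v] = pos
                continue
            lo[v] = pos
            stack.append((v, True))
            if v < self.n:
                order[pos] = v
                pos += 1
            else:
                for c in children[v]:
                    stack.append((c, False))
        return order, lo, hi

    def clade_sizes(self) -> np.ndarray:
        """Number of leaves below each node."""
        _, lo, hi = self.leaf_intervals()
        return hi - lo


@dataclass
class EpochRecord:
    """One lineage of one epoch: mutation count and clade size."""

    k: int
    lineage: int          # node id of the lineage
    m: int                # mutations on this lineage during epoch k
    w: int                # clade (subtended leaf) size


def genealogy_epoch_decomposition(g: Genealogy) -> list[EpochRecord]:
    """Per-epoch, per-lineage (m_{k,i}, w_{k,i}) table.

    Derived purely from node times, topology and mutation times, so it can
    serve as an independent route to the ℓ-HAF scores.  Raises ValueError
    if the structure is not a single binary tree (e.g. recombinant data).
    """
    n = g.n
    if g.parent.shape != (2 * n - 1,) or (g.parent < 0).sum() != 1:
        raise ValueError("epoch decomposition requires a single non-recombining tree")
    ct = g.coalescence_times()
    bounds = np.concatenate([[0.0], ct])          # epoch j spans bounds[j]..bounds[j+1]
    sizes = g.clade_sizes()
    root_time = ct[-1]

    # mutation epoch via its time: epoch index j has k = n - j lineages
    mut_epoch = np.searchsorted(ct, g.mut_time, side="left")  # j in 0..n-2
    records: dict[tuple[int, int], int] = {}

    # enumerate live lineages per epoch: node v is live in epoch j iff
    # time[v] <= bounds[j] and parent time > bounds[j] (root excluded)
    ptime = np.where(g.parent >= 0, g.time[np.maximum(g.parent, 0)], np.inf)
    for j in range(n - 1):
        k = n - j
        t0, t1 = bounds[j], bounds[j + 1]
        live = np.flatnonzero((g.time <= t0 + 1e-12) & (ptime > t0 + 1e-12))
        live = live[g.time[live] < root_time]      # root itself is never a lineage
        if len(live) != k:
            raise ValueError(f"epoch {k}: expected {k} live lineages, found {len(live)}")
        for v in live:
            records[(k, int(v))] = 0
    for node, j in zip(g.mut_node, mut_epoch):
        k = n - int(j)
        key = (k, int(node))
        if key not in records:
            raise ValueError(f"mutation on node {node} not live in epoch {k}")
        records[key] += 1
    return [
        EpochRecord(k=k, lineage=v, m=m, w=int(sizes[v]))
        for (k, v), m in sorted(records.items())
    ]


def reconstruct_scores(g: Genealogy, ell: int = 1) -> np.ndarray:
    """ℓ-HAF scores of all leaves via the epoch decomposition Σ_k m_k w_k^ℓ."""
    order, lo, hi = g.leaf_intervals()
    sizes = hi - lo
    scores = np.zeros(g.n, dtype=np.int64)
    for rec in genealogy_epoch_decomposition(g):
        if rec.m:
            leaves = order[lo[rec.lineage]:hi[rec.lineage]]
            scores[leaves] += rec.m * int(sizes[rec.lineage]) ** ell
    return scores


def genealogy_to_matrix(g: Genealogy):
    """Binary haplotype matrix implied by the genealogy's mutations.

    Columns are ordered by position; a column's carriers are the leaves of
    the mutated node's clade.  Fixed columns cannot arise (mutations sit on
    proper subtrees), so the result is already polymorphic-filtered.
    """
    from .core import HaplotypeMatrix

    order, lo, hi = g.leaf_intervals()
    idx = np.argsort(g.mut_position, kind="stable")
    S = len(idx)
    data = np.zeros((g.n, S), dtype=np.int8)
    for j, mi in enumerate(idx):
        v = g.mut_node[mi]
        data[order[lo[v]:hi[v]], j] = 1
    return HaplotypeMatrix(data=data, positions=g.mut_position[idx])
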
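"""Haplotype matrices and HAF (haplotype allele frequency) scores.

A *HAF vector* of a haplotype replaces each derived allele (1) in the binary
haplotype vector by the derived-allele count of that site in the sample, and
each ancestral allele (0) by 0.  The ℓ-HAF score is the sum of the ℓ-th powers
of the HAF-vector entries; 1-HAF is simply the sum of the sample frequencies
of all derived alleles the haplotype carries.  All frequencies here are
integer counts within the sample, so score arithmetic is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("hafscore")

__all__ = [
    "HaplotypeMatrix",
    "HAFResult",
    "SiteFrequencySpectrum",
    "filter_polymorphic",
    "haf_vectors",
    "ell_haf",
    "sfs",
    "mean_ell_haf_via_sfs",
    "normalized_ell_haf",
]


class InvalidInputError(ValueError):
    """Raised when a haplotype matrix or parameter violates its contract."""


@dataclass
class HaplotypeMatrix:
    """n x S binary matrix of polarized derived-allele states.

    Parameters
    ----------
    data
        Array of shape (n, S) with entries in {0, 1}; 1 marks the derived
        (non-ancestral) allele.
    positions
        S site coordinates in base pairs, strictly increasing.  Fractional
        coordinates are allowed (infinite-sites simulations).
    sample_ids
        n haplotype labels.  Defaults to ``hap0..hap{n-1}``.
    carrier_truth
        Optional boolean n-vector: True where the haplotype carries the
        favored allele (simulation ground truth or annotation).
    """

    data: np.ndarray
    positions: np.ndarray = None
    sample_ids: Sequence[str] = None
    carrier_truth: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidInputError("haplotype data must be a 2-D array")
        bad = (self.data != 0) & (self.data != 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise InvalidInputError(
                f"non-binary entry {self.data[r, c]!r} at row {r}, column {c}"
            )
        self.data = self.data.astype(np.int8, copy=False)
        n, S = self.data.shape
        if self.positions is None:
            self.positions = np.arange(S, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (S,):
            raise InvalidInputError("positions length must equal column count")
        if S > 1 and not np.all(np.diff(self.positions) > 0):
            raise InvalidInputError("positions must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = [f"hap{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise InvalidInputError("sample_ids length must equal row count")
        if self.carrier_truth is not None:
            self.carrier_truth = np.asarray(self.carrier_truth, dtype=bool)
            if self.carrier_truth.shape != (n,):
                raise InvalidInputError("carrier_truth length must equal row count")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def num_sites(self) -> int:
        return self.data.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Per-site derived-allele counts w_j (column sums)."""
        return self.data.sum(axis=0, dtype=np.int64)


@dataclass
class HAFResult:
    """Per-haplotype HAF vectors and ℓ-HAF scores for one sample."""

    haf_vectors: np.ndarray                      # n x S integer matrix
    scores: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def ell_values(self) -> list[int]:
        return sorted(self.scores)


@dataclass
class SiteFrequencySpectrum:
    """Counts xi_w of polymorphic sites at each derived count w = 1..n-1."""

    counts: np.ndarray
    n: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n < 1:
            raise InvalidInputError("sample size must be >= 1")
        if self.counts.shape != (max(self.n - 1, 0),):
            raise InvalidInputError("counts must have length n-1")

    @property
    def num_sites(self) -> int:
        return int(self.counts.sum())


def filter_polymorphic(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Drop sites fixed (w = n) or absent (w = 0) in the sample.

    Column order is preserved; positions, and nothing else, are subset.
    """
    w = matrix.derived_counts()
    keep = (w > 0) & (w < matrix.n)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_polymorphic: dropped %d non-polymorphic site(s)", dropped)
    return replace(
        matrix,
        data=matrix.data[:, keep],
        positions=matrix.positions[keep],
    )


def haf_vectors(matrix: HaplotypeMatrix) -> HAFResult:
    """HAF vectors: derived entries replaced by their sample counts.

    Expects a polymorphic-filtered matrix (every column count in 1..n-1).
    """
    w = matrix.derived_counts()
    vecs = matrix.data.astype(np.int64) * w[np.newaxis, :]
    return HAFResult(haf_vectors=vecs)


def ell_haf(matrix: HaplotypeMatrix, ell: int = 1) -> np.ndarray:
    """ℓ-HAF scores: score[v] = sum_j c_j^ℓ over the haplotype's HAF vector.

    Integer-exact; ℓ defaults to 1.
    """
    if ell < 1:
        raise InvalidInputError(f"ell must be a positive integer, got {ell}")
    w = matrix.derived_counts()
    # sum_{j: data[v,j]=1} w_j^ell as an integer matrix-vector product
    if matrix.num_sites == 0:
        return np.zeros(matrix.n, dtype=np.int64)
    wl = w.astype(object) ** ell if ell > 20 else (w.astype(np.int64) ** ell)
    return matrix.data.astype(np.int64) @ wl


def scores_from_result(result: HAFResult, ell: int = 1) -> np.ndarray:
    """ℓ-HAF from precomputed HAF vectors (sum of ℓ-th powers of entries)."""
    if ell < 1:
        raise InvalidInputError(f"ell must be a positive integer, got {ell}")
    v = result.haf_vectors
    if v.shape[1] == 0:
        return np.zeros(v.shape[0], dtype=np.int64)
    out = (v.astype(np.int64) ** ell).sum(axis=1)
    result.scores[ell] = out
    return out


def sfs(matrix: HaplotypeMatrix) -> SiteFrequencySpectrum:
    """Site frequency spectrum of a polymorphic-filtered matrix."""
    n = matrix.n
    w = matrix.derived_counts()
    counts = np.bincount(w, minlength=n + 1)[1:n] if n > 1 else np.zeros(0, int)
    return SiteFrequencySpectrum(counts=counts, n=n)


def mean_ell_haf_via_sfs(spectrum: SiteFrequencySpectrum, ell: int = 1) -> Fraction:
    """Sample-mean ℓ-HAF from the SFS: (1/n) * sum_w xi_w * w^(ℓ+1).

    Exact rational; identical to the mean of the per-haplotype scores.
    """
    if ell < 1:
        raise InvalidInputError(f"ell must be a positive integer, got {ell}")
    if spectrum.n == 0:
        raise InvalidInputError("empty spectrum: n = 0")
    total = sum(
        int(xi) * w ** (ell + 1)
        for w, xi in enumerate(spectrum.counts, start=1)
    )
    return Fraction(total, spectrum.n)


def normalized_ell_haf(scores: np.ndarray, ell: int) -> np.ndarray:
    """ℓ-th root transform ℓ-HAF^(1/ℓ), for cross-ℓ comparison plots."""
    return np.asarray(scores, dtype=float) ** (1.0 / ell)
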
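"""PreCIOSS: predicting carriers of an ongoing selective sweep.

Mid-sweep, haplotypes carrying the favored allele accumulate high-frequency
hitchhiking variation and therefore high 1-HAF scores, while non-carriers
stay near the neutral expectation.  PreCIOSS exploits this: it fits a
two-component Gaussian mixture to the in-sample ℓ-HAF scores by EM and
labels the haplotypes assigned to the higher-mean component as carriers.
No knowledge of the favored site is used.

Evaluation utilities: balanced accuracy (mean of sensitivity and
specificity, robust to the severe carrier/non-carrier class imbalance at
either end of a sweep) and the Wilcoxon rank-sum test of carrier vs
non-carrier score separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import HaplotypeMatrix, ell_haf

logger = logging.getLogger("hafscore")

__all__ = [
    "MixtureFit",
    "CarrierPrediction",
    "EvaluationResult",
    "fit_gmm_em",
    "predict_carriers",
    "balanced_accuracy",
    "carrier_separation_test",
    "rank_percentile",
]


class DegenerateInputError(ValueError):
    """All scores identical: no two-cluster structure to fit."""


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture fitted by EM."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray          # n x 2 posteriors
    loglik: float
    n_iter: int
    converged: bool
    n_restarts: int = 1
    best_restart: int = 0

    @property
    def low_confidence(self) -> bool:
        """True when the two means are closer than 2 max(sd): the two-cluster
        assumption is unsupported and labels are close to arbitrary."""
        return abs(self.means[0] - self.means[1]) < 2.0 * np.sqrt(self.variances.max())


@dataclass
class CarrierPrediction:
    labels: np.ndarray                    # boolean, True = carrier
    fit: MixtureFit
    scores: np.ndarray
    ell: int


@dataclass
class EvaluationResult:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    balanced_accuracy: Optional[float] = None
    wilcoxon_p: Optional[float] = None
    single_class_truth: bool = False


def _loglik(x, means, variances, weights):
    comp = weights * np.exp(
        -0.5 * (x[:, None] - means) ** 2 / variances
    ) / np.sqrt(2 * np.pi * variances)
    tot = comp.sum(axis=1)
    return float(np.log(np.maximum(tot, 1e-300)).sum()), comp


def _em_run(x, means, variances, weights, var_floor, max_iter, tol):
    prev = -np.inf
    resp = None
    for it in range(1, max_iter + 1):
        ll, comp = _loglik(x, means, variances, weights)
        resp = comp / np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
        nk = resp.sum(axis=0)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
        variances = np.maximum(variances, var_floor)
        if np.isfinite(prev) and abs(ll - prev) <= tol * max(abs(ll), 1.0):
            return means, variances, weights, resp, ll, it, True
        prev = ll
    ll, comp = _loglik(x, means, variances, weights)
    resp = comp / np.maximum(comp.sum(axis=1, keepdims=True), 1e-300)
    return means, variances, weights, resp, ll, max_iter, False


def fit_gmm_em(
    scores: Sequence[float],
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> MixtureFit:
    """Fit a two-component 1-D Gaussian mixture to HAF scores by EM.

    The first restart is deterministic (components seeded from the lower and
    upper median-split halves); the remaining restarts draw random initial
    responsibilities from the seeded generator.  The restart with the highest
    final log-likelihood wins.  A variance floor of 1e-6 x sample variance
    keeps components from collapsing onto duplicated scores.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError(f"need at least 4 finite scores, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    if np.ptp(x) == 0:
        raise DegenerateInputError(
            "all scores identical: no sweep structure for a two-component fit"
        )
    svar = float(x.var())
    var_floor = max(1e-6 * svar, 1e-12)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        if r == 0:
            med = np.median(x)
            lowm = x[x <= med]
            highm = x[x > med]
            if len(highm) == 0:                 # > half the scores tie at the median
                lowm, highm = x[x < med], x[x >= med]
            means = np.array([lowm.mean(), highm.mean()])
            variances = np.maximum(
                np.array([lowm.var(), highm.var()]), var_floor
            )
            weights = np.array([len(lowm), len(highm)], dtype=float) / len(x)
        else:
            resp0 = rng.dirichlet([1.0, 1.0], size=len(x))
            nk = resp0.sum(axis=0)
            means = (resp0 * x[:, None]).sum(axis=0) / nk
            variances = np.maximum(
                (resp0 * (x[:, None] - means) ** 2).sum(axis=0) / nk, var_floor
            )
            weights = nk / len(x)
        out = _em_run(x, means, variances, weights, var_floor, max_iter, tol)
        if best is None or out[4] > best[0][4]:
            best = (out, r)
    (means, variances, weights, resp, ll, n_iter, conv), r_best = best
    fit = MixtureFit(
        means=means, variances=variances, weights=weights,
        responsibilities=resp, loglik=ll, n_iter=n_iter, converged=conv,
        n_restarts=n_restarts, best_restart=r_best,
    )
    logger.debug("fit_gmm_em: best restart %d/%d, loglik %.3f, %d iter",
                 r_best, n_restarts, ll, n_iter)
    return fit


def predict_carriers(
    matrix: HaplotypeMatrix, ell: int = 1, seed: int = 0, **fit_kwargs
) -> CarrierPrediction:
    """Run PreCIOSS on a polymorphic-filtered haplotype matrix.

    Computes ℓ-HAF scores (ℓ = 1 by default), fits the mixture, assigns each
    haplotype to its maximum-posterior component, and labels the component
    with the larger mean as 'carrier'.  A posterior of exactly 0.5 goes to
    the carrier component.
    """
    if matrix.num_sites == 0:
        raise ValueError("no polymorphic sites: cannot score haplotypes")
    scores = ell_haf(matrix, ell)
    fit = fit_gmm_em(scores, seed=seed, **fit_kwargs)
    hi = int(np.argmax(fit.means))
    labels = fit.responsibilities[:, hi] >= 0.5
    if fit.low_confidence:
        warnings.warn(
            "mixture means closer than 2 max(sd): carrier labels are "
            "low-confidence (no clear sweep structure)", stacklevel=2,
        )
    return CarrierPrediction(labels=labels, fit=fit, scores=scores, ell=ell)


def balanced_accuracy(labels: Sequence[bool], truth: Sequence[bool]) -> EvaluationResult:
    """(sensitivity + specificity) / 2 of predicted vs true carrier status."""
    labels = np.asarray(labels, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    tp = int((labels & truth).sum())
    fn = int((~labels & truth).sum())
    tn = int((~labels & ~truth).sum())
    fp = int((labels & ~truth).sum())
    res = EvaluationResult(tp=tp, fp=fp, tn=tn, fn=fn)
    if tp + fn == 0 or tn + fp == 0:
        # single-class truth: report the one defined rate, flagged
        res.single_class_truth = True
        res.balanced_accuracy = (
            tp / (tp + fn) if tp + fn > 0 else tn / (tn + fp)
        )
        warnings.warn("truth contains a single class: reporting the defined "
                      "rate only", stacklevel=2)
        return res
    res.balanced_accuracy = 0.5 * (tp / (tp + fn) + tn / (fp + tn))
    return res


def carrier_separation_test(
    scores: Sequence[float], truth: Sequence[bool]
) -> EvaluationResult:
    """Two-sided Wilcoxon rank-sum test of carrier vs non-carrier scores.

    Exact enumeration when both groups have <= 20 observations and the data
    are tie-free; otherwise the tie-corrected normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    a, b = scores[truth], scores[~truth]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    has_ties = len(np.unique(scores)) < len(scores)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    stat = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    res = EvaluationResult(wilcoxon_p=float(stat.pvalue))
    return res


def rank_percentile(scores: Sequence[float]) -> np.ndarray:
    """In-sample percentile rank of each score (mid-rank ties), in [0, 100]."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        return np.zeros(0)
    ranks = stats.rankdata(scores, method="average")
    return (ranks - 0.5) / len(scores) * 100.0
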
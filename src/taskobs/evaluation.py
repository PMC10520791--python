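"""Observer scoring and figures of merit: empirical AUC, binormal AUC, SNR.

Scores are linear functionals of the images (inner products with a
template, possibly through a channel projection first).  The empirical AUC
is the Mann-Whitney statistic (ties take half credit); the binormal AUC
fits class-conditional Gaussians to the scores by moments and reports
``Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2))``, with an uncertainty from
a seeded nonparametric case bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .channels import ChannelizedObserver, channelize
from .hotelling import LinearObserver
from .object_models import PairedImageSet

__all__ = [
    "ScoreSet",
    "ROCSummary",
    "apply_observer",
    "score_dataset",
    "empirical_auc",
    "binormal_fit",
    "snr",
]


@dataclass
class ScoreSet:
    """Test statistics with binary hypothesis labels (0 = absent, 1 = present)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        return self.scores[self.labels == 0], self.scores[self.labels == 1]


@dataclass
class ROCSummary:
    """Empirical and binormal-fit AUC with binormal parameters.

    The binormal slope-intercept parametrization is ``a = (mu1 - mu0) /
    sigma1`` and ``b = sigma0 / sigma1``; ``auc_binormal =
    Phi(a / sqrt(1 + b^2))``.
    """

    auc_empirical: float
    auc_binormal: float
    mu0: float
    mu1: float
    sigma0: float
    sigma1: float
    auc_std: float
    degenerate: bool = False

    @property
    def a(self) -> float:
        return (self.mu1 - self.mu0) / self.sigma1

    @property
    def b(self) -> float:
        return self.sigma0 / self.sigma1


def apply_observer(observer: LinearObserver | ChannelizedObserver,
                   images: np.ndarray,
                   labels: np.ndarray) -> ScoreSet:
    """Score images with a linear or channelized observer."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if isinstance(observer, ChannelizedObserver):
        scores = channelize(observer.channels, images) @ observer.wv
    else:
        if images.shape[1] != observer.template.size:
            raise ValueError("image length does not match template")
        scores = images @ observer.template
    return ScoreSet(scores=scores, labels=labels)


def score_dataset(observer, dataset: PairedImageSet) -> ScoreSet:
    """Score the pooled images of a paired dataset."""
    images, labels = dataset.pooled()
    return apply_observer(observer, images, labels)


def empirical_auc(scores: ScoreSet) -> float:
    """Mann-Whitney AUC: fraction of (present, absent) pairs ranked
    correctly, ties counting one half."""
    s0, s1 = scores.split()
    if s0.size == 0 or s1.size == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(np.concatenate([s0, s1]))
    r1 = ranks[s0.size:].sum()
    return float((r1 - s1.size * (s1.size + 1) / 2.0) / (s0.size * s1.size))


def _binormal_auc(mu0, mu1, var0, var1) -> float:
    denom = np.sqrt(var0 + var1)
    if denom == 0.0:
        return 0.5
    return float(norm.cdf((mu1 - mu0) / denom))


def binormal_fit(scores: ScoreSet,
                 bootstrap_reps: int = 1000,
                 rng: np.random.Generator | None = None) -> ROCSummary:
    """Binormal ROC fit by moments with a case-bootstrap AUC uncertainty.

    Class-conditional means and standard deviations are the sample moments
    of the scores; the bootstrap resamples cases within each class
    (seeded via ``rng``) and refits.  Zero variance in both classes with
    equal means is flagged degenerate with AUC 0.5.
    """
    s0, s1 = scores.split()
    if s0.size < 2 or s1.size < 2:
        raise ValueError("need at least 2 scores per class")
    mu0, mu1 = float(s0.mean()), float(s1.mean())
    var0, var1 = float(s0.var()), float(s1.var())
    degenerate = var0 == 0.0 and var1 == 0.0
    if degenerate and mu0 != mu1:
        raise ValueError("zero-variance classes with distinct means: AUC undefined by binormal fit")
    auc_b = 0.5 if degenerate else _binormal_auc(mu0, mu1, var0, var1)

    auc_std = 0.0
    if bootstrap_reps > 0 and not degenerate:
        rng = np.random.default_rng(0) if rng is None else rng
        i0 = rng.integers(0, s0.size, size=(bootstrap_reps, s0.size))
        i1 = rng.integers(0, s1.size, size=(bootstrap_reps, s1.size))
        b0, b1 = s0[i0], s1[i1]
        d = b1.mean(axis=1) - b0.mean(axis=1)
        v = b0.var(axis=1) + b1.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            aucs = norm.cdf(np.where(v > 0, d / np.sqrt(v), 0.0))
        auc_std = float(np.std(aucs))

    return ROCSummary(auc_empirical=empirical_auc(scores),
                      auc_binormal=auc_b,
                      mu0=mu0, mu1=mu1,
                      sigma0=float(np.sqrt(var0)), sigma1=float(np.sqrt(var1)),
                      auc_std=auc_std, degenerate=degenerate)


def snr(scores: ScoreSet) -> float:
    """Test-statistic SNR: class-mean separation over the pooled std,
    ``(m1 - m0) / sqrt(v0/2 + v1/2)``."""
    s0, s1 = scores.split()
    if s0.size < 2 or s1.size < 2:
        raise ValueError("need at least 2 scores per class")
    pooled = 0.5 * s0.var() + 0.5 * s1.var()
    if pooled == 0.0:
        raise ValueError("zero pooled variance")
    return float((s1.mean() - s0.mean()) / np.sqrt(pooled))
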
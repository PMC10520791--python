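"""Image-space Hotelling observers.

The Hotelling observer (HO) is the optimal linear discriminator for a
binary detection task: its template is ``w = K^{-1} dg`` where ``K`` is the
average of the class-conditional covariance matrices and ``dg`` the mean
signal (difference of class means).  Two estimation routes are provided:

HO-Direct  empirical covariances from the paired training images, inverted
           with a truncated-SVD (regularized Moore-Penrose) pseudoinverse;
HO-CMD     covariance-matrix decomposition, ``K = K_background + delta^2 I``
           from noiseless imaged backgrounds plus the known i.i.d. Gaussian
           noise covariance — an upper-bound reference available only when
           noiseless images exist and the noise covariance is known.

Covariances use divisor ``n`` (the plain expectation), not ``n - 1``; the
difference is immaterial at study sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .object_models import NoiseSpec, PairedImageSet

__all__ = [
    "MeanSignalEstimate",
    "CovarianceModel",
    "LinearObserver",
    "estimate_mean_signal",
    "estimate_covariances",
    "regularized_pinv",
    "ho_direct",
    "ho_cmd",
]


@dataclass(frozen=True)
class MeanSignalEstimate:
    """Mean signal difference ``dg = mean(present) - mean(absent)``."""

    delta_g: np.ndarray
    source: str = "estimated_from_subset"  # or "provided_fixed"
    n_pairs_used: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_g", np.asarray(self.delta_g, dtype=float).ravel())
        if not np.all(np.isfinite(self.delta_g)):
            raise ValueError("delta_g must be finite")


@dataclass
class CovarianceModel:
    """Per-hypothesis empirical covariances and their average."""

    k0: np.ndarray
    k1: np.ndarray

    @property
    def k_avg(self) -> np.ndarray:
        return 0.5 * (self.k0 + self.k1)


@dataclass(frozen=True)
class LinearObserver:
    """Image-space linear observer; score is ``template @ g``."""

    template: np.ndarray
    method: str = "ho_direct"

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", np.asarray(self.template, dtype=float).ravel())
        if not np.all(np.isfinite(self.template)):
            raise ValueError("template must be finite")


def estimate_mean_signal(dataset: PairedImageSet) -> MeanSignalEstimate:
    """Mean signal from paired data: mean(present) - mean(absent)."""
    if dataset.n_pairs < 1:
        raise ValueError("empty dataset")
    delta = dataset.images_present.mean(axis=0) - dataset.images_absent.mean(axis=0)
    return MeanSignalEstimate(delta_g=delta, source="estimated_from_subset",
                              n_pairs_used=dataset.n_pairs)


def _empirical_cov(images: np.ndarray) -> np.ndarray:
    n = images.shape[0]
    centered = images - images.mean(axis=0)
    k = centered.T @ centered / n
    return 0.5 * (k + k.T)


def estimate_covariances(dataset: PairedImageSet) -> CovarianceModel:
    """Per-hypothesis empirical covariance matrices (divisor n)."""
    if dataset.n_pairs < 2:
        raise ValueError("need at least 2 images per hypothesis")
    return CovarianceModel(k0=_empirical_cov(dataset.images_absent),
                           k1=_empirical_cov(dataset.images_present))


def regularized_pinv(matrix: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    """Truncated-SVD Moore-Penrose pseudoinverse of a symmetric matrix.

    Singular values below ``rel_tol`` times the largest singular value are
    discarded.  The input is symmetrized first to suppress round-off
    asymmetry; for a symmetric matrix the SVD coincides with the
    eigendecomposition up to signs, so the truncation acts on absolute
    eigenvalues.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be finite")
    m = 0.5 * (m + m.T)
    eigvals, eigvecs = scipy.linalg.eigh(m)
    smax = np.abs(eigvals).max(initial=0.0)
    if smax == 0.0:
        warnings.warn("regularized_pinv of an all-zero matrix: returning zeros")
        return np.zeros_like(m)
    keep = np.abs(eigvals) > rel_tol * smax
    inv_vals = np.zeros_like(eigvals)
    inv_vals[keep] = 1.0 / eigvals[keep]
    return (eigvecs * inv_vals) @ eigvecs.T


def ho_direct(dataset: PairedImageSet,
              signal: MeanSignalEstimate | None = None,
              rel_tol: float = 1e-6) -> LinearObserver:
    """HO template by direct empirical covariance inversion.

    ``w = pinv(0.5 (K0 + K1)) dg`` with the truncated-SVD pseudoinverse.
    When ``signal`` is omitted it is estimated from the same dataset.
    """
    if signal is None:
        signal = estimate_mean_signal(dataset)
    # accumulate 0.5 (K0 + K1) one class at a time to halve peak memory
    k_avg = _empirical_cov(dataset.images_absent)
    k_avg += _empirical_cov(dataset.images_present)
    k_avg *= 0.5
    template = regularized_pinv(k_avg, rel_tol=rel_tol) @ signal.delta_g
    return LinearObserver(template=template, method="ho_direct")


def ho_cmd(noiseless_backgrounds: np.ndarray,
           noise: NoiseSpec,
           signal: MeanSignalEstimate,
           rel_tol: float = 1e-6) -> LinearObserver:
    """HO template by covariance-matrix decomposition.

    Requires i.i.d. Gaussian measurement noise, whose covariance
    ``delta^2 I`` is added to the empirical covariance of the noiseless
    imaged backgrounds.  The mixed Poisson/Gaussian model is rejected: its
    covariance is signal-dependent and not closed-form after per-image
    rescaling.
    """
    if noise.kind != "gaussian_iid":
        raise ValueError("ho_cmd requires gaussian_iid noise with known covariance")
    backgrounds = np.atleast_2d(np.asarray(noiseless_backgrounds, dtype=float))
    if backgrounds.shape[0] < 2:
        raise ValueError("need at least 2 noiseless backgrounds")
    k = _empirical_cov(backgrounds)
    k[np.diag_indices_from(k)] += noise.gaussian_std ** 2
    template = regularized_pinv(k, rel_tol=rel_tol) @ signal.delta_g
    return LinearObserver(template=template, method="ho_cmd")
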
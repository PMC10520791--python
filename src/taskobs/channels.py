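"""Channel construction and the channelized Hotelling observer (CHO).

A channel matrix projects an N-pixel image to M scalar features,
``v = T g`` with ``M << N``; the Hotelling observer is then computed in
channel space, where its M x M covariance is estimable from modest data.
Implemented channel families:

LG       Laguerre-Gauss: rotationally symmetric functions
         ``u_j(r) ∝ exp(-pi r^2 / a^2) L_j(2 pi r^2 / a^2)``, the classical
         efficient channels for smooth symmetric signals on lumpy
         backgrounds;
conv-LG  the filtered channel observer realized with an LG baseline: each
         LG channel convolved ('same' size) with the estimated mean-signal
         image, then renormalized;
PLS      partial least squares (NIPALS): latent directions maximizing the
         covariance between images and the binary class label;
NPWMF    the nonprewhitening matched filter, an image-space observer whose
         template is the mean signal itself (no covariance whitening).

Orientation convention: channels are stored column-wise in an N x M array
``t_matrix``, so the projection of a stack of images ``G`` (n, N) is
``G @ t_matrix`` and the channel matrix of the detection-theory literature
is ``t_matrix.T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.special import eval_laguerre

from .hotelling import LinearObserver, MeanSignalEstimate, estimate_mean_signal, regularized_pinv
from .object_models import PairedImageSet

__all__ = [
    "ChannelMatrix",
    "ChannelizedObserver",
    "lg_channels",
    "conv_lg_channels",
    "pls_channels",
    "npwmf_observer",
    "channelize",
    "cho_build",
]

MAX_STUDY_CHANNELS = 20


@dataclass(frozen=True)
class ChannelMatrix:
    """N x M channel matrix; columns are unit-norm channels in image space."""

    t_matrix: np.ndarray
    grid_shape: tuple[int, int]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_matrix, dtype=float)
        object.__setattr__(self, "t_matrix", t)
        if t.ndim != 2:
            raise ValueError("t_matrix must be 2-D (N x M)")
        n, m = t.shape
        if m > n:
            raise ValueError("more channels than pixels")
        if not np.all(np.isfinite(t)):
            raise ValueError("channels must be finite")
        if np.any(np.linalg.norm(t, axis=0) == 0.0):
            raise ValueError("zero channel column")

    @property
    def n_channels(self) -> int:
        return self.t_matrix.shape[1]

    def select(self, columns) -> "ChannelMatrix":
        cols = np.asarray(columns, dtype=int)
        return ChannelMatrix(t_matrix=self.t_matrix[:, cols],
                             grid_shape=self.grid_shape,
                             method=self.method,
                             params={**self.params, "selected_columns": cols.tolist()})


@dataclass
class ChannelizedObserver:
    """CHO: channel matrix plus the channel-space Hotelling ingredients."""

    channels: ChannelMatrix
    wv: np.ndarray
    kv: np.ndarray
    delta_v: np.ndarray

    def __post_init__(self) -> None:
        m = self.channels.n_channels
        self.wv = np.asarray(self.wv, dtype=float).ravel()
        self.delta_v = np.asarray(self.delta_v, dtype=float).ravel()
        self.kv = np.asarray(self.kv, dtype=float)
        if self.wv.shape != (m,) or self.delta_v.shape != (m,) or self.kv.shape != (m, m):
            raise ValueError("inconsistent CHO dimensions")

    @property
    def method(self) -> str:
        return self.channels.method


def _radial_sq(grid_shape, center):
    if center is None:
        center = ((grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0)
    dy = np.arange(grid_shape[0], dtype=float) - center[0]
    dx = np.arange(grid_shape[1], dtype=float) - center[1]
    return dy[:, None] ** 2 + dx[None, :] ** 2


def lg_channels(n_channels: int,
                gauss_width: float,
                grid_shape: tuple[int, int],
                center: tuple[float, float] | None = None) -> ChannelMatrix:
    """Laguerre-Gauss channels evaluated on the pixel grid.

    ``gauss_width`` is the Gaussian aperture ``a`` in pixels.  Channels are
    rotationally symmetric about ``center`` (grid midpoint by default) and
    normalized to unit Euclidean norm.
    """
    if not 1 <= n_channels <= MAX_STUDY_CHANNELS:
        raise ValueError(f"n_channels must be in 1..{MAX_STUDY_CHANNELS}")
    if gauss_width <= 0:
        raise ValueError("gauss_width must be > 0")
    r2 = _radial_sq(grid_shape, center)
    x = 2.0 * np.pi * r2 / gauss_width ** 2
    envelope = np.exp(-0.5 * x)
    cols = []
    for j in range(n_channels):
        u = envelope * eval_laguerre(j, x)
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            raise ValueError(f"LG channel {j} aliases to a near-zero vector "
                             f"(gauss_width={gauss_width} too small for the grid)")
        cols.append(u.ravel() / norm)
    return ChannelMatrix(t_matrix=np.column_stack(cols), grid_shape=tuple(grid_shape),
                         method="lg", params={"gauss_width": float(gauss_width),
                                              "n_channels": int(n_channels)})


def conv_lg_channels(base: ChannelMatrix,
                     signal_image: MeanSignalEstimate | np.ndarray) -> ChannelMatrix:
    """Convolutional-LG (FCO) channels: each base channel convolved with the
    mean-signal image ('same' size), renormalized to unit norm."""
    sig = signal_image.delta_g if isinstance(signal_image, MeanSignalEstimate) else signal_image
    sig = np.asarray(sig, dtype=float).reshape(base.grid_shape)
    if np.all(sig == 0.0):
        raise ValueError("zero signal image yields degenerate channels")
    cols = []
    for j in range(base.n_channels):
        ch = base.t_matrix[:, j].reshape(base.grid_shape)
        conv = scipy.signal.fftconvolve(ch, sig, mode="same")
        norm = np.linalg.norm(conv)
        if norm < 1e-12:
            raise ValueError(f"convolved channel {j} is degenerate")
        cols.append(conv.ravel() / norm)
    return ChannelMatrix(t_matrix=np.column_stack(cols), grid_shape=base.grid_shape,
                         method="conv_lg", params=dict(base.params))


def pls_channels(training_images: np.ndarray,
                 labels: np.ndarray,
                 n_channels: int,
                 grid_shape: tuple[int, int] | None = None) -> ChannelMatrix:
    """Partial-least-squares channels by the NIPALS iteration.

    The images are column-centered and the binary labels centered; each
    component's weight vector is ``X^T y`` normalized, after which both X
    and y are deflated by the component scores.  The unit-norm weight
    vectors are the channels.  (Deflating y as well as X changes nothing
    for the first component; the y-deflating variant is used throughout.)
    """
    x = np.atleast_2d(np.asarray(training_images, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("one label per image")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if not 1 <= n_channels <= MAX_STUDY_CHANNELS:
        raise ValueError(f"n_channels must be in 1..{MAX_STUDY_CHANNELS}")
    x = x - x.mean(axis=0)
    y = y - y.mean()
    if not np.any(x) or not np.any(y):
        raise ValueError("zero-variance input")
    weights = []
    for _ in range(n_channels):
        k = x.T @ y
        nk = np.linalg.norm(k)
        if nk < 1e-12:
            raise ValueError("PLS deflation exhausted the label covariance")
        k /= nk
        t = x @ k
        tt = float(t @ t)
        p = x.T @ t / tt
        x = x - np.outer(t, p)
        y = y - t * (float(t @ y) / tt)
        weights.append(k)
    if grid_shape is None:
        side = int(round(np.sqrt(x.shape[1])))
        grid_shape = (side, x.shape[1] // side)
    return ChannelMatrix(t_matrix=np.column_stack(weights), grid_shape=tuple(grid_shape),
                         method="pls", params={"n_channels": int(n_channels)})


def npwmf_observer(signal: MeanSignalEstimate) -> LinearObserver:
    """Nonprewhitening matched filter: template equals the mean signal."""
    if not np.any(signal.delta_g):
        raise ValueError("zero mean signal")
    return LinearObserver(template=signal.delta_g, method="npwmf")


def channelize(channels: ChannelMatrix, images: np.ndarray) -> np.ndarray:
    """Project images onto the channels: rows of (n, N) -> rows of (n, M)."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if images.shape[1] != channels.t_matrix.shape[0]:
        raise ValueError("image length does not match channel matrix")
    return images @ channels.t_matrix


def cho_build(channels: ChannelMatrix,
              covariance_dataset: PairedImageSet,
              signal: MeanSignalEstimate | None = None,
              cond_limit: float = 1e12) -> ChannelizedObserver:
    """Build the CHO from a channel set and a held-out covariance dataset.

    ``Kv`` is the average of the two class-conditional channel covariances
    estimated on ``covariance_dataset``; ``dv`` is the channelized mean
    signal (from ``signal`` if given, else re-estimated from the same
    dataset); ``wv`` solves ``Kv wv = dv`` directly, falling back to the
    truncated-SVD pseudoinverse when ``Kv`` is ill-conditioned.
    """
    v0 = channelize(channels, covariance_dataset.images_absent)
    v1 = channelize(channels, covariance_dataset.images_present)
    kv0 = np.cov(v0, rowvar=False, bias=True)
    kv1 = np.cov(v1, rowvar=False, bias=True)
    kv = np.atleast_2d(0.5 * (kv0 + kv1))
    if signal is None:
        signal = estimate_mean_signal(covariance_dataset)
    delta_v = channels.t_matrix.T @ signal.delta_g
    if np.linalg.cond(kv) < cond_limit:
        wv = np.linalg.solve(kv, delta_v)
    else:
        wv = regularized_pinv(kv) @ delta_v
    return ChannelizedObserver(channels=channels, wv=wv, kv=kv, delta_v=delta_v)
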
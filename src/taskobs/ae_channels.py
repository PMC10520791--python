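"""Tied-weight linear autoencoder channels.

A linear autoencoder with tied weights is a single N x M matrix ``W``: the
encoder maps an image ``g`` to the embedding ``W^T g`` and the decoder maps
back with ``W``, so the reconstruction is ``W W^T g``.  Training minimizes
a mean squared reconstruction error over mini-batches:

conventional   target is the input image itself — the classical
               autoencoder, whose optimal subspace is spanned by the top
               principal directions of the data;
task-informed  target is ``I(g) * dg``, the indicator of signal presence
               times the estimated mean-signal image — the embedding then
               spends its entire capacity on signal-relevant structure,
               which is what makes the encoder columns efficient CHO
               channels.

The encoder doubles as the channel matrix: ``T = W^T``.  Optimization is
Adam on the analytic gradient

    dL/dW = (2/B) [ R^T Z + G^T (R W) ],   Z = G W,  R = Z W^T - Y,

with ``G`` the (B, N) batch, ``Y`` the targets, mini-batches balanced
between the two classes, and a truncated-normal initialization (cut at
two standard deviations).  Training is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .channels import MAX_STUDY_CHANNELS, ChannelMatrix, ChannelizedObserver, cho_build
from .evaluation import empirical_auc, score_dataset
from .hotelling import MeanSignalEstimate
from .object_models import PairedImageSet

__all__ = [
    "TiedLinearAE",
    "AELossSpec",
    "AETrainConfig",
    "ae_loss",
    "train_ae",
    "save_ae",
    "load_ae",
    "select_ae_model",
    "SelectionResult",
    "ablate_channels",
    "AblationResult",
]


@dataclass
class TiedLinearAE:
    """Tied-weight, bias-free linear autoencoder; ``weights`` is N x M."""

    weights: np.ndarray
    loss_trace: np.ndarray | None = None
    config: "AETrainConfig | None" = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be N x M")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    def encode(self, images: np.ndarray) -> np.ndarray:
        return np.atleast_2d(images) @ self.weights

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.encode(images) @ self.weights.T

    def as_channels(self, grid_shape: tuple[int, int]) -> ChannelMatrix:
        """Expose the encoder as a CHO channel matrix (columns = channels)."""
        return ChannelMatrix(t_matrix=self.weights.copy(), grid_shape=tuple(grid_shape),
                             method="ae", params={"n_channels": self.n_channels})


@dataclass(frozen=True)
class AELossSpec:
    """Reconstruction target: the input (conventional) or I(g) * dg (task)."""

    kind: str = "task"
    target_signal: MeanSignalEstimate | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("conventional", "task"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind == "task":
            if self.target_signal is None or not np.any(self.target_signal.delta_g):
                raise ValueError("task loss requires a non-zero target signal")


@dataclass(frozen=True)
class AETrainConfig:
    """Adam training hyperparameters.

    Study defaults: 500 epochs, balanced mini-batches of 250, truncated-
    normal init with std 5e-6, learning rate 1e-5 for the Gaussian-noise
    lumpy study and 5e-3 for rescaled-intensity data; the optional burn-in
    pre-trains on a 500-image subset before the main phase (Adam moments
    are reset between phases).
    """

    learning_rate: float = 1e-5
    epochs: int = 500
    batch_size: int = 250
    init_std: float = 5e-6
    burn_in: bool = False
    burn_in_images: int = 500
    burn_in_epochs: int = 500
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    dtype: str = "float64"  # "float32" halves the cost of large runs

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (balanced class halves)")
        if self.init_std <= 0:
            raise ValueError("init_std must be > 0")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")


def _targets(images: np.ndarray, labels: np.ndarray, spec: AELossSpec) -> np.ndarray:
    if spec.kind == "conventional":
        return images
    return np.outer(labels.astype(float), spec.target_signal.delta_g)


def ae_loss(ae: TiedLinearAE, images: np.ndarray, labels: np.ndarray,
            spec: AELossSpec) -> float:
    """Mean squared reconstruction error of the batch against its targets."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    labels = np.asarray(labels).ravel()
    if images.shape[0] != labels.size:
        raise ValueError("one label per image")
    resid = ae.reconstruct(images) - _targets(images, labels, spec)
    return float(np.mean(np.sum(resid ** 2, axis=1)))


def _loss_and_grad(w: np.ndarray, g: np.ndarray, y: np.ndarray):
    z = g @ w
    r = z @ w.T - y
    loss = float(np.mean(np.sum(r ** 2, axis=1)))
    grad = (2.0 / g.shape[0]) * (r.T @ z + g.T @ (r @ w))
    return loss, grad


class _Adam:
    def __init__(self, shape, cfg: AETrainConfig, dtype=np.float64):
        self.m = np.zeros(shape, dtype=dtype)
        self.v = np.zeros(shape, dtype=dtype)
        self.t = 0
        self.cfg = cfg

    def step(self, w, grad):
        c = self.cfg
        self.t += 1
        self.m = c.adam_beta1 * self.m + (1 - c.adam_beta1) * grad
        self.v = c.adam_beta2 * self.v + (1 - c.adam_beta2) * grad ** 2
        mhat = self.m / (1 - c.adam_beta1 ** self.t)
        vhat = self.v / (1 - c.adam_beta2 ** self.t)
        return w - c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def _run_phase(w, images0, images1, spec, cfg, epochs, rng):
    """Adam over balanced mini-batches; returns weights and per-epoch loss.

    All arithmetic stays in the dtype of ``w`` (the images are cast once by
    the caller), so a float32 run really is float32 end to end.
    """
    dtype = w.dtype
    n_pairs = min(images0.shape[0], images1.shape[0])
    half = cfg.batch_size // 2
    n_batches = max(1, n_pairs // half)
    opt = _Adam(w.shape, cfg, dtype=dtype)
    trace = np.empty(epochs)
    labels = np.concatenate([np.zeros(half, dtype=dtype), np.ones(half, dtype=dtype)])
    delta = None
    if spec.kind == "task":
        delta = np.asarray(spec.target_signal.delta_g, dtype=dtype)
    for epoch in range(epochs):
        # re-pair the class halves every epoch
        idx0 = rng.permutation(images0.shape[0])[: n_batches * half]
        idx1 = rng.permutation(images1.shape[0])[: n_batches * half]
        epoch_loss = 0.0
        for b in range(n_batches):
            sl = slice(b * half, (b + 1) * half)
            g = np.vstack([images0[idx0[sl]], images1[idx1[sl]]])
            y = g if delta is None else np.outer(labels, delta)
            loss, grad = _loss_and_grad(w, g, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"AE training diverged at epoch {epoch}, batch {b} "
                    f"(lr={cfg.learning_rate}, loss={loss})")
            w = opt.step(w, grad)
            epoch_loss += loss
        trace[epoch] = epoch_loss / n_batches
    return w, trace


def train_ae(rng: np.random.Generator | None,
             train_dataset: PairedImageSet,
             signal: MeanSignalEstimate | None,
             n_channels: int,
             config: AETrainConfig,
             loss: AELossSpec | None = None) -> TiedLinearAE:
    """Train a tied-weight linear AE and return it (encoder = channels).

    ``rng=None`` derives the generator from ``config.seed`` so runs are
    reproducible from the config alone.  ``loss=None`` defaults to the
    task-informed loss with ``signal`` as target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if loss is None:
        loss = AELossSpec(kind="task", target_signal=signal)
    if not 1 <= n_channels <= MAX_STUDY_CHANNELS:
        raise ValueError(f"n_channels must be in 1..{MAX_STUDY_CHANNELS}")
    dtype = np.dtype(config.dtype)
    images0 = train_dataset.images_absent.astype(dtype, copy=False)
    images1 = train_dataset.images_present.astype(dtype, copy=False)
    half = config.batch_size // 2
    if min(images0.shape[0], images1.shape[0]) < half:
        raise ValueError("dataset too small for one balanced mini-batch")

    n_pixels = train_dataset.n_pixels
    w = scipy.stats.truncnorm.rvs(-2.0, 2.0, scale=config.init_std,
                                  size=(n_pixels, n_channels),
                                  random_state=rng).astype(dtype)

    traces = []
    if config.burn_in and 2 * images0.shape[0] > config.burn_in_images:
        n_sub = max(half, config.burn_in_images // 2)
        sub = rng.permutation(images0.shape[0])[:n_sub]
        w, tr = _run_phase(w, images0[sub], images1[sub], loss, config,
                           config.burn_in_epochs, rng)
        traces.append(tr)
    w, tr = _run_phase(w, images0, images1, loss, config, config.epochs, rng)
    traces.append(tr)
    return TiedLinearAE(weights=w, loss_trace=np.concatenate(traces), config=config)


def save_ae(path, ae: TiedLinearAE) -> None:
    """Serialize a trained AE: weights, loss trace and training config."""
    import dataclasses

    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=ae.weights)
        if ae.loss_trace is not None:
            f.create_dataset("loss_trace", data=ae.loss_trace)
        if ae.config is not None:
            for key, value in dataclasses.asdict(ae.config).items():
                f.attrs[f"config_{key}"] = value


def load_ae(path) -> TiedLinearAE:
    import h5py

    with h5py.File(path, "r") as f:
        weights = f["weights"][...]
        trace = f["loss_trace"][...] if "loss_trace" in f else None
        cfg_items = {k[len("config_"):]: v for k, v in f.attrs.items()
                     if k.startswith("config_")}
    config = None
    if cfg_items:
        for key in ("epochs", "batch_size", "burn_in_images", "burn_in_epochs", "seed"):
            if key in cfg_items:
                cfg_items[key] = int(cfg_items[key])
        for key in ("burn_in",):
            if key in cfg_items:
                cfg_items[key] = bool(cfg_items[key])
        if "dtype" in cfg_items:
            cfg_items["dtype"] = str(cfg_items["dtype"])
        config = AETrainConfig(**cfg_items)
    return TiedLinearAE(weights=weights, loss_trace=trace, config=config)


@dataclass
class SelectionResult:
    """Best validation-AUC CHO among trained AE candidates, with leaderboard."""

    observer: ChannelizedObserver
    best_index: int
    leaderboard: list[dict] = field(default_factory=list)


def select_ae_model(candidates: list[tuple[TiedLinearAE, AETrainConfig]],
                    validation_dataset: PairedImageSet,
                    covariance_dataset: PairedImageSet,
                    signal: MeanSignalEstimate) -> SelectionResult:
    """Convert each candidate encoder to a CHO and pick the validation-AUC
    argmax; the full leaderboard is returned for audit."""
    if not candidates:
        raise ValueError("empty candidate list")
    rows = []
    observers = []
    for i, (ae, cfg) in enumerate(candidates):
        chans = ae.as_channels(validation_dataset.grid_shape)
        obs = cho_build(chans, covariance_dataset, signal)
        auc = empirical_auc(score_dataset(obs, validation_dataset))
        observers.append(obs)
        rows.append({"index": i, "n_channels": ae.n_channels,
                     "learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
                     "burn_in": cfg.burn_in, "seed": cfg.seed,
                     "validation_auc": auc})
    best = int(np.argmax([r["validation_auc"] for r in rows]))
    return SelectionResult(observer=observers[best], best_index=best, leaderboard=rows)


@dataclass
class AblationResult:
    """Greedy backward-elimination ranking of CHO channels.

    ``elimination_order`` lists original column indices in removal order
    (least important first); ``channel_counts``/``aucs`` trace validation
    AUC as the channel count shrinks from M down to 1.
    """

    elimination_order: list[int]
    channel_counts: list[int]
    aucs: list[float]


def ablate_channels(observer: ChannelizedObserver,
                    validation_dataset: PairedImageSet,
                    covariance_dataset: PairedImageSet,
                    signal: MeanSignalEstimate) -> AblationResult:
    """Iteratively prune the channel whose removal best preserves
    validation AUC, producing an importance ranking and an AUC-vs-count
    curve."""
    m = observer.channels.n_channels
    if m < 2:
        raise ValueError("need at least 2 channels to ablate")
    remaining = list(range(m))
    counts = [m]
    aucs = [empirical_auc(score_dataset(observer, validation_dataset))]
    order: list[int] = []
    base = observer.channels
    while len(remaining) > 1:
        best_auc, best_j = -np.inf, None
        for j in range(len(remaining)):
            keep = remaining[:j] + remaining[j + 1:]
            obs = cho_build(base.select(keep), covariance_dataset, signal)
            auc = empirical_auc(score_dataset(obs, validation_dataset))
            if auc > best_auc:
                best_auc, best_j = auc, j
        order.append(remaining.pop(best_j))
        counts.append(len(remaining))
        aucs.append(best_auc)
    order.append(remaining[0])
    return AblationResult(elimination_order=order, channel_counts=counts, aucs=aucs)
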
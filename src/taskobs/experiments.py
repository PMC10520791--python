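"""Config-driven reproduction of the detection studies.

Two study families are provided:

* ``run_size_sweep`` — the lumpy Gaussian-noise study: observers trained on
  growing subsets of a fixed training set, channel covariance from a
  dedicated held-out pair set, AUC on a common test set.  A fixed-signal
  variant re-uses the maximum-size mean-signal estimate for every subset.
* ``run_domain_shift`` — the stylized-PET study: three imaging-system
  widths (1.0, 2.0, 4.0) share one background stream, use mixed
  Poisson/Gaussian noise with per-image [0, 1] rescaling, and every
  observer trained on each source (the three widths plus an evenly
  amalgamated dataset) is evaluated on every target's test set.

Observer builders for each method live here so both runners and the
command-line interface share them.  Every run derives all randomness from
a single seed via ``numpy.random.SeedSequence`` and is reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ae_channels as ae
from . import channels as ch
from . import evaluation as ev
from . import hotelling as ho
from . import object_models as om

__all__ = [
    "StudyConfig",
    "run_size_sweep",
    "run_domain_shift",
    "load_external_rois",
    "assert_disjoint",
    "save_observer",
    "load_observer",
    "plot_channels",
    "plot_template",
]

KNOWN_METHODS = ("ho_direct", "ho_cmd", "conv_lg", "pls", "npwmf",
                 "ae_task", "ae_conventional")


@dataclass
class StudyConfig:
    """Parameters of one study run.

    The defaults reproduce the full-scale study conditions (30,000 / 5,000 /
    5,000 pairs); desk-scale runs shrink the sizes and grids, not the
    object, system or noise parameters.
    """

    study: str = "domain_shift"
    methods: tuple[str, ...] = ("ho_direct", "conv_lg", "pls", "npwmf", "ae_task")
    # dataset sizes (pairs)
    n_train_pairs: int = 30_000
    n_val_pairs: int = 5_000
    n_test_pairs: int = 5_000
    sizes: tuple[int, ...] | None = None  # subset sizes for sweeps
    fixed_signal: bool = False
    # object / system / noise
    background: om.LumpyBackgroundParams = field(default_factory=om.LumpyBackgroundParams)
    signal: om.EllipticalSignalParams = field(default_factory=om.EllipticalSignalParams)
    system: om.ImagingSystemSpec = field(default_factory=om.ImagingSystemSpec)
    noise: om.NoiseSpec = field(default_factory=om.NoiseSpec)
    widths: tuple[float, ...] = (1.0, 2.0, 4.0)
    include_amalgamated: bool = True
    # reference-channel grids
    lg_width_grid: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 40.0)
    channel_count_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 15, 20)
    # AE grids and budget
    ae_channel_grid: tuple[int, ...] = (10, 20)
    ae_lr_grid: tuple[float, ...] = (1e-5,)
    ae_epochs: int = 500
    ae_batch_size: int = 250
    ae_subset_pairs: int | None = None
    ae_burn_in: bool = False
    ae_sources: tuple | None = None  # restrict AE training to these sources
    # HO-CMD
    n_cmd_backgrounds: int | None = None
    # evaluation
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}")
        if not self.methods:
            raise ValueError("methods must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, typ in (("background", om.LumpyBackgroundParams),
                         ("signal", om.EllipticalSignalParams),
                         ("system", om.ImagingSystemSpec),
                         ("noise", om.NoiseSpec)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tup in ("angle_set", "center", "grid_shape"):
                    if tup in sub and isinstance(sub[tup], list):
                        sub[tup] = tuple(sub[tup])
                d[key] = typ(**sub)
        for tup in ("methods", "sizes", "widths", "lg_width_grid", "channel_count_grid",
                    "ae_channel_grid", "ae_lr_grid", "ae_sources"):
            if tup in d and isinstance(d[tup], list):
                d[tup] = tuple(d[tup])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# observer builders
# ---------------------------------------------------------------------------

def _grid_search_channel_cho(bases: list[ch.ChannelMatrix],
                             counts: tuple[int, ...],
                             val: om.PairedImageSet,
                             covar: om.PairedImageSet,
                             signal: ho.MeanSignalEstimate):
    """Pick the (base, channel count) pair maximizing validation AUC."""
    best = (-np.inf, None)
    for base in bases:
        for m in counts:
            if m > base.n_channels:
                continue
            obs = ch.cho_build(base.select(range(m)), covar, signal)
            auc = ev.empirical_auc(ev.score_dataset(obs, val))
            if auc > best[0]:
                best = (auc, obs)
    return best[1]


def build_observer(method: str,
                   train: om.PairedImageSet,
                   val: om.PairedImageSet,
                   signal: ho.MeanSignalEstimate,
                   config: StudyConfig,
                   rng: np.random.Generator):
    """Train / select one observer on a (train, validation) source.

    The validation split doubles as the held-out channel-covariance set, as
    in the study protocol; the training images never enter the channel
    covariance.
    """
    max_m = max(config.channel_count_grid)
    if method == "ho_direct":
        return ho.ho_direct(train, signal)
    if method == "ho_cmd":
        n_bg = config.n_cmd_backgrounds or 2 * (train.n_pairs + val.n_pairs)
        bgs = om.generate_noiseless_backgrounds(rng, n_bg, config.background, config.system)
        return ho.ho_cmd(bgs, config.noise, signal)
    if method == "npwmf":
        return ch.npwmf_observer(signal)
    if method == "conv_lg":
        bases = [ch.conv_lg_channels(
                    ch.lg_channels(max_m, a, train.grid_shape, center=config.signal.center),
                    signal)
                 for a in config.lg_width_grid]
        return _grid_search_channel_cho(bases, config.channel_count_grid, val, val, signal)
    if method == "pls":
        images, labels = train.pooled()
        base = ch.pls_channels(images, labels, max_m, grid_shape=train.grid_shape)
        return _grid_search_channel_cho([base], config.channel_count_grid, val, val, signal)
    if method in ("ae_task", "ae_conventional"):
        kind = "task" if method == "ae_task" else "conventional"
        spec = ae.AELossSpec(kind=kind,
                             target_signal=signal if kind == "task" else None)
        sub = train
        if config.ae_subset_pairs and config.ae_subset_pairs < train.n_pairs:
            sub = train.subset(range(config.ae_subset_pairs))
        candidates = []
        for m in config.ae_channel_grid:
            for lr in config.ae_lr_grid:
                seed = int(rng.integers(0, 2**31 - 1))
                cfg = ae.AETrainConfig(learning_rate=lr, epochs=config.ae_epochs,
                                       batch_size=config.ae_batch_size,
                                       burn_in=config.ae_burn_in, seed=seed)
                model = ae.train_ae(None, sub, signal, m, cfg, spec)
                candidates.append((model, cfg))
        return ae.select_ae_model(candidates, val, val, signal).observer
    raise ValueError(f"unknown method {method!r}")


def _evaluate(observer, test: om.PairedImageSet, rng, reps) -> dict:
    scores = ev.score_dataset(observer, test)
    roc = ev.binormal_fit(scores, bootstrap_reps=reps, rng=rng)
    return {"auc_binormal": roc.auc_binormal,
            "auc_empirical": roc.auc_empirical,
            "auc_std": roc.auc_std,
            "snr": ev.snr(scores)}


# ---------------------------------------------------------------------------
# study runners
# ---------------------------------------------------------------------------

def run_size_sweep(config: StudyConfig) -> pd.DataFrame:
    """Training-set-size sweep on a single imaging configuration.

    Generates one maximum-size training set plus held-out channel-
    covariance and test sets, then trains every method on each subset size.
    With ``fixed_signal`` the mean signal is estimated once from the
    maximum-size training and validation data and provided to every subset.
    """
    sizes = config.sizes or (config.n_train_pairs,)
    if max(sizes) > config.n_train_pairs:
        raise ValueError("subset size exceeds available training pairs")
    ss = np.random.SeedSequence(config.seed)
    r_train, r_val, r_test, r_meth, r_boot = [np.random.default_rng(s)
                                              for s in ss.spawn(5)]
    gen = lambda rng, n: om.generate_paired_dataset(
        rng, n, config.background, config.signal, config.system, config.noise)
    train_full = gen(r_train, config.n_train_pairs)
    val = gen(r_val, config.n_val_pairs)
    test = gen(r_test, config.n_test_pairs)

    fixed = None
    if config.fixed_signal:
        delta = (np.vstack([train_full.images_present, val.images_present]).mean(axis=0)
                 - np.vstack([train_full.images_absent, val.images_absent]).mean(axis=0))
        fixed = ho.MeanSignalEstimate(delta_g=delta, source="provided_fixed",
                                      n_pairs_used=train_full.n_pairs + val.n_pairs)

    rows = []
    for size in sizes:
        train = train_full.subset(range(size))
        signal = fixed if fixed is not None else ho.estimate_mean_signal(train)
        for method in config.methods:
            obs = build_observer(method, train, val, signal, config, r_meth)
            metrics = _evaluate(obs, test, r_boot, config.bootstrap_reps)
            rows.append({"study": config.study, "method": method,
                         "n_pairs": size, "source_width": config.system.psf_width,
                         "target_width": config.system.psf_width,
                         "seed": config.seed, **metrics})
    return pd.DataFrame(rows)


def run_domain_shift(config: StudyConfig) -> pd.DataFrame:
    """Domain-shift and amalgamation study.

    The three system widths share one background scene stream per split
    (identical object realizations, different blur and noise draws).  Every
    method is trained on every source — each width plus, optionally, the
    evenly amalgamated dataset — and every trained observer is scored on
    every width's test set, yielding the source x method x target grid.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)
    r_meth = np.random.default_rng(seeds[3])
    r_amalg = np.random.default_rng(seeds[4])
    r_boot = np.random.default_rng(seeds[5])

    noise = config.noise if config.noise.kind == "poisson_plus_gaussian" \
        else om.NoiseSpec.mixed()
    datasets: dict = {}
    for w in config.widths:
        system = dataclasses.replace(config.system, psf_width=float(w))
        splits = {}
        for name, seed, n in (("train", seeds[0], config.n_train_pairs),
                              ("val", seeds[1], config.n_val_pairs),
                              ("test", seeds[2], config.n_test_pairs)):
            rng = np.random.default_rng(seed)  # same stream across widths
            splits[name] = om.generate_paired_dataset(
                rng, n, config.background, config.signal, system, noise)
        datasets[w] = splits

    sources: dict = {w: (datasets[w]["train"], datasets[w]["val"]) for w in config.widths}
    if config.include_amalgamated:
        sources["amalg"] = (
            om.amalgamate([datasets[w]["train"] for w in config.widths],
                          r_amalg, config.n_train_pairs),
            om.amalgamate([datasets[w]["val"] for w in config.widths],
                          r_amalg, config.n_val_pairs),
        )

    rows = []
    for source, (train, val) in sources.items():
        signal = ho.estimate_mean_signal(train)
        for method in config.methods:
            if method in ("ae_task", "ae_conventional") and config.ae_sources \
                    and source not in config.ae_sources:
                continue
            obs = build_observer(method, train, val, signal, config, r_meth)
            for w in config.widths:
                metrics = _evaluate(obs, datasets[w]["test"], r_boot,
                                    config.bootstrap_reps)
                rows.append({"study": "domain_shift", "method": method,
                             "source_width": source, "target_width": w,
                             "n_pairs": train.n_pairs, "seed": config.seed,
                             **metrics})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# external ROI stacks and audits
# ---------------------------------------------------------------------------

def load_external_rois(path,
                       absent_key: str = "images_absent",
                       present_key: str = "images_present",
                       angles_key: str | None = None) -> om.PairedImageSet:
    """Load user-supplied ROI stacks (e.g. VICTRE-style 109x109 or 65x65
    arrays with binary labels) into a PairedImageSet.

    The container is HDF5 with one stack per class, either (n, H, W) or
    flattened (n, H*W) with a ``grid_shape`` attribute.  Both classes must
    be present with equal counts.
    """
    import h5py

    with h5py.File(path, "r") as f:
        for key in (absent_key, present_key):
            if key not in f:
                raise ValueError(f"missing class stack {key!r} in {path}")
        absent = f[absent_key][...]
        present = f[present_key][...]
        angles = f[angles_key][...] if angles_key and angles_key in f else None
        if absent.ndim == 3:
            grid = absent.shape[1:]
            absent = absent.reshape(absent.shape[0], -1)
            present = present.reshape(present.shape[0], -1)
        else:
            grid = tuple(int(s) for s in f.attrs["grid_shape"])
    if absent.shape != present.shape:
        raise ValueError("class stacks must have matching shapes")
    return om.PairedImageSet(images_absent=absent, images_present=present,
                             grid_shape=tuple(int(s) for s in grid),
                             angles=angles, meta={"path": str(path)})


def assert_disjoint(*datasets: om.PairedImageSet) -> None:
    """Audit that no image row appears in more than one split."""
    seen: dict[bytes, str] = {}
    for i, d in enumerate(datasets):
        for stack in (d.images_absent, d.images_present):
            for row in stack:
                key = row.tobytes()
                if key in seen:
                    raise AssertionError(
                        f"image shared between split {seen[key]} and split {i}")
                seen[key] = str(i)


# ---------------------------------------------------------------------------
# visualization
# ---------------------------------------------------------------------------

def plot_channels(channels: ch.ChannelMatrix, path, n_cols: int = 5) -> None:
    """Write a PNG grid of the channels (one panel per column of T)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = channels.n_channels
    n_rows = int(np.ceil(m / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(2 * n_cols, 2 * n_rows),
                             squeeze=False)
    for j in range(n_rows * n_cols):
        axis = axes[j // n_cols][j % n_cols]
        axis.axis("off")
        if j < m:
            axis.imshow(channels.t_matrix[:, j].reshape(channels.grid_shape),
                        cmap="gray")
            axis.set_title(str(j), fontsize=8)
    fig.suptitle(f"{channels.method} channels")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def plot_template(observer, grid_shape, path) -> None:
    """Write a PNG of an observer's image-space template.

    For a CHO the effective template is the channel matrix applied to the
    channel-space weights, T^T wv.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(observer, ch.ChannelizedObserver):
        template = observer.channels.t_matrix @ observer.wv
        method = observer.channels.method
    else:
        template, method = observer.template, observer.method
    fig, axis = plt.subplots(figsize=(4, 4))
    im = axis.imshow(template.reshape(grid_shape), cmap="gray")
    fig.colorbar(im, ax=axis, shrink=0.8)
    axis.set_title(f"{method} template")
    axis.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# observer serialization
# ---------------------------------------------------------------------------

def save_observer(path, observer) -> None:
    """Serialize a linear or channelized observer to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        if isinstance(observer, ch.ChannelizedObserver):
            f.attrs["kind"] = "channelized"
            f.attrs["method"] = observer.channels.method
            f.attrs["grid_shape"] = np.asarray(observer.channels.grid_shape, dtype=int)
            f.attrs["params_json"] = json.dumps(observer.channels.params)
            f.create_dataset("t_matrix", data=observer.channels.t_matrix)
            f.create_dataset("wv", data=observer.wv)
            f.create_dataset("kv", data=observer.kv)
            f.create_dataset("delta_v", data=observer.delta_v)
        elif isinstance(observer, ho.LinearObserver):
            f.attrs["kind"] = "linear"
            f.attrs["method"] = observer.method
            f.create_dataset("template", data=observer.template)
        else:
            raise TypeError(f"cannot serialize {type(observer).__name__}")


def load_observer(path):
    import h5py

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        if kind == "linear":
            return ho.LinearObserver(template=f["template"][...],
                                     method=str(f.attrs["method"]))
        chans = ch.ChannelMatrix(t_matrix=f["t_matrix"][...],
                                 grid_shape=tuple(int(s) for s in f.attrs["grid_shape"]),
                                 method=str(f.attrs["method"]),
                                 params=json.loads(f.attrs["params_json"]))
        return ch.ChannelizedObserver(channels=chans, wv=f["wv"][...],
                                      kv=f["kv"][...], delta_v=f["delta_v"][...])
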
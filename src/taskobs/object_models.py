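"""Stochastic object models, stylized imaging system, and paired detection datasets.

The simulation chain is the standard one for signal-detection studies on
lumpy backgrounds: a continuous-domain object ``f = fb + fs`` made of
Gaussian components is pushed through a continuous-to-discrete imaging
operator (a Gaussian point-response function modelling an idealized
parallel-hole collimator) and corrupted by measurement noise, yielding a
measured image ``g = Hf + n``.  Signal-present and signal-absent images are
generated in pairs so that downstream observers can be trained and scored
on a balanced binary detection task.

Because every object component is Gaussian and the PSF is Gaussian, the
action of ``H`` is available in closed form: a component with amplitude
``alpha`` and covariance ``Sigma`` contributes

    alpha * h * sqrt(det Sigma / det(Sigma + w^2 I))
          * exp(-0.5 * d^T (Sigma + w^2 I)^{-1} d)

to the pixel at displacement ``d`` from the component centre, where ``h``
and ``w`` are the PSF height and width.  The discrete-convolution route
exists only as a test oracle.

Coordinate convention: pixels are indexed ``(row, col)`` with centres at
integer coordinates ``0 .. nrows-1``; lump centres are sampled uniformly
over the continuous square ``[0, nrows) x [0, ncols)``; there is no
wrap-around, lumps near the border are simply truncated by the field of
view.  Signal orientation angles are measured in the ``(x, y) = (col,
row)`` plane, in degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LumpyBackgroundParams",
    "ImagingSystemSpec",
    "EllipticalSignalParams",
    "NoiseSpec",
    "GaussianComponent",
    "ObjectScene",
    "PairedImageSet",
    "sample_lumpy_scene",
    "signal_component",
    "apply_imaging_operator",
    "imaged_signal",
    "add_noise",
    "rescale_unit",
    "generate_paired_dataset",
    "generate_noiseless_backgrounds",
    "amalgamate",
    "save_dataset",
    "load_dataset",
]

DATASET_FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class LumpyBackgroundParams:
    """Lumpy stochastic object model: a Poisson number of isotropic Gaussian
    lumps with amplitude ``lump_amplitude`` and width (standard deviation)
    ``lump_width`` pixels, centred uniformly at random in the field of view.
    """

    mean_lump_count: float = 5.0
    lump_amplitude: float = 1.0
    lump_width: float = 7.0

    def __post_init__(self) -> None:
        _require(np.isfinite(self.mean_lump_count) and self.mean_lump_count >= 0,
                 "mean_lump_count must be finite and >= 0")
        _require(np.isfinite(self.lump_amplitude) and self.lump_amplitude > 0,
                 "lump_amplitude must be finite and > 0")
        _require(np.isfinite(self.lump_width) and self.lump_width > 0,
                 "lump_width must be finite and > 0")


@dataclass(frozen=True)
class ImagingSystemSpec:
    """Gaussian point-response imaging system.

    ``psf_height`` is the gain of the PSF; ``psf_width`` its standard
    deviation in pixels.  The detection studies use widths 0.5 (Gaussian
    noise study) and {1.0, 2.0, 4.0} (domain-shift study).
    """

    psf_height: float = 40.0
    psf_width: float = 0.5
    grid_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        _require(np.isfinite(self.psf_height) and self.psf_height > 0,
                 "psf_height must be finite and > 0")
        _require(np.isfinite(self.psf_width) and self.psf_width > 0,
                 "psf_width must be finite and > 0")
        _require(len(self.grid_shape) == 2 and all(int(s) >= 1 for s in self.grid_shape),
                 "grid_shape must be two entries >= 1")

    @property
    def n_pixels(self) -> int:
        return int(self.grid_shape[0]) * int(self.grid_shape[1])


@dataclass(frozen=True)
class EllipticalSignalParams:
    """Elliptical Gaussian signal with peak ``amplitude``, per-axis widths
    ``width_x`` / ``width_y`` (standard deviations in pixels), rotated by an
    angle drawn from ``angle_set`` (degrees) and centred at ``center`` given
    as ``(row, col)``.  A single angle gives the location-known task; the
    set ``(0, 45, 90, 135)`` gives the fixed-centroid SKS task.
    """

    amplitude: float = 0.2
    width_x: float = 5.0
    width_y: float = 1.5
    angle_set: tuple[float, ...] = (0.0,)
    center: tuple[float, float] = (32.0, 32.0)

    def __post_init__(self) -> None:
        _require(np.isfinite(self.amplitude) and self.amplitude > 0,
                 "amplitude must be finite and > 0")
        _require(self.width_x > 0 and self.width_y > 0, "signal widths must be > 0")
        _require(len(self.angle_set) > 0, "angle_set must be non-empty")
        _require(len(self.center) == 2, "center must be a 2-vector")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise model.

    ``gaussian_iid``           i.i.d. additive N(0, gaussian_std^2) per pixel.
    ``poisson_plus_gaussian``  each pixel replaced by Poisson(pixel) plus
                               N(0, gaussian_std^2) with unit std by default;
                               with ``rescale_to_unit`` the noisy images are
                               then min-max mapped to [0, 1].

    ``rescale_mode`` selects the [0, 1] normalization constants:
    ``"dataset"`` (default) uses one min-max pair over the whole stack —
    an affine map of the dataset, the convention under which the mixed-
    noise detection studies reproduce their reported operating points —
    while ``"image"`` normalizes each image by its own range.
    """

    kind: str = "gaussian_iid"
    gaussian_std: float = 20.0
    rescale_to_unit: bool = False
    rescale_mode: str = "dataset"

    def __post_init__(self) -> None:
        _require(self.kind in ("gaussian_iid", "poisson_plus_gaussian"),
                 f"unknown noise kind {self.kind!r}")
        _require(np.isfinite(self.gaussian_std) and self.gaussian_std >= 0,
                 "gaussian_std must be finite and >= 0")
        _require(self.rescale_mode in ("dataset", "image"),
                 f"unknown rescale_mode {self.rescale_mode!r}")
        if self.rescale_to_unit:
            _require(self.kind == "poisson_plus_gaussian",
                     "rescale_to_unit applies only to the mixed noise model")

    @classmethod
    def gaussian(cls, std: float = 20.0) -> "NoiseSpec":
        return cls(kind="gaussian_iid", gaussian_std=std)

    @classmethod
    def mixed(cls, rescale_to_unit: bool = True, rescale_mode: str = "dataset") -> "NoiseSpec":
        return cls(kind="poisson_plus_gaussian", gaussian_std=1.0,
                   rescale_to_unit=rescale_to_unit, rescale_mode=rescale_mode)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    """A single continuous-domain Gaussian component of the object function.

    ``center`` is ``(row, col)``; ``cov`` a 2x2 SPD covariance (pixel^2) in
    (row, col) coordinates; ``amplitude`` the peak value.
    """

    center: tuple[float, float]
    amplitude: float
    cov: tuple[tuple[float, float], tuple[float, float]]
    tag: str = "background"

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        _require(c.shape == (2, 2) and np.all(np.isfinite(c)), "cov must be finite 2x2")
        _require(abs(c[0, 1] - c[1, 0]) <= 1e-12 * max(1.0, abs(c[0, 1])),
                 "cov must be symmetric")
        _require(c[0, 0] > 0 and np.linalg.det(c) > 0, "cov must be positive definite")
        _require(np.isfinite(self.amplitude), "amplitude must be finite")

    @property
    def cov_array(self) -> np.ndarray:
        return np.asarray(self.cov, dtype=float)


@dataclass
class ObjectScene:
    """Continuous-domain object function: a sum of Gaussian components."""

    components: list[GaussianComponent] = field(default_factory=list)
    fov: tuple[float, float] = (64.0, 64.0)

    def background_components(self) -> list[GaussianComponent]:
        return [c for c in self.components if c.tag == "background"]


def sample_lumpy_scene(rng: np.random.Generator,
                       params: LumpyBackgroundParams,
                       fov: tuple[float, float] = (64.0, 64.0)) -> ObjectScene:
    """Draw one lumpy background: Poisson(mean_lump_count) isotropic lumps
    with centres i.i.d. uniform over the continuous field of view."""
    n_lumps = int(rng.poisson(params.mean_lump_count))
    s2 = params.lump_width ** 2
    comps = []
    for _ in range(n_lumps):
        r = (float(rng.uniform(0.0, fov[0])), float(rng.uniform(0.0, fov[1])))
        comps.append(GaussianComponent(center=r, amplitude=params.lump_amplitude,
                                       cov=((s2, 0.0), (0.0, s2)), tag="background"))
    return ObjectScene(components=comps, fov=tuple(float(f) for f in fov))


def signal_component(params: EllipticalSignalParams, angle: float) -> GaussianComponent:
    """Elliptical Gaussian signal component rotated by ``angle`` degrees.

    The signal value at offset u from the centre is
    ``A * exp(-(R u)^T D^{-1} (R u))`` with ``D = diag(2 sx^2, 2 sy^2)`` and
    ``R`` the rotation by ``angle`` acting in the (x, y) = (col, row) plane;
    equivalently a Gaussian with per-axis variances (sx^2, sy^2) in the
    rotated frame.
    """
    if angle not in params.angle_set:
        raise ValueError(f"angle {angle} not in angle_set {params.angle_set}")
    th = np.deg2rad(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # covariance in (x, y), then swap axes to the (row, col) convention
    cov_xy = rot.T @ np.diag([params.width_x ** 2, params.width_y ** 2]) @ rot
    cov_rc = np.array([[cov_xy[1, 1], cov_xy[1, 0]],
                       [cov_xy[0, 1], cov_xy[0, 0]]])
    cov_rc = 0.5 * (cov_rc + cov_rc.T)
    return GaussianComponent(center=tuple(float(c) for c in params.center),
                             amplitude=float(params.amplitude),
                             cov=tuple(tuple(float(x) for x in row) for row in cov_rc),
                             tag="signal")


def evaluate_scene(scene: ObjectScene, grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the continuous object on the pixel grid (no imaging blur).

    Used for visualisation and as an ingredient of the FFT-convolution test
    oracle; the measurement path never calls this.
    """
    rows = np.arange(grid_shape[0], dtype=float)
    cols = np.arange(grid_shape[1], dtype=float)
    out = np.zeros(grid_shape, dtype=float)
    for comp in scene.components:
        out += _gaussian_on_grid(comp.center, comp.amplitude, comp.cov_array, rows, cols)
    return out


def _gaussian_on_grid(center, amplitude, cov, rows, cols) -> np.ndarray:
    inv = np.linalg.inv(cov)
    dy = rows - center[0]
    dx = cols - center[1]
    q = (inv[0, 0] * dy[:, None] ** 2
         + inv[1, 1] * dx[None, :] ** 2
         + 2.0 * inv[0, 1] * dy[:, None] * dx[None, :])
    return amplitude * np.exp(-0.5 * q)


# ---------------------------------------------------------------------------
# imaging operator
# ---------------------------------------------------------------------------

def apply_imaging_operator(scene: ObjectScene, system: ImagingSystemSpec) -> np.ndarray:
    """Apply the continuous-to-discrete Gaussian-PSF imaging operator.

    Each Gaussian component is integrated against the PSF analytically
    (Gaussian-Gaussian integral), so the result is exact up to round-off.
    Returns the noiseless image flattened row-major (length ``n_pixels``).
    """
    nr, nc = (int(s) for s in system.grid_shape)
    rows = np.arange(nr, dtype=float)
    cols = np.arange(nc, dtype=float)
    w2 = system.psf_width ** 2
    h = system.psf_height
    out = np.zeros((nr, nc), dtype=float)

    iso: list[GaussianComponent] = []
    aniso: list[GaussianComponent] = []
    for comp in scene.components:
        c = comp.cov_array
        if c[0, 1] == 0.0 and c[1, 0] == 0.0 and c[0, 0] == c[1, 1]:
            iso.append(comp)
        else:
            aniso.append(comp)

    # isotropic components with a shared variance batch into a separable
    # outer-product evaluation; this is the hot path for lumpy backgrounds
    if iso:
        variances = np.array([c.cov_array[0, 0] for c in iso])
        for s2 in np.unique(variances):
            group = [c for c, v in zip(iso, variances) if v == s2]
            v = s2 + w2
            amp = np.array([c.amplitude for c in group]) * h * (s2 / v)
            cy = np.array([c.center[0] for c in group])
            cx = np.array([c.center[1] for c in group])
            ey = np.exp(-0.5 * (rows[None, :] - cy[:, None]) ** 2 / v)
            ex = np.exp(-0.5 * (cols[None, :] - cx[:, None]) ** 2 / v)
            out += np.einsum("l,lr,lc->rc", amp, ey, ex, optimize=True)

    for comp in aniso:
        blurred = comp.cov_array + w2 * np.eye(2)
        gain = h * np.sqrt(np.linalg.det(comp.cov_array) / np.linalg.det(blurred))
        out += _gaussian_on_grid(comp.center, comp.amplitude * gain, blurred, rows, cols)

    return out.ravel()


def _imaged_lumpy_batch(rng: np.random.Generator,
                        n_images: int,
                        params: LumpyBackgroundParams,
                        system: ImagingSystemSpec) -> np.ndarray:
    """Noiseless imaged lumpy backgrounds (n_images, N), vectorized.

    Statistically identical to imaging ``sample_lumpy_scene`` draws one at
    a time, but draws all lump counts first and then all centres, and
    shares the exponential evaluations across lumps.  The scene stream
    depends only on ``rng`` and ``params`` (not on the PSF), which is what
    lets several imaging systems share one background stream.
    """
    nr, nc = (int(s) for s in system.grid_shape)
    counts = rng.poisson(params.mean_lump_count, size=n_images)
    total = int(counts.sum())
    centers = rng.uniform(0.0, [float(nr), float(nc)], size=(total, 2))
    out = np.zeros((n_images, nr * nc))
    if total == 0:
        return out
    s2 = params.lump_width ** 2
    v = s2 + system.psf_width ** 2
    gain = params.lump_amplitude * system.psf_height * (s2 / v)
    rows = np.arange(nr, dtype=float)
    cols = np.arange(nc, dtype=float)
    ey = np.exp(-0.5 * (rows[None, :] - centers[:, 0:1]) ** 2 / v) * gain
    ex = np.exp(-0.5 * (cols[None, :] - centers[:, 1:2]) ** 2 / v)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i in range(n_images):
        lo, hi = offsets[i], offsets[i + 1]
        if hi > lo:
            out[i] = (ey[lo:hi].T @ ex[lo:hi]).ravel()
    return out


def imaged_signal(signal: EllipticalSignalParams, angle: float,
                  system: ImagingSystemSpec) -> np.ndarray:
    """Noiseless imaged signal ``H fs`` for one orientation, flattened."""
    scene = ObjectScene(components=[signal_component(signal, angle)],
                        fov=tuple(float(s) for s in system.grid_shape))
    return apply_imaging_operator(scene, system)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def rescale_unit(images: np.ndarray, mode: str = "dataset") -> np.ndarray:
    """Min-max map a stack of images to [0, 1].

    ``mode="dataset"`` uses one (min, max) pair over the whole stack (an
    affine map of the data); ``mode="image"`` normalizes each image by its
    own range.
    """
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if mode == "dataset":
        lo, hi = images.min(), images.max()
        span = hi - lo if hi > lo else 1.0
        return (images - lo) / span
    lo = images.min(axis=1, keepdims=True)
    hi = images.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (images - lo) / span


def add_noise(rng: np.random.Generator, images: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the measurement noise model to a stack of images (n, N).

    With ``rescale_to_unit`` the [0, 1] normalization uses the stack passed
    to this call; when a dataset is built from several stacks that must
    share the normalization, noise the combined stack in one call (as
    ``generate_paired_dataset`` does).
    """
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if spec.kind == "gaussian_iid":
        if spec.gaussian_std == 0.0:
            return images.copy()
        return images + rng.normal(0.0, spec.gaussian_std, size=images.shape)
    # mixed Poisson + Gaussian; Poisson means clamped at zero to guard round-off
    lam = np.maximum(images, 0.0)
    counts = rng.poisson(lam)
    del lam
    noisy = counts.astype(float)
    del counts
    if spec.gaussian_std > 0.0:
        noisy += rng.normal(0.0, spec.gaussian_std, size=noisy.shape)
    if spec.rescale_to_unit:
        if spec.rescale_mode == "dataset":
            lo, hi = noisy.min(), noisy.max()
            noisy -= lo
            if hi > lo:
                noisy /= hi - lo
        else:
            noisy = rescale_unit(noisy, mode="image")
    return noisy


# ---------------------------------------------------------------------------
# paired datasets
# ---------------------------------------------------------------------------

@dataclass
class PairedImageSet:
    """Matched signal-present / signal-absent measured images.

    ``images_absent`` and ``images_present`` are (n_pairs, N) arrays of
    flattened images; ``angles`` records the signal orientation used for
    each signal-present image; ``meta`` carries every generation parameter
    and seed needed to reproduce the set bit-for-bit.
    """

    images_absent: np.ndarray
    images_present: np.ndarray
    grid_shape: tuple[int, int]
    angles: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images_absent = np.atleast_2d(np.asarray(self.images_absent, dtype=float))
        self.images_present = np.atleast_2d(np.asarray(self.images_present, dtype=float))
        _require(self.images_absent.shape == self.images_present.shape,
                 "present/absent image counts and sizes must match")
        _require(self.images_absent.shape[1] == int(self.grid_shape[0]) * int(self.grid_shape[1]),
                 "image length must equal grid size")
        _require(np.all(np.isfinite(self.images_absent)) and np.all(np.isfinite(self.images_present)),
                 "images must be finite")
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float)
            _require(self.angles.shape == (self.n_pairs,),
                     "one angle per signal-present image")

    @property
    def n_pairs(self) -> int:
        return self.images_absent.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.images_absent.shape[1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All images stacked (absent first) with 0/1 hypothesis labels."""
        images = np.vstack([self.images_absent, self.images_present])
        labels = np.concatenate([np.zeros(self.n_pairs, dtype=int),
                                 np.ones(self.n_pairs, dtype=int)])
        return images, labels

    def subset(self, indices: Sequence[int]) -> "PairedImageSet":
        idx = np.asarray(indices, dtype=int)
        return PairedImageSet(
            images_absent=self.images_absent[idx],
            images_present=self.images_present[idx],
            grid_shape=self.grid_shape,
            angles=None if self.angles is None else self.angles[idx],
            meta={**self.meta, "subset_indices": idx.copy()},
        )


def generate_paired_dataset(rng: np.random.Generator,
                            n_pairs: int,
                            background: LumpyBackgroundParams,
                            signal: EllipticalSignalParams,
                            system: ImagingSystemSpec,
                            noise: NoiseSpec | None) -> PairedImageSet:
    """Generate a paired detection-task dataset.

    2*n_pairs independent lumpy scenes are imaged; half receive the
    noiseless imaged signal (orientation drawn uniformly from the signal's
    angle set, independently per image) before noise is added, so that
    ``g = H(fb + fs) + n`` holds exactly.  ``noise=None`` yields noiseless
    measurements (used for oracles and the covariance-decomposition HO).

    The background scene stream depends only on ``rng`` and ``background``,
    so two calls with identically seeded generators and the same background
    parameters see the same object realizations even when the imaging
    system or noise model differ — the construction behind the shared-
    background domain-shift study.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    n_images = 2 * n_pairs
    backgrounds = _imaged_lumpy_batch(rng, n_images, background, system)

    angle_set = np.asarray(signal.angle_set, dtype=float)
    angle_idx = rng.integers(0, len(angle_set), size=n_pairs)
    angles = angle_set[angle_idx]
    signal_images = {a: imaged_signal(signal, a, system) for a in angle_set}

    # signal added in place to the second half of the combined stack, and
    # the stack noised in one call, so that any [0, 1] rescaling shares its
    # normalization constants across the two hypotheses
    for i, a in enumerate(angles):
        backgrounds[n_pairs + i] += signal_images[a]
    if noise is not None:
        backgrounds = add_noise(rng, backgrounds, noise)
    absent = backgrounds[:n_pairs].copy()
    present = backgrounds[n_pairs:].copy()
    del backgrounds

    meta = {
        "background": dataclasses.asdict(background),
        "signal": dataclasses.asdict(signal),
        "system": dataclasses.asdict(system),
        "noise": None if noise is None else dataclasses.asdict(noise),
        "n_pairs": int(n_pairs),
        "format_version": DATASET_FORMAT_VERSION,
    }
    return PairedImageSet(images_absent=absent, images_present=present,
                          grid_shape=system.grid_shape, angles=angles, meta=meta)


def generate_noiseless_backgrounds(rng: np.random.Generator,
                                   n_images: int,
                                   background: LumpyBackgroundParams,
                                   system: ImagingSystemSpec) -> np.ndarray:
    """Noiseless imaged lumpy backgrounds (n_images, N), for HO-CMD."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return _imaged_lumpy_batch(rng, n_images, background, system)


def amalgamate(datasets: Sequence[PairedImageSet],
               rng: np.random.Generator,
               n_pairs: int) -> PairedImageSet:
    """Evenly sample pairs without replacement from several datasets.

    Each source contributes ``n_pairs // len(datasets)`` pairs (the division
    must be exact); a per-pair source index is recorded in the metadata so
    train/validation/test separation can be audited downstream.
    """
    k = len(datasets)
    if k == 0:
        raise ValueError("need at least one source dataset")
    if n_pairs % k != 0:
        raise ValueError(f"n_pairs={n_pairs} not divisible by {k} sources")
    per = n_pairs // k
    grid = datasets[0].grid_shape
    for d in datasets:
        if tuple(d.grid_shape) != tuple(grid):
            raise ValueError("all sources must share grid_shape")
        if d.n_pairs < per:
            raise ValueError("a source has fewer pairs than its share")
    absent, present, angles, src = [], [], [], []
    has_angles = all(d.angles is not None for d in datasets)
    for j, d in enumerate(datasets):
        idx = rng.choice(d.n_pairs, size=per, replace=False)
        absent.append(d.images_absent[idx])
        present.append(d.images_present[idx])
        if has_angles:
            angles.append(d.angles[idx])
        src.append(np.full(per, j, dtype=int))
    meta = {"sources": [d.meta for d in datasets],
            "source_index": np.concatenate(src),
            "format_version": DATASET_FORMAT_VERSION}
    return PairedImageSet(images_absent=np.vstack(absent),
                          images_present=np.vstack(present),
                          grid_shape=grid,
                          angles=np.concatenate(angles) if has_angles else None,
                          meta=meta)


# ---------------------------------------------------------------------------
# container I/O (HDF5)
# ---------------------------------------------------------------------------

def save_dataset(path, dataset: PairedImageSet) -> None:
    """Write a PairedImageSet to an HDF5 container.

    Layout: datasets ``images_absent``, ``images_present`` and optionally
    ``angles``; attributes ``grid_shape``, ``format_version`` and a JSON
    dump of the generation metadata.
    """
    import json

    import h5py

    def _jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        return obj

    with h5py.File(path, "w") as f:
        f.create_dataset("images_absent", data=dataset.images_absent)
        f.create_dataset("images_present", data=dataset.images_present)
        if dataset.angles is not None:
            f.create_dataset("angles", data=dataset.angles)
        f.attrs["grid_shape"] = np.asarray(dataset.grid_shape, dtype=int)
        f.attrs["format_version"] = DATASET_FORMAT_VERSION
        f.attrs["meta_json"] = json.dumps(_jsonable(dataset.meta))


def load_dataset(path) -> PairedImageSet:
    """Read a PairedImageSet from the HDF5 container written by save_dataset."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        absent = f["images_absent"][...]
        present = f["images_present"][...]
        angles = f["angles"][...] if "angles" in f else None
        grid = tuple(int(s) for s in f.attrs["grid_shape"])
        meta = json.loads(f.attrs["meta_json"]) if "meta_json" in f.attrs else {}
    return PairedImageSet(images_absent=absent, images_present=present,
                          grid_shape=grid, angles=angles, meta=meta)
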
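"""Object model, imaging operator, noise and dataset assembly."""

import numpy as np
import pytest
import scipy.signal
import scipy.stats

import taskobs as tk
from taskobs.object_models import evaluate_scene

GRID64 = tk.ImagingSystemSpec()  # h=40, w=0.5, 64x64


# ---------------------------------------------------------------------------
# lumpy scenes
# ---------------------------------------------------------------------------

def test_parameter_validation_rejects_nonphysical_values():
    with pytest.raises(ValueError):
        tk.LumpyBackgroundParams(mean_lump_count=-1)
    with pytest.raises(ValueError):
        tk.LumpyBackgroundParams(lump_amplitude=0.0)
    with pytest.raises(ValueError):
        tk.ImagingSystemSpec(psf_width=0.0)
    with pytest.raises(ValueError):
        tk.NoiseSpec(gaussian_std=-1.0)
    with pytest.raises(ValueError):
        tk.NoiseSpec(kind="gaussian_iid", rescale_to_unit=True)
    with pytest.raises(ValueError):
        tk.EllipticalSignalParams(angle_set=())


def test_zero_mean_lump_count_gives_empty_scenes(rng, background):
    params = tk.LumpyBackgroundParams(mean_lump_count=0.0)
    for _ in range(20):
        assert sample_count(rng, params) == 0


def sample_count(rng, params):
    return len(tk.sample_lumpy_scene(rng, params).components)


def test_lump_count_is_poisson(rng, background):
    """Mean count ~5 over 10,000 draws, and the count distribution passes a
    chi-square test against the Poisson(5) pmf at alpha = 0.01."""
    n = 100_000
    counts = np.array([sample_count(rng, background) for _ in range(n)])
    assert abs(counts.mean() - 5.0) < 3.0 * np.sqrt(5.0 / n)

    kmax = 15
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    pmf = scipy.stats.poisson.pmf(np.arange(kmax), 5.0)
    probs = np.append(pmf, 1.0 - pmf.sum())
    stat = ((observed - n * probs) ** 2 / (n * probs)).sum()
    crit = scipy.stats.chi2.ppf(0.99, df=kmax)
    assert stat < crit


def test_lump_centers_uniform_over_fov(rng, background):
    centers = np.array([c.center
                        for _ in range(2000)
                        for c in tk.sample_lumpy_scene(rng, background).components])
    assert centers.min() >= 0.0 and centers.max() < 64.0
    # KS against uniform on each axis
    for axis in (0, 1):
        p = scipy.stats.kstest(centers[:, axis] / 64.0, "uniform").pvalue
        assert p > 1e-4


# ---------------------------------------------------------------------------
# signal component
# ---------------------------------------------------------------------------

def test_signal_peak_value_is_amplitude(signal_params):
    comp = tk.signal_component(signal_params, 0.0)
    scene = tk.ObjectScene(components=[comp])
    img = evaluate_scene(scene, (64, 64))
    assert img[32, 32] == pytest.approx(0.2, rel=1e-12)


def test_signal_rotation_by_90_swaps_axes():
    params = tk.EllipticalSignalParams(angle_set=(0.0, 90.0))
    img0 = evaluate_scene(tk.ObjectScene(components=[tk.signal_component(params, 0.0)]), (64, 64))
    img90 = evaluate_scene(tk.ObjectScene(components=[tk.signal_component(params, 90.0)]), (64, 64))
    swapped = tk.EllipticalSignalParams(width_x=params.width_y, width_y=params.width_x,
                                        angle_set=(0.0,))
    img_sw = evaluate_scene(tk.ObjectScene(components=[tk.signal_component(swapped, 0.0)]), (64, 64))
    np.testing.assert_allclose(img90, img_sw, atol=1e-12)
    assert not np.allclose(img0, img90)


def test_signal_rotation_matches_direct_formula():
    """Rendering at 45 degrees equals direct evaluation of the rotated
    anisotropic Gaussian, to machine tolerance."""
    params = tk.EllipticalSignalParams(angle_set=(45.0,))
    img = evaluate_scene(tk.ObjectScene(components=[tk.signal_component(params, 45.0)]), (64, 64))
    th = np.deg2rad(45.0)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    dinv = np.linalg.inv(np.diag([2 * 5.0 ** 2, 2 * 1.5 ** 2]))
    expect = np.empty((64, 64))
    for r in range(64):
        for c in range(64):
            u = np.array([c - 32.0, r - 32.0])  # (x, y) = (col, row)
            v = rot @ u
            expect[r, c] = 0.2 * np.exp(-(v @ dinv @ v))
    np.testing.assert_allclose(img, expect, atol=1e-13)


# ---------------------------------------------------------------------------
# imaging operator
# ---------------------------------------------------------------------------

def test_empty_scene_images_to_zero():
    img = tk.apply_imaging_operator(tk.ObjectScene(components=[]), GRID64)
    assert img.shape == (4096,)
    assert np.all(img == 0.0)


def test_single_lump_peak_matches_closed_form_and_quadrature():
    """Peak pixel value a*h*s^2/(s^2+w^2) for a lump centred on a pixel, and
    agreement with 2-D numerical quadrature at an off-centre position.

    The quadrature reference 39.72429532511797 was computed with
    scipy.integrate.dblquad (epsabs 1e-10) for a unit lump (s=7) at
    (30.3, 25.7) seen by pixel (30, 26) through the h=40, w=0.5 system.
    """
    s2 = 49.0
    lump = tk.GaussianComponent(center=(32.0, 32.0), amplitude=1.0,
                                cov=((s2, 0.0), (0.0, s2)))
    img = tk.apply_imaging_operator(tk.ObjectScene(components=[lump]), GRID64).reshape(64, 64)
    assert img[32, 32] == pytest.approx(40.0 * 49.0 / 49.25, rel=1e-12)

    lump_off = tk.GaussianComponent(center=(30.3, 25.7), amplitude=1.0,
                                    cov=((s2, 0.0), (0.0, s2)))
    img2 = tk.apply_imaging_operator(tk.ObjectScene(components=[lump_off]), GRID64).reshape(64, 64)
    assert img2[30, 26] == pytest.approx(39.72429532511797, rel=1e-6)


def test_imaging_is_linear(rng):
    scenes = [tk.sample_lumpy_scene(rng, tk.LumpyBackgroundParams()) for _ in range(2)]
    joint = tk.ObjectScene(components=scenes[0].components + scenes[1].components)
    merged = tk.apply_imaging_operator(joint, GRID64)
    summed = sum(tk.apply_imaging_operator(s, GRID64) for s in scenes)
    np.testing.assert_allclose(merged, summed, rtol=1e-12, atol=1e-12)


def test_closed_form_blur_matches_fft_convolution(rng):
    """Analytic Gaussian-Gaussian imaging agrees with discrete convolution
    of a finely rasterized scene with the rasterized PSF (interior pixels,
    1e-3 relative)."""
    system = tk.ImagingSystemSpec(psf_height=40.0, psf_width=2.0, grid_shape=(64, 64))
    scene = tk.sample_lumpy_scene(np.random.default_rng(7), tk.LumpyBackgroundParams())
    analytic = tk.apply_imaging_operator(scene, system).reshape(64, 64)

    up = 4   # rasterize at 4x resolution
    pad = 16  # extend beyond the field of view to capture lump tails
    coords = np.arange(-pad * up, (64 + pad) * up) / up
    n = coords.size
    fine = np.zeros((n, n))
    for comp in scene.components:
        inv = np.linalg.inv(comp.cov_array)
        dy = coords - comp.center[0]
        dx = coords - comp.center[1]
        q = (inv[0, 0] * dy[:, None] ** 2 + inv[1, 1] * dx[None, :] ** 2
             + 2 * inv[0, 1] * dy[:, None] * dx[None, :])
        fine += comp.amplitude * np.exp(-0.5 * q)
    w = system.psf_width
    k = np.arange(-6 * w * up, 6 * w * up + 1) / up
    psf1d = np.exp(-0.5 * k ** 2 / w ** 2)
    psf = system.psf_height / (2 * np.pi * w ** 2) * np.outer(psf1d, psf1d) / up ** 2
    blurred = scipy.signal.fftconvolve(fine, psf, mode="same")
    discrete = blurred[pad * up::up, pad * up::up][:64, :64]

    interior = (slice(8, 56), slice(8, 56))
    scale = np.abs(analytic[interior]).max()
    err = np.abs(discrete[interior] - analytic[interior]) / scale
    assert err.max() < 1e-3


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def test_zero_std_gaussian_noise_is_identity(rng):
    images = rng.random((3, 16))
    out = tk.add_noise(rng, images, tk.NoiseSpec.gaussian(0.0))
    np.testing.assert_array_equal(out, images)


def test_mixed_noise_variance_is_poisson_plus_gaussian(rng):
    """Poisson(c) + N(0,1) has variance c + 1; checked on a constant image."""
    c = 12.0
    images = np.full((40, 4096), c)
    spec = tk.NoiseSpec(kind="poisson_plus_gaussian", gaussian_std=1.0)
    out = tk.add_noise(rng, images, spec)
    var = out.ravel().var()
    assert abs(var - (c + 1.0)) / (c + 1.0) < 0.05


def test_mixed_noise_rescale_modes(rng):
    images = rng.random((5, 64)) * 30.0
    per_image = tk.add_noise(rng, images, tk.NoiseSpec.mixed(rescale_mode="image"))
    np.testing.assert_allclose(per_image.min(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(per_image.max(axis=1), 1.0, atol=1e-12)
    global_ = tk.add_noise(rng, images, tk.NoiseSpec.mixed())
    assert global_.min() == pytest.approx(0.0, abs=1e-12)
    assert global_.max() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# paired datasets
# ---------------------------------------------------------------------------

def test_dataset_shapes_and_angles(rng, background, small_signal, small_system):
    ds = tk.generate_paired_dataset(rng, 10, background, small_signal,
                                    small_system, tk.NoiseSpec.gaussian(5.0))
    assert ds.images_absent.shape == (10, 256)
    assert ds.images_present.shape == (10, 256)
    assert ds.angles.shape == (10,)
    assert set(ds.angles) <= set(small_signal.angle_set)


def test_noiseless_class_mean_difference_is_imaged_signal(rng, small_system):
    """With noise disabled and the background term removed (zero lumps, so
    the independent background draws of the two hypotheses cannot leak into
    the difference), mean(present) - mean(absent) equals the mean noiseless
    imaged signal over the recorded angles, to machine tolerance."""
    empty = tk.LumpyBackgroundParams(mean_lump_count=0.0)
    sks = tk.EllipticalSignalParams(amplitude=0.2, width_x=3.0, width_y=1.0,
                                    angle_set=(0.0, 45.0, 90.0, 135.0),
                                    center=(8.0, 8.0))
    ds = tk.generate_paired_dataset(rng, 40, empty, sks, small_system, None)
    expected = np.mean([tk.imaged_signal(sks, a, small_system) for a in ds.angles], axis=0)
    delta = ds.images_present.mean(axis=0) - ds.images_absent.mean(axis=0)
    np.testing.assert_allclose(delta, expected, atol=1e-12)
    assert np.all(ds.images_absent == 0.0)


def test_dataset_determinism(background, small_signal, small_system):
    make = lambda: tk.generate_paired_dataset(
        np.random.default_rng(99), 12, background, small_signal,
        small_system, tk.NoiseSpec.mixed())
    a, b = make(), make()
    np.testing.assert_array_equal(a.images_absent, b.images_absent)
    np.testing.assert_array_equal(a.images_present, b.images_present)
    np.testing.assert_array_equal(a.angles, b.angles)


def test_background_stream_shared_across_system_widths(background, small_signal):
    """Identically seeded generation through different PSF widths sees the
    same object realizations: total imaged flux (h times object mass inside
    the field of view) agrees closely, though the blur differs."""
    imgs = {}
    for w in (0.5, 2.0):
        system = tk.ImagingSystemSpec(psf_width=w, grid_shape=(16, 16))
        ds = tk.generate_paired_dataset(np.random.default_rng(5), 30, background,
                                        small_signal, system, None)
        imgs[w] = ds.images_absent
    flux_a = imgs[0.5].sum(axis=1)
    flux_b = imgs[2.0].sum(axis=1)
    np.testing.assert_allclose(flux_a, flux_b, rtol=0.05)
    assert not np.allclose(imgs[0.5], imgs[2.0])


def test_amalgamate_even_sampling_without_replacement(rng, small_dataset):
    parts = [small_dataset.subset(range(0, 20)),
             small_dataset.subset(range(20, 40)),
             small_dataset.subset(range(40, 60))]
    out = tk.amalgamate(parts, rng, 30)
    assert out.n_pairs == 30
    src = out.meta["source_index"]
    assert all((src == j).sum() == 10 for j in range(3))
    rows = {r.tobytes() for r in out.images_absent}
    assert len(rows) == 30  # no pair sampled twice

    single = tk.amalgamate([parts[0]], rng, 15)
    pool = {r.tobytes() for r in parts[0].images_absent}
    assert all(r.tobytes() in pool for r in single.images_absent)

    with pytest.raises(ValueError):
        tk.amalgamate(parts, rng, 90)  # more than available per source


def test_dataset_round_trip_is_bit_identical(tmp_path, small_dataset):
    path = tmp_path / "ds.h5"
    tk.save_dataset(path, small_dataset)
    back = tk.load_dataset(path)
    np.testing.assert_array_equal(back.images_absent, small_dataset.images_absent)
    np.testing.assert_array_equal(back.images_present, small_dataset.images_present)
    np.testing.assert_array_equal(back.angles, small_dataset.angles)
    assert back.grid_shape == small_dataset.grid_shape
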
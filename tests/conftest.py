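"""Shared fixtures: small synthetic detection datasets and default parameter sets."""

import numpy as np
import pytest

import taskobs as tk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def background():
    return tk.LumpyBackgroundParams()


@pytest.fixture
def signal_params():
    return tk.EllipticalSignalParams()


@pytest.fixture
def small_system():
    """16x16 grid keeps covariance work trivial in unit tests."""
    return tk.ImagingSystemSpec(psf_height=40.0, psf_width=0.5, grid_shape=(16, 16))


@pytest.fixture
def small_signal():
    return tk.EllipticalSignalParams(amplitude=0.2, width_x=3.0, width_y=1.0,
                                     angle_set=(0.0,), center=(8.0, 8.0))


@pytest.fixture
def small_dataset(rng, background, small_signal, small_system):
    """60 pairs of noisy 16x16 images, Gaussian noise."""
    return tk.generate_paired_dataset(rng, 60, background, small_signal,
                                      small_system, tk.NoiseSpec.gaussian(5.0))


def make_gaussian_scores(rng, n0, n1, mu0=0.0, mu1=1.0, s0=1.0, s1=1.0):
    """Score set with Gaussian class-conditional distributions."""
    scores = np.concatenate([rng.normal(mu0, s0, n0), rng.normal(mu1, s1, n1)])
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return tk.ScoreSet(scores=scores, labels=labels)
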
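# taskobs

Model observers for objective image-quality assessment: simulate binary
signal-detection tasks on lumpy stochastic backgrounds, build Hotelling
and channelized Hotelling observers (CHO), learn CHO channels with a
task-informed linear autoencoder, and score everything with binormal-fit
and empirical AUC.

## The problem

Imaging systems are best compared by how well an observer can perform a
diagnostic task on their images, not by visual appeal. The gold-standard
linear figure of merit is the Hotelling observer (HO), whose template
solves

    w_HO = [ (K_0 + K_1) / 2 ]^{-1} (g1_bar - g0_bar),

with K_j and gj_bar the covariance and mean of the image data under
hypothesis H_j (signal absent / present). For N-pixel images the N x N
covariance makes the HO expensive and data-hungry, so practitioners
project images onto a few channels, v = T g, and compute the HO in channel
space (the CHO):

    t(v) = (K_v^{-1} dv_bar)^T v.

Everything then rests on finding *efficient* channels — a T whose CHO
approaches the HO. This package implements the classical channel families
(Laguerre-Gauss, convolutional LG / filtered-channel observer, partial
least squares, nonprewhitening matched filter) and a learned alternative:
a tied-weight, bias-free linear autoencoder whose encoder W^T doubles as
T. With the conventional reconstruction loss the autoencoder learns
background structure and its channels are nearly useless for detection;
replacing the reconstruction target by the signal-present indicator times
the mean signal,

    L_task(W) = (1/P) * sum_i || W W^T g_i - I(g_i) * dg_bar ||^2,

forces the embedding to encode only task-relevant structure and yields
channels competitive with the best hand-crafted families — including under
domain shift, when an observer built on one imaging system is applied to
another.

The package generates its own inputs: 64x64 images of a lumpy object
model (Poisson number of Gaussian lumps) seen through an idealized
parallel-hole-collimator system with a Gaussian point response, under
i.i.d. Gaussian or mixed Poisson/Gaussian noise. User-supplied ROI stacks
(e.g. digital-mammography crops) load through a documented HDF5 layout.

## Worked example

Location-known elliptical signal (amplitude 0.2, widths 5 x 1.5 px) on the
lumpy background with delta = 20 Gaussian noise; a 10-channel
convolutional-LG CHO against the nonprewhitening matched filter:

```python
import numpy as np
import taskobs as tk

rng = np.random.default_rng(0)
background = tk.LumpyBackgroundParams()                  # L ~ Poisson(5), a=1, s=7
signal = tk.EllipticalSignalParams()                     # A=0.2, sx=5, sy=1.5
system = tk.ImagingSystemSpec()                          # h=40, w=0.5, 64x64
noise = tk.NoiseSpec.gaussian(20.0)                      # i.i.d. N(0, 20^2)

train = tk.generate_paired_dataset(rng, 2000, background, signal, system, noise)
covar = tk.generate_paired_dataset(rng, 500, background, signal, system, noise)
test  = tk.generate_paired_dataset(rng, 500, background, signal, system, noise)

delta = tk.estimate_mean_signal(train)                   # noisy signal estimate

base = tk.lg_channels(10, 25.0, (64, 64), center=signal.center)
fco = tk.conv_lg_channels(base, delta)                   # LG convolved with the signal
cho = tk.cho_build(fco, covar, delta)                    # whiten in channel space

for name, obs in [("conv-LG CHO (10 ch)", cho),
                  ("NPWMF", tk.npwmf_observer(delta))]:
    scores = tk.score_dataset(obs, test)
    roc = tk.binormal_fit(scores, rng=np.random.default_rng(1))
    print(f"{name:20s} AUC {roc.auc_binormal:.3f} +/- {roc.auc_std:.3f}"
          f"  (empirical {roc.auc_empirical:.3f}, SNR {tk.snr(scores):.2f})")
```

Output:

```
conv-LG CHO (10 ch)  AUC 0.739 +/- 0.015  (empirical 0.737, SNR 0.91)
NPWMF                AUC 0.517 +/- 0.018  (empirical 0.526, SNR 0.06)
```

Reading it: at this faint signal amplitude and noise level, matched
filtering without prewhitening is nearly blind (AUC ~ 0.52, chance is
0.50), because the lumpy background, not the detector noise, dominates the
image covariance. Whitening in a 10-dimensional channel space lifts the
same signal estimate to AUC ~ 0.74. The `+/-` is a case-bootstrap standard
deviation of the binormal-fit AUC; the test-statistic SNR relates to AUC
by AUC = Phi(SNR / sqrt(2)) for Gaussian scores.

Larger studies (training-set-size sweeps, the fixed-signal variant, the
domain-shift and amalgamation grids) run through `taskobs.run_size_sweep`
/ `taskobs.run_domain_shift` or the CLI:

```
taskobs simulate --n-pairs 1000 --seed 1 --out data.h5
taskobs train --dataset data.h5 --loss task --channels 10 --lr 1e-5 --out obs.h5
taskobs evaluate --observer obs.h5 --dataset data.h5
taskobs study --config study.yaml --out-dir results/
```

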
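"""Bias-corrected single-cell Fisher information.

Compares a spatially tuned and an untuned cell. The naive signal-to-noise
ratio between two locations is positive in expectation even for an untuned
cell (sampling noise in the means); the finite-sample correction removes
that bias, so untuned cells scatter around zero while tuned cells stay
positive.
"""

import numpy as np

from dgspace import pairwise_bias_corrected_snr, single_cell_fi
from dgspace.preprocess import MovementMask
from dgspace.session import PositionTrack

rng = np.random.default_rng(1)
n, belt = 9000, 180.0
time = np.arange(n) / 15.0
position = np.mod(20.0 * time, belt)
track = PositionTrack.from_position(position, time, belt)
mask = MovementMask(np.ones(n, dtype=bool), ((0, n),))

theta = 2 * np.pi * position / belt
tuned = 0.8 * np.exp(2.0 * (np.cos(theta - 1.0) - 1.0)) + rng.normal(0, 0.3, n)
untuned = rng.normal(0, 0.3, n)

est = single_cell_fi(np.vstack([tuned, untuned]), track, mask, 20, belt)
print(f"tuned cell   FI = {est.fi[0]:+.4f}  ({est.n_usable_pairs[0]} adjacent bin pairs)")
print(f"untuned cell FI = {est.fi[1]:+.4f}")

# the bias at work: equal-mean Gaussian samples, T = 50 per location
T = 50
raw_vals, cor_vals = [], []
for _ in range(2000):
    xj, xk = rng.normal(0, 1, T), rng.normal(0, 1, T)
    cor = pairwise_bias_corrected_snr(xj, xk)
    cor_vals.append(cor)
    raw_vals.append((cor + 2 / T) * (2 * T - 2) / (2 * T - 4))
print(f"\nnull pair, T={T}: raw SNR averages {np.mean(raw_vals):.4f} "
      f"(analytic bias 2/T = {2 / T}), corrected averages {np.mean(cor_vals):+.4f}")
print("A corrected value can be negative on a single estimate; only its "
      "average is anchored at the true discriminability.")
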
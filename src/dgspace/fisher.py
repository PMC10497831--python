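"""Bias-corrected single-cell Fisher information across belt position bins.

The discriminability of two belt locations j, k by one cell is a
signal-to-noise ratio: signal = squared difference of the mean unfiltered
ΔF/F at the two locations, noise = average of the two within-location
variances. The naive ratio is biased upward for finite samples (it is
positive in expectation even for an untuned cell); the single-neuron
finite-sample correction used here is

    FI_bc = raw · (2T − 4) / (2T − 2) − 2 / (T · δs²),

with T = min(T_j, T_k) samples per location and δs the stimulus spacing
(1 bin by convention). Under Gaussian sampling with equal per-location
variance this estimator is exactly unbiased for (Δμ)²/σ² (the correction
factor cancels the inverse-variance moment, the subtracted term the
mean-difference sampling variance), so null cells average 0 — possibly
going negative on any single estimate.

A cell's FI is the mean of the pairwise estimate over the circularly
adjacent bin pairs (Fisher information is a local, slope-like quantity);
an all-pairs mode with distance-scaled δs is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import MovementMask
from .session import PositionTrack
from .tuning import position_bins

__all__ = [
    "FisherEstimate",
    "DegeneratePairError",
    "InsufficientSamplesError",
    "bin_samples",
    "pairwise_bias_corrected_snr",
    "single_cell_fi",
]


class DegeneratePairError(ValueError):
    """Both locations have zero pooled variance; the SNR is undefined."""


class InsufficientSamplesError(ValueError):
    """Fewer than 3 samples at one of the two locations."""


@dataclass(frozen=True)
class FisherEstimate:
    """Per-cell bias-corrected spatial discriminability.

    ``fi`` is NaN for cells with no usable bin pair (``defined`` False).
    ``per_pair`` holds the pairwise estimates (NaN where a pair was skipped
    for degeneracy or insufficient samples).
    """

    fi: np.ndarray  # (cells,)
    per_pair: np.ndarray  # (cells, n_pairs)
    samples_per_bin: np.ndarray  # (n_bins,) counts T_j
    n_usable_pairs: np.ndarray  # (cells,)
    defined: np.ndarray  # (cells,) bool
    pairs: tuple[tuple[int, int], ...]


def bin_samples(
    dff_raw: np.ndarray,
    track: PositionTrack,
    mask: MovementMask,
    n_bins: int,
    belt_length: float,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Assign each moving frame's raw ΔF/F value to its position bin.

    Returns per-bin sample arrays (for a single cell trace) and the counts
    T_j. ``dff_raw`` is 1-D here; :func:`single_cell_fi` handles matrices.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    dff_raw = np.asarray(dff_raw, dtype=float)
    bins = position_bins(track.position, belt_length, n_bins)
    m = mask.moving
    bins_m, vals = bins[m], dff_raw[m]
    counts = np.bincount(bins_m, minlength=n_bins)
    order = np.argsort(bins_m, kind="stable")
    split = np.split(vals[order], np.cumsum(counts)[:-1])
    return split, counts


def pairwise_bias_corrected_snr(
    samples_j: np.ndarray, samples_k: np.ndarray, delta_s: float = 1.0
) -> float:
    """Bias-corrected SNR between two locations' response samples.

    With sample means μ̂, sample variances s² (ddof=1), pooled noise
    σ̂² = (s²_j + s²_k)/2 and T = min(T_j, T_k):

        raw = (μ̂_j − μ̂_k)² / σ̂²
        corrected = raw·(2T − 4)/(2T − 2)/δs² − 2/(T·δs²)

    Raises :class:`InsufficientSamplesError` for T < 3 and
    :class:`DegeneratePairError` for σ̂² = 0.
    """
    xj = np.asarray(samples_j, dtype=float)
    xk = np.asarray(samples_k, dtype=float)
    T = min(xj.size, xk.size)
    if T < 3:
        raise InsufficientSamplesError(f"need >= 3 samples per location, got T={T}")
    pooled = (xj.var(ddof=1) + xk.var(ddof=1)) / 2.0
    if pooled <= 0:
        raise DegeneratePairError("zero pooled variance at both locations")
    raw = (xj.mean() - xk.mean()) ** 2 / pooled
    ds2 = delta_s**2
    return raw * (2 * T - 4) / (2 * T - 2) / ds2 - 2.0 / (T * ds2)


def _circular_pairs(n_bins: int, mode: str) -> list[tuple[int, int]]:
    if mode == "adjacent":
        return [(j, (j + 1) % n_bins) for j in range(n_bins)]
    if mode == "all":
        return [(j, k) for j in range(n_bins) for k in range(j + 1, n_bins)]
    raise ValueError("pairs mode must be 'adjacent' or 'all'")


def _circular_distance(j: int, k: int, n_bins: int) -> int:
    d = abs(j - k) % n_bins
    return min(d, n_bins - d)


def single_cell_fi(
    dff_raw: np.ndarray,
    track: PositionTrack,
    mask: MovementMask,
    n_bins: int,
    belt_length: float,
    pairs: str = "adjacent",
) -> FisherEstimate:
    """Bias-corrected Fisher information per cell over belt position bins.

    ``dff_raw`` is the (cells, frames) *unfiltered* ΔF/F matrix. Movement
    frames are binned by position; for every circularly adjacent bin pair
    (or all pairs with δs = circular bin distance, ``pairs="all"``) the
    bias-corrected SNR is computed, and a cell's FI is the mean over pairs
    with both bins usable (T ≥ 3, nonzero pooled variance). Pairs skipped
    for degeneracy are excluded from the mean; cells with no usable pair
    are flagged undefined (NaN), not raised.
    """
    dff_raw = np.atleast_2d(np.asarray(dff_raw, dtype=float))
    n_cells = dff_raw.shape[0]
    bins = position_bins(track.position, belt_length, n_bins)
    m = mask.moving
    bins_m = bins[m]
    vals = dff_raw[:, m]
    counts = np.bincount(bins_m, minlength=n_bins)

    # per (cell, bin) sums and sums of squares -> means and sample variances
    s1 = np.zeros((n_bins, n_cells))
    s2 = np.zeros((n_bins, n_cells))
    np.add.at(s1, bins_m, vals.T)
    np.add.at(s2, bins_m, (vals**2).T)
    s1, s2 = s1.T, s2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / counts
        var = (s2 - counts * mean**2) / (counts - 1)
    var = np.maximum(var, 0.0)  # guard tiny negative rounding residue

    pair_list = _circular_pairs(n_bins, pairs)
    jj = np.array([p[0] for p in pair_list])
    kk = np.array([p[1] for p in pair_list])
    T = np.minimum(counts[jj], counts[kk]).astype(float)
    if pairs == "all":
        ds = np.array([_circular_distance(j, k, n_bins) for j, k in pair_list], float)
    else:
        ds = np.ones(len(pair_list))

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (var[:, jj] + var[:, kk]) / 2.0
        raw = (mean[:, jj] - mean[:, kk]) ** 2 / pooled
        corrected = raw * (2 * T - 4) / (2 * T - 2) / ds**2 - 2.0 / (T * ds**2)
    usable = (T >= 3) & (pooled > 0) & np.isfinite(corrected)
    per_pair = np.where(usable, corrected, np.nan)
    n_usable = usable.sum(axis=1)
    defined = n_usable > 0
    fi = np.full(n_cells, np.nan)
    with np.errstate(invalid="ignore"):
        fi[defined] = np.nanmean(per_pair[defined], axis=1)
    return FisherEstimate(
        fi=fi,
        per_pair=per_pair,
        samples_per_bin=counts,
        n_usable_pairs=n_usable,
        defined=defined,
        pairs=tuple(pair_list),
    )
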
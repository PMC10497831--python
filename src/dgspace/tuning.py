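"""Spatial tuning on the circular belt: occupancy maps, tuning vectors, the
circular tuning index, lap rasters, and top-decile cell selection.

The belt loops, so the 100 position bins map to angles on the circle and the
tuning index of a cell is the modulus (mean resultant length) of its
occupancy-normalized, sum-normalized rate map: 0 for spatially uniform
activity, 1 for activity confined to a single bin. For a noiseless place
cell with a von Mises tuning curve of concentration κ the index converges to
``I₁(κ)/I₀(κ)`` (ratio of modified Bessel functions) in the many-lap limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np

from .preprocess import MovementMask, ThresholdedTraces
from .session import PositionTrack

__all__ = [
    "TuningResult",
    "LapRaster",
    "RasterError",
    "position_bins",
    "occupancy_map",
    "tuning_vector",
    "tuning_index",
    "lap_raster",
    "select_top_fi_cells",
]


class RasterError(ValueError):
    """Raised when a lap raster is requested with no completed lap."""


@dataclass(frozen=True)
class TuningResult:
    """Per-cell rate maps and circular tuning indices for one session.

    Cells whose rate map sums to zero have no defined tuning direction:
    ``defined`` is False, ``weights`` rows are zero, and ``tuning_index`` is
    NaN (flagged, excluded from group statistics — never an exception).
    """

    rate_map: np.ndarray  # (cells, n_bins), a.u./s
    occupancy: np.ndarray  # (n_bins,), s
    weights: np.ndarray  # (cells, n_bins), rows sum to 1 when defined
    tuning_index: np.ndarray  # (cells,), in [0, 1] or NaN
    preferred_bin: np.ndarray  # (cells,) argmax of rate_map
    defined: np.ndarray  # (cells,) bool
    source: str = "unknown"  # trace source the rates came from


@dataclass(frozen=True)
class LapRaster:
    """Per-lap, per-bin suprathreshold activity with an even/odd lap split.

    ``sort_order`` permutes cells by ascending preferred bin computed on all
    laps; the same order applies to both parity sub-rasters.
    """

    raster: np.ndarray  # (cells, laps, n_bins)
    even: np.ndarray  # (cells, laps_even, n_bins) — laps 0, 2, ...
    odd: np.ndarray  # (cells, laps_odd, n_bins)
    sort_order: np.ndarray  # (cells,) permutation


def position_bins(position: np.ndarray, belt_length: float, n_bins: int) -> np.ndarray:
    """Equal-width half-open belt bins: bin j covers [j·L/n, (j+1)·L/n)."""
    b = np.floor(np.asarray(position) / belt_length * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


def occupancy_map(
    track: PositionTrack, mask: MovementMask, n_bins: int, belt_length: float
) -> np.ndarray:
    """Seconds spent per belt bin during movement epochs.

    Each moving frame contributes its duration Δt to the bin containing its
    position; non-moving frames contribute nothing.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bins = position_bins(track.position, belt_length, n_bins)
    dt = track.frame_dt()
    m = mask.moving
    return np.bincount(bins[m], weights=dt[m], minlength=n_bins)


def _binned_activity(
    supra: np.ndarray,
    track: PositionTrack,
    frames: np.ndarray,
    n_bins: int,
    belt_length: float,
) -> np.ndarray:
    """Sum of supra·Δt per (cell, bin) over the given frame selection."""
    bins = position_bins(track.position, belt_length, n_bins)[frames]
    dt = track.frame_dt()[frames]
    acc = np.zeros((n_bins, supra.shape[0]))
    np.add.at(acc, bins, (supra[:, frames] * dt).T)
    return acc.T


def tuning_vector(
    thresholded: ThresholdedTraces,
    track: PositionTrack,
    mask: MovementMask,
    n_bins: int,
    belt_length: float,
) -> TuningResult:
    """Occupancy-normalized rate maps and circular tuning indices.

    ``rate_map[c, j]`` is the time-weighted mean suprathreshold activity of
    cell c in bin j during movement, i.e. (Σ supra·Δt over moving frames in
    bin j) / occupancy[j]. Unoccupied bins get rate 0 and are excluded from
    the normalization rather than interpolated. ``weights`` is the rate map
    normalized to sum 1, and ``tuning_index`` its mean resultant length.
    """
    occ = occupancy_map(track, mask, n_bins, belt_length)
    num = _binned_activity(
        thresholded.supra, track, np.flatnonzero(mask.moving), n_bins, belt_length
    )
    rate = np.zeros_like(num)
    occupied = occ > 0
    rate[:, occupied] = num[:, occupied] / occ[occupied]
    totals = rate.sum(axis=1)
    defined = totals > 0
    weights = np.zeros_like(rate)
    weights[defined] = rate[defined] / totals[defined, None]
    ti = np.full(rate.shape[0], np.nan)
    ti[defined] = tuning_index(weights[defined])
    return TuningResult(
        rate_map=rate,
        occupancy=occ,
        weights=weights,
        tuning_index=ti,
        preferred_bin=rate.argmax(axis=1),
        defined=defined,
        source=thresholded.source,
    )


def tuning_index(weights: np.ndarray) -> np.ndarray | float:
    """Modulus of the normalized tuning vector (mean resultant length).

    Bin j (of n) maps to the bin-centre angle θ_j = 2π(j + 0.5)/n; the index
    is ``|Σ_j w_j e^{iθ_j}|`` for weights w on the simplex. Returns a scalar
    for a 1-D weight vector, a per-row array for a matrix.
    """
    w = np.asarray(weights, dtype=float)
    one_d = w.ndim == 1
    w = np.atleast_2d(w)
    n = w.shape[-1]
    theta = 2 * np.pi * (np.arange(n) + 0.5) / n
    resultant = np.abs(w @ np.exp(1j * theta))
    return float(resultant[0]) if one_d else resultant


def lap_raster(
    thresholded: ThresholdedTraces,
    track: PositionTrack,
    mask: MovementMask,
    n_bins: int,
    belt_length: float,
) -> LapRaster:
    """Lap-by-bin activity rasters with an even/odd lap parity split.

    Requires at least one completed lap (one belt wrap). All laps touched by
    the recording are included; the even/odd sub-rasters partition them by
    lap parity. Cells are sorted by the bin of their all-lap activity
    maximum, ties broken by cell index, and the same order is reused for
    both parities.
    """
    n_laps = int(track.lap_index.max()) + 1
    if int(track.lap_index.max()) < 1:
        raise RasterError("lap raster requires at least one completed lap")
    supra = thresholded.supra
    bins = position_bins(track.position, belt_length, n_bins)
    dt = track.frame_dt()
    raster = np.zeros((supra.shape[0], n_laps, n_bins))
    m = np.flatnonzero(mask.moving)
    flat = track.lap_index[m] * n_bins + bins[m]
    acc = np.zeros((n_laps * n_bins, supra.shape[0]))
    np.add.at(acc, flat, (supra[:, m] * dt[m]).T)
    raster = acc.T.reshape(supra.shape[0], n_laps, n_bins)
    all_lap = raster.sum(axis=1)
    sort_order = np.argsort(all_lap.argmax(axis=1), kind="stable")
    return LapRaster(
        raster=raster,
        even=raster[:, 0::2, :],
        odd=raster[:, 1::2, :],
        sort_order=sort_order,
    )


def select_top_fi_cells(
    fi: Sequence[float],
    cell_ids: Sequence[str],
    fraction: float = 0.1,
    mode: str = "top",
) -> list[str]:
    """Cells in the extreme Fisher-information decile.

    Returns the ``⌈fraction·n⌉`` defined cells with the largest FI
    (``mode="top"``, the place-cell-like high-information cells) or smallest
    (``mode="bottom"``). Ties are broken by lexicographic cell id so the
    selection is deterministic. Cells with undefined (NaN) FI are excluded
    from n.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if mode not in ("top", "bottom"):
        raise ValueError("mode must be 'top' or 'bottom'")
    fi = np.asarray(fi, dtype=float)
    ids = np.asarray(cell_ids, dtype=object)
    ok = ~np.isnan(fi)
    fi, ids = fi[ok], ids[ok]
    if fi.size == 0:
        return []
    k = ceil(fraction * fi.size)
    key = sorted(range(fi.size), key=lambda i: ((-fi[i] if mode == "top" else fi[i]), ids[i]))
    return [str(ids[i]) for i in key[:k]]
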
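"""Trace conditioning: zero-phase lowpass, rolling baseline, σ-thresholding,
and movement-epoch detection.

The thresholding convention differs by source. Filtered ΔF/F is *subtracted*
(supra = amount above baseline + k·σ) because it feeds an area-under-the-curve
activity measure; deconvolved event amplitudes are *gated* (values at or below
k·σ set to zero, values above kept at full amplitude) because an event's
amplitude is already a point estimate of transient size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import PositionTrack, ValidationError

__all__ = [
    "ThresholdedTraces",
    "MovementMask",
    "lowpass_filter",
    "rolling_baseline",
    "threshold_traces",
    "threshold_events",
    "movement_epochs",
]


@dataclass(frozen=True)
class ThresholdedTraces:
    """Suprathreshold activity per cell and frame.

    ``supra`` is nonnegative: for ``source == "filtered_dff"`` it is the
    amount by which the filtered trace exceeds ``baseline + k*sigma`` (0
    elsewhere); for ``source == "events"`` it is the event amplitude where
    that amplitude exceeds ``k*sigma`` and 0 elsewhere.
    """

    supra: np.ndarray  # (cells, frames), >= 0
    baseline: np.ndarray  # (cells, frames)
    sigma: np.ndarray  # (cells,) noise scale, a.u.
    source: str  # "filtered_dff" | "events"
    degenerate: np.ndarray  # (cells,) bool: constant/empty trace, supra forced 0


@dataclass(frozen=True)
class MovementMask:
    """Frames belonging to movement epochs (runs of running > min duration)."""

    moving: np.ndarray  # (frames,) bool
    epochs: tuple[tuple[int, int], ...]  # half-open [start, end) frame intervals


def lowpass_filter(
    trace: np.ndarray, frame_rate: float, cutoff: float, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth lowpass.

    Accepts a 1-D trace or a (cells, frames) matrix filtered along the last
    axis. DC gain is exactly 1 and the forward-backward pass cancels phase
    lag; the effective magnitude response is the square of the single-pass
    Butterworth response.
    """
    trace = np.asarray(trace, dtype=float)
    nyquist = frame_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz; got {cutoff}")
    if trace.shape[-1] <= 3 * (order + 1):
        raise ValueError(
            f"trace too short for zero-phase order-{order} filter: "
            f"need > {3 * (order + 1)} frames, got {trace.shape[-1]}"
        )
    b, a = signal.butter(order, cutoff / nyquist, btype="low")
    # pad well past the filter's transient so the forward-backward pass is
    # symmetric under time reversal to machine precision
    padlen = min(
        trace.shape[-1] - 1,
        max(3 * (order + 1), int(round(15.0 * frame_rate / cutoff))),
    )
    return signal.filtfilt(b, a, trace, axis=-1, padlen=padlen)


def rolling_baseline(trace: np.ndarray, frame_rate: float, window: float) -> np.ndarray:
    """Centred rolling-mean baseline with edge truncation.

    The window is ``w = round(window * frame_rate)`` frames, centred on each
    frame as ``[i - (w-1)//2, i + w//2]`` inclusive and truncated to the
    available samples at the edges (no padding values are invented). Works on
    a 1-D trace or a (cells, frames) matrix along the last axis.
    """
    if window <= 0:
        raise ValueError("baseline window must be > 0 s")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    w = max(1, int(round(window * frame_rate)))
    left = (w - 1) // 2
    right = w // 2
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    cs = np.concatenate(
        [np.zeros(trace.shape[:-1] + (1,)), np.cumsum(trace, axis=-1)], axis=-1
    )
    sums = cs[..., hi + 1] - cs[..., lo]
    return sums / (hi - lo + 1)


def _sigma(resid: np.ndarray, robust: bool) -> np.ndarray:
    if robust:
        med = np.median(resid, axis=-1, keepdims=True)
        return 1.4826 * np.median(np.abs(resid - med), axis=-1)
    return resid.std(axis=-1)


def threshold_traces(
    filtered: np.ndarray,
    frame_rate: float,
    window: float = 30.0,
    k: float = 2.0,
    robust: bool = False,
) -> ThresholdedTraces:
    """Threshold filtered ΔF/F to ``k·σ`` above a rolling-mean baseline.

    Per cell: ``baseline`` is the centred rolling mean; ``σ`` is the standard
    deviation of the residual (filtered − baseline) over the whole recording
    (or 1.4826×MAD when ``robust``); ``supra = max(0, filtered − baseline −
    k·σ)``. Cells with a constant trace have σ = 0 and are flagged degenerate
    with ``supra ≡ 0`` rather than raising.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    baseline = rolling_baseline(filtered, frame_rate, window)
    resid = filtered - baseline
    sigma = _sigma(resid, robust)
    degenerate = sigma <= 0
    supra = np.maximum(0.0, resid - k * sigma[:, None])
    supra[degenerate] = 0.0
    return ThresholdedTraces(supra, baseline, sigma, "filtered_dff", degenerate)


def threshold_events(events: np.ndarray, k: float = 2.0) -> ThresholdedTraces:
    """Gate deconvolved event amplitudes at ``k·σ`` above a zero baseline.

    Deconvolved amplitudes are nonnegative with baseline 0, so σ per cell is
    the root-mean-square of the event row about 0 over the whole trace.
    Amplitudes at or below ``k·σ`` are set to zero; amplitudes above are kept
    at full value (gated, not subtracted). All-zero rows are degenerate.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    events = np.atleast_2d(np.asarray(events, dtype=float))
    if np.any(events < 0):
        raise ValidationError("event amplitudes must be nonnegative")
    sigma = np.sqrt(np.mean(events**2, axis=-1))
    degenerate = sigma <= 0
    supra = np.where(events > k * sigma[:, None], events, 0.0)
    supra[degenerate] = 0.0
    return ThresholdedTraces(
        supra, np.zeros_like(events), sigma, "events", degenerate
    )


def movement_epochs(
    track: PositionTrack, speed_threshold: float = 1.0, min_duration: float = 1.0
) -> MovementMask:
    """Find movement epochs: runs of speed > threshold lasting > min_duration.

    A frame is candidate-moving when its speed strictly exceeds
    ``speed_threshold`` (cm/s). Maximal runs of candidate frames whose total
    duration (sum of per-frame durations) strictly exceeds ``min_duration``
    seconds become epochs; all other frames are non-moving.
    """
    if min_duration <= 0:
        raise ValueError("min_duration must be > 0 s")
    cand = track.speed > speed_threshold
    dt = track.frame_dt()
    n = cand.size
    moving = np.zeros(n, dtype=bool)
    epochs: list[tuple[int, int]] = []
    # run-length scan over candidate frames
    edges = np.flatnonzero(np.diff(cand.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [n]])
    for s, e in zip(starts, ends):
        if not cand[s]:
            continue
        if dt[s:e].sum() > min_duration:
            epochs.append((int(s), int(e)))
            moving[s:e] = True
    return MovementMask(moving, tuple(epochs))
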
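"""Distance-normalized single-cell calcium activity.

The activity of a cell is the area under its thresholded, suprathreshold
trace (a.u.·s) divided by the total distance the mouse ran in the session
(metres). Activity is computed over the whole recording — only the spatial
tuning analyses are restricted to movement epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import ThresholdedTraces

__all__ = ["ActivityResult", "single_cell_activity"]


@dataclass(frozen=True)
class ActivityResult:
    """Per-cell distance-normalized activity.

    ``activity`` is NaN for every cell when ``total_distance`` is 0 (the
    normalization is undefined; such sessions are excluded downstream).
    """

    activity: np.ndarray  # (cells,) a.u.·s / m
    total_distance: float  # m
    is_active: np.ndarray  # (cells,) bool: >= 1 suprathreshold frame


def single_cell_activity(
    thresholded: ThresholdedTraces,
    time: np.ndarray,
    total_distance_m: float,
    time_weighted: bool = True,
) -> ActivityResult:
    """Cumulative suprathreshold activity normalized to distance run.

    Per cell, ``A = (Σ_t supra[t]·Δt[t]) / D`` with Δt taken from the time
    vector (last frame repeats the previous interval) and D the total
    distance in metres. With ``time_weighted=False`` the raw frame sum
    ``Σ_t supra[t] / D`` is used instead (the two differ by the frame
    interval; with a single shared frame rate the choice only rescales).
    """
    supra = thresholded.supra
    is_active = (supra > 0).any(axis=-1)
    if time_weighted:
        time = np.asarray(time, dtype=float)
        if time.size < 2:
            dt = np.zeros(time.size)
        else:
            dt = np.diff(time)
            dt = np.concatenate([dt, dt[-1:]])
        auc = supra @ dt
    else:
        auc = supra.sum(axis=-1)
    if total_distance_m <= 0:
        activity = np.full(supra.shape[0], np.nan)
    else:
        activity = auc / total_distance_m
    return ActivityResult(activity, float(total_distance_m), is_active)
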
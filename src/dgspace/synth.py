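"""Ground-truthed synthetic treadmill sessions.

The generator emulates the structure the analysis assumes: 10-minute
sessions at 15.253 frames/s on a 180 cm circular belt with four texture
zones, sparse position-tuned cells with calcium-indicator dynamics, mice
nested within two conditions ("young"/"aged"), four imaging days, and
partial cell reactivation across days.

Generative model per cell: an inhomogeneous Poisson event process whose
rate follows a von Mises bump on the belt,

    rate(t) = r_base + (r_field − r_base) · exp(κ·(cos(θ(t) − θ_pref) − 1)),

(peak-normalized so the rate at the preferred position is r_field; κ = 0
gives a flat, untuned rate). Event amplitudes are gamma-distributed and
scaled by condition gain × per-mouse gain (a lognormal random effect).
ΔF/F is the event train convolved with a two-exponential indicator kernel
plus white Gaussian noise; the events matrix carries the true binned
amplitudes (ideal deconvolution), so tuning-path tests are not confounded
by an inference step.

Condition knobs: the "aged" condition has a transient-amplitude gain > 1
(hyperactivity) and a per-day κ schedule that starts below the young value
and rises to parity (tuning that is initially degraded and recovers with
familiarity). Cells persist across days with probability
``reactivation_prob``; persistent cells keep their preferred position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .session import PositionTrack, Session, SessionMeta, TraceSet, write_session

__all__ = [
    "SynthParams",
    "Cohort",
    "young_defaults",
    "aged_defaults",
    "generate_track",
    "generate_cell_traces",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters for one condition (group).

    Defaults reflect the study design this generator emulates: 8 mice per
    group, ~114 cells per young mouse, 600 s sessions at 15.253 fps, a
    180 cm belt with four texture zones, and a 20% cross-day reactivation
    probability. ``kappa_by_day`` gives the place-cell von Mises
    concentration per imaging day.
    """

    group_label: str = "young"
    n_mice: int = 8
    cells_per_mouse: int = 114
    place_cell_fraction: float = 0.5
    kappa_by_day: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0)
    gain: float = 1.0  # condition-level transient amplitude multiplier
    mouse_gain_sd: float = 0.1  # lognormal sd of the per-mouse gain random effect
    noise_sd: float = 0.05  # ΔF/F additive white noise, a.u.
    event_rate_in_field: float = 0.4  # events/s at the preferred position
    baseline_event_rate: float = 0.02  # events/s far from the field
    amp_shape: float = 2.0  # gamma shape of single-event amplitudes
    amp_scale: float = 0.5  # gamma scale (mean amplitude = shape*scale = 1 a.u.)
    kernel_rise: float = 0.05  # s, indicator rise time constant
    kernel_decay: float = 0.8  # s, indicator decay time constant
    session_length: float = 600.0  # s
    frame_rate: float = 15.253  # Hz
    belt_length: float = 180.0  # cm
    zone_boundaries: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)  # texture zones, cm
    speed_range: tuple[float, float] = (8.0, 25.0)  # cm/s running-bout speeds
    bout_mean_s: float = 8.0  # mean running-bout duration
    pause_prob: float = 0.3  # probability a bout is a pause
    pause_mean_s: float = 2.0  # mean pause duration
    reactivation_prob: float = 0.2

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.frame_rate))


def young_defaults(**overrides) -> SynthParams:
    return replace(SynthParams(), **overrides)


def aged_defaults(**overrides) -> SynthParams:
    base = SynthParams(
        group_label="aged",
        cells_per_mouse=87,
        gain=1.5,
        kappa_by_day=(1.0, 2.0, 3.0, 4.0),
    )
    return replace(base, **overrides)


def generate_track(params: SynthParams, rng: np.random.Generator) -> PositionTrack:
    """Variable-speed forward belt motion with pauses.

    Motion is a sequence of bouts: with probability ``pause_prob`` a bout
    is a pause (exponential duration, speed 0), otherwise a running bout
    with exponential duration and a uniform speed from ``speed_range``.
    Position integrates speed and wraps at ``belt_length``.
    """
    n = params.n_frames
    dt = 1.0 / params.frame_rate
    speed = np.empty(0)
    while speed.size < n:
        if rng.uniform() < params.pause_prob:
            dur = rng.exponential(params.pause_mean_s)
            v = 0.0
        else:
            dur = rng.exponential(params.bout_mean_s)
            v = rng.uniform(*params.speed_range)
        k = max(1, int(round(dur * params.frame_rate)))
        speed = np.concatenate([speed, np.full(k, v)])
    speed = speed[:n]
    unwrapped = np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])
    position = np.mod(unwrapped, params.belt_length)
    time = np.arange(n) * dt
    return PositionTrack.from_position(position, time, params.belt_length)


def _kernel(params: SynthParams) -> np.ndarray:
    dt = 1.0 / params.frame_rate
    t = np.arange(0.0, 6.0 * params.kernel_decay, dt)
    k = (1.0 - np.exp(-t / params.kernel_rise)) * np.exp(-t / params.kernel_decay)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_cell_traces(
    track: PositionTrack,
    truth: pd.DataFrame,
    params: SynthParams,
    rng: np.random.Generator,
    gain_multipliers: np.ndarray | None = None,
) -> TraceSet:
    """Simulate ΔF/F and ideal-deconvolution event traces for a set of cells.

    ``truth`` needs columns ``cell_id, preferred_cm, kappa`` (one row per
    cell); ``gain_multipliers`` is the per-cell total gain (condition ×
    mouse), default 1. Event counts per frame are Poisson with the von
    Mises rate; per-frame amplitude is the sum of that many gamma draws
    (gamma additivity: shape ``amp_shape × count``), times the gain.
    """
    n = track.n_frames
    dt = 1.0 / params.frame_rate
    theta = 2 * np.pi * track.position / params.belt_length
    pref = 2 * np.pi * truth["preferred_cm"].to_numpy(dtype=float) / params.belt_length
    kappa = truth["kappa"].to_numpy(dtype=float)
    n_cells = len(truth)

    bump = np.exp(kappa[:, None] * (np.cos(theta[None, :] - pref[:, None]) - 1.0))
    rate = params.baseline_event_rate + (
        params.event_rate_in_field - params.baseline_event_rate
    ) * bump
    counts = rng.poisson(rate * dt)
    amps = rng.gamma(np.maximum(params.amp_shape * counts, 1e-300), params.amp_scale)
    amps[counts == 0] = 0.0
    if gain_multipliers is not None:
        amps = amps * np.asarray(gain_multipliers, dtype=float)[:, None]

    kern = _kernel(params)
    clean = signal.fftconvolve(amps, kern[None, :], axes=1)[:, :n]
    if params.noise_sd > 0:
        # noise_sd is relative to the unit single-event amplitude: a cell's
        # noise scales with its total gain (indicator expression sets both
        # transient and noise amplitude in ΔF/F), so an amplitude gain is an
        # exact rescaling of the whole trace and spatial-coding metrics that
        # should be amplitude-invariant stay so.
        cell_sd = np.full(n_cells, params.noise_sd)
        if gain_multipliers is not None:
            cell_sd = cell_sd * np.asarray(gain_multipliers, dtype=float)
        dff = clean + cell_sd[:, None] * rng.normal(0.0, 1.0, size=(n_cells, n))
    else:
        dff = clean
    return TraceSet(
        dff=dff, cell_ids=tuple(truth["cell_id"].astype(str)), events=amps
    )


@dataclass(frozen=True)
class Cohort:
    """A full synthetic experiment: sessions, ground truth, match table."""

    sessions: dict[tuple[str, str, int], Session]  # (group, mouse, day) -> Session
    ground_truth: pd.DataFrame  # one row per (mouse, ground-truth cell)
    match_table: pd.DataFrame  # multiday MATCH_COLUMNS format
    mouse_gains: pd.DataFrame  # per-mouse gain random effects


def generate_cohort(
    params_young: SynthParams,
    params_aged: SynthParams,
    n_days: int = 4,
    seed: int = 0,
) -> Cohort:
    """Generate a two-group, multi-day cohort with ground truth.

    Per group × mouse × day one Session is produced. Each mouse's day-1
    cells persist across all later days with probability
    ``reactivation_prob`` (keeping their preferred position; κ follows the
    group's per-day schedule); non-persistent day-1 cells are replaced by
    fresh cells on later days so the per-session cell count stays constant.
    The emitted match table records ground-truth cross-day identity. Fully
    deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    sessions: dict[tuple[str, str, int], Session] = {}
    truth_rows: list[dict] = []
    match_rows: list[dict] = []
    gain_rows: list[dict] = []

    for params in (params_young, params_aged):
        group = params.group_label
        for mi in range(params.n_mice):
            mouse = f"{group}_m{mi + 1:02d}"
            mouse_gain = float(rng.lognormal(0.0, params.mouse_gain_sd))
            gain_rows.append(
                {"group": group, "mouse_id": mouse, "mouse_gain": mouse_gain}
            )
            C = params.cells_per_mouse
            # ground-truth cell universe for this mouse: day-1 cells plus the
            # fresh cells that replace non-persistent ones on each later day
            is_place = rng.uniform(size=C) < params.place_cell_fraction
            preferred = rng.uniform(0.0, params.belt_length, size=C)
            persists = rng.uniform(size=C) < params.reactivation_prob
            day1_ids = [f"{mouse}_d1_c{j:03d}" for j in range(C)]
            for j in range(C):
                truth_rows.append(
                    {
                        "group": group,
                        "mouse_id": mouse,
                        "cell_id_day1": day1_ids[j],
                        "preferred_cm": preferred[j],
                        "is_place_cell": bool(is_place[j]),
                        "persists_across_days": bool(persists[j]),
                        "gain": params.gain * mouse_gain,
                    }
                )

            for day in range(1, n_days + 1):
                kappa_day = params.kappa_by_day[
                    min(day - 1, len(params.kappa_by_day) - 1)
                ]
                if day == 1:
                    ids = day1_ids
                    pref_day = preferred
                    place_day = is_place
                else:
                    keep = np.flatnonzero(persists)
                    n_new = C - keep.size
                    ids = [f"{mouse}_d{day}_c{j:03d}" for j in range(C)]
                    pref_new = rng.uniform(0.0, params.belt_length, size=n_new)
                    place_new = rng.uniform(size=n_new) < params.place_cell_fraction
                    pref_day = np.concatenate([preferred[keep], pref_new])
                    place_day = np.concatenate([is_place[keep], place_new])
                    for slot, j in enumerate(keep):
                        match_rows.append(
                            {
                                "mouse_id": mouse,
                                "day": day,
                                "cell_id_day1": day1_ids[j],
                                "cell_id": ids[slot],
                            }
                        )
                    for j in np.flatnonzero(~persists):
                        match_rows.append(
                            {
                                "mouse_id": mouse,
                                "day": day,
                                "cell_id_day1": day1_ids[j],
                                "cell_id": None,
                            }
                        )
                truth_day = pd.DataFrame(
                    {
                        "cell_id": ids,
                        "preferred_cm": pref_day,
                        "kappa": np.where(place_day, kappa_day, 0.0),
                    }
                )
                track = generate_track(params, rng)
                traces = generate_cell_traces(
                    track,
                    truth_day,
                    params,
                    rng,
                    gain_multipliers=np.full(C, params.gain * mouse_gain),
                )
                meta = SessionMeta(
                    mouse_id=mouse,
                    group=group,
                    day=day,
                    frame_rate=params.frame_rate,
                    belt_length=params.belt_length,
                    n_frames=track.n_frames,
                    n_cells=C,
                )
                session = Session(meta=meta, track=track, traces=traces)
                session.validate()
                sessions[(group, mouse, day)] = session

    match = pd.DataFrame(
        match_rows, columns=["mouse_id", "day", "cell_id_day1", "cell_id"]
    )
    return Cohort(
        sessions=sessions,
        ground_truth=pd.DataFrame(truth_rows),
        match_table=match,
        mouse_gains=pd.DataFrame(gain_rows),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Write every session bundle plus ground-truth and match tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for (group, mouse, day), session in cohort.sessions.items():
        prefix = out / f"{mouse}_day{day}"
        write_session(session, prefix)
        written.append(prefix)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    cohort.match_table.to_csv(out / "match_table.csv", index=False)
    cohort.mouse_gains.to_csv(out / "mouse_gains.csv", index=False)
    return written
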
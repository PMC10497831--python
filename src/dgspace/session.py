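"""Session container, interchange format, and kinematics.

A *session* is one mouse-day recording on a circular treadmill belt: a
cell-by-frame ΔF/F trace matrix, an optional parallel matrix of deconvolved
event amplitudes, and a per-frame belt position track, plus metadata.

On disk a session is a plain-text bundle so that fixtures stay diff-able:

``<name>.traces.csv``
    header ``time_s,position_cm,<cell_id>,...``; one row per frame.
``<name>.events.csv``
    optional, same header and shape, nonnegative deconvolved amplitudes.
``<name>.meta.yaml``
    keys ``mouse_id, group, day, frame_rate_hz, belt_length_cm``.

Positions are 0-based centimetres in the half-open interval
``[0, belt_length)``; the belt is circular and assumed to advance forward
only, so a drop in raw position is a wrap (lap boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "SessionMeta",
    "PositionTrack",
    "TraceSet",
    "Session",
    "AnalysisConfig",
    "derive_kinematics",
    "read_session",
    "write_session",
]

# float formatting used for all trace tables: round-trips float64 exactly
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A session bundle on disk is malformed or incomplete."""


class ValidationError(ValueError):
    """In-memory session data violate a structural invariant."""


@dataclass(frozen=True)
class SessionMeta:
    """Recording metadata for one mouse-day session."""

    mouse_id: str
    group: str
    day: int
    frame_rate: float  # Hz
    belt_length: float  # cm
    n_frames: int
    n_cells: int

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if self.belt_length <= 0:
            raise ValidationError("belt_length must be > 0")
        if self.n_frames <= 0:
            raise ValidationError("n_frames must be > 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.day < 1:
            raise ValidationError("day must be >= 1")


def derive_kinematics(
    position: np.ndarray, time: np.ndarray, belt_length: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-frame speed, lap index, and total distance from a belt position trace.

    The belt is circular and advances forward only: the displacement between
    consecutive frames is the minimal *forward* displacement
    ``(pos[t] - pos[t-1]) mod belt_length``, so a raw decrease in position is
    a wrap through the lap boundary and counts as forward motion.

    Parameters
    ----------
    position : array, cm, values in ``[0, belt_length)``
    time : array, seconds, strictly increasing
    belt_length : belt circumference in cm

    Returns
    -------
    speed : array, cm/s, same length as ``position``; ``speed[0]`` copies
        ``speed[1]`` (no displacement is defined before the first frame)
    lap_index : int array, 0-based, increments by 1 at each wrap
    total_distance : float, cm, sum of per-step forward displacements
    """
    position = np.asarray(position, dtype=float)
    time = np.asarray(time, dtype=float)
    if position.shape != time.shape or position.ndim != 1:
        raise ValidationError("position and time must be 1-D arrays of equal length")
    n = position.size
    if n == 0:
        raise ValidationError("empty position trace")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValidationError("time must be strictly increasing")
    if n == 1:
        return np.zeros(1), np.zeros(1, dtype=int), 0.0
    raw = np.diff(position)
    disp = np.mod(raw, belt_length)
    wraps = raw < 0
    lap_index = np.concatenate([[0], np.cumsum(wraps)]).astype(int)
    step_speed = disp / dt
    speed = np.concatenate([[step_speed[0]], step_speed])
    return speed, lap_index, float(disp.sum())


@dataclass(frozen=True)
class PositionTrack:
    """Per-frame treadmill kinematics.

    ``speed`` and ``lap_index`` are derived from ``position``/``time`` by
    :func:`derive_kinematics`; use :meth:`from_position` to build a
    consistent track.
    """

    position: np.ndarray  # cm, [0, belt_length)
    time: np.ndarray  # s, strictly increasing
    speed: np.ndarray  # cm/s
    lap_index: np.ndarray  # nondecreasing ints
    total_distance: float  # cm

    @classmethod
    def from_position(
        cls, position: Sequence[float], time: Sequence[float], belt_length: float
    ) -> "PositionTrack":
        position = np.asarray(position, dtype=float)
        time = np.asarray(time, dtype=float)
        if position.size and (position.min() < 0 or position.max() >= belt_length):
            raise ValidationError(
                f"position must lie in [0, {belt_length}); "
                f"got range [{position.min()}, {position.max()}]"
            )
        speed, lap_index, total = derive_kinematics(position, time, belt_length)
        return cls(position, time, speed, lap_index, total)

    @property
    def n_frames(self) -> int:
        return self.position.size

    def frame_dt(self) -> np.ndarray:
        """Per-frame duration in s (forward difference; last frame repeats)."""
        if self.time.size < 2:
            return np.zeros(self.time.size)
        dt = np.diff(self.time)
        return np.concatenate([dt, dt[-1:]])


@dataclass(frozen=True)
class TraceSet:
    """Cell-by-frame fluorescence traces for one session."""

    dff: np.ndarray  # (n_cells, n_frames), ΔF/F a.u.
    cell_ids: tuple[str, ...]
    events: Optional[np.ndarray] = None  # same shape, nonnegative a.u.

    def validate(self, n_frames: int | None = None) -> None:
        if self.dff.ndim != 2:
            raise ValidationError("dff must be 2-D (cells x frames)")
        n_cells = self.dff.shape[0]
        if len(self.cell_ids) != n_cells:
            raise ValidationError("cell_ids length must match dff rows")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell_ids must be unique within a session")
        if n_frames is not None and self.dff.shape[1] != n_frames:
            raise ValidationError("dff frame count does not match track/meta")
        if self.events is not None:
            if self.events.shape != self.dff.shape:
                raise ValidationError("events shape must match dff")
            if np.any(self.events < 0):
                raise ValidationError("events must be nonnegative")


@dataclass(frozen=True)
class Session:
    """One mouse-day recording: metadata, kinematics, traces."""

    meta: SessionMeta
    track: PositionTrack
    traces: TraceSet

    def validate(self) -> None:
        self.meta.validate()
        if self.track.n_frames != self.meta.n_frames:
            raise ValidationError("track length does not match meta.n_frames")
        if self.traces.dff.shape[0] != self.meta.n_cells:
            raise ValidationError("trace cell count does not match meta.n_cells")
        self.traces.validate(n_frames=self.meta.n_frames)
        if self.track.position.size and (
            self.track.position.min() < 0
            or self.track.position.max() >= self.meta.belt_length
        ):
            raise ValidationError("position outside [0, belt_length)")


@dataclass
class AnalysisConfig:
    """All fixed analysis parameters, with the study's defaults.

    Parameters
    ----------
    lowpass_cutoff : Hz, Butterworth lowpass corner for ΔF/F filtering.
    butterworth_order : filter order (zero-phase forward-backward pass).
    baseline_window : s, centred rolling-mean baseline window.
    threshold_k : σ multiplier for transient thresholding.
    speed_threshold : cm/s, minimum running speed for movement frames.
    min_move_duration : s, movement runs must be strictly longer than this.
    n_tuning_bins : belt bins for the tuning vector (100).
    n_fi_bins : belt bins for Fisher information (20).
    bootstrap_B : bootstrap iterations for the nested group test.
    alpha : significance level.
    rng_seed : seed for all stochastic stages.
    robust_sigma : use 1.4826*MAD instead of the residual SD for σ.
    time_weighted_activity : weight the thresholded-trace sum by frame
        duration (area under the curve) rather than a raw frame sum.
    fi_pairs : ``"adjacent"`` (circularly adjacent bins) or ``"all"``.
    top_fi_mode : ``"top"`` or ``"bottom"`` decile for raster cell selection.
    bootstrap_statistic : ``"mouse_mean"`` (mean of per-mouse means) or
        ``"pooled"`` (grand mean over cells).
    """

    lowpass_cutoff: float = 2.0
    butterworth_order: int = 3
    baseline_window: float = 30.0
    threshold_k: float = 2.0
    speed_threshold: float = 1.0
    min_move_duration: float = 1.0
    n_tuning_bins: int = 100
    n_fi_bins: int = 20
    bootstrap_B: int = 100_000
    alpha: float = 0.05
    rng_seed: int = 0
    robust_sigma: bool = False
    time_weighted_activity: bool = True
    fi_pairs: str = "adjacent"
    top_fi_mode: str = "top"
    bootstrap_statistic: str = "mouse_mean"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _bundle_paths(path: str | Path) -> tuple[Path, Path, Path]:
    prefix = Path(path)
    base = prefix.parent / prefix.name
    return (
        Path(f"{base}.traces.csv"),
        Path(f"{base}.events.csv"),
        Path(f"{base}.meta.yaml"),
    )


def read_session(path: str | Path) -> Session:
    """Read and validate a session bundle.

    ``path`` is the bundle prefix: ``read_session("dir/m1_d1")`` reads
    ``dir/m1_d1.traces.csv``, ``dir/m1_d1.meta.yaml`` and, if present,
    ``dir/m1_d1.events.csv``.
    """
    traces_p, events_p, meta_p = _bundle_paths(path)
    if not meta_p.exists():
        raise FormatError(f"missing metadata sidecar {meta_p}")
    if not traces_p.exists():
        raise FormatError(f"missing trace table {traces_p}")
    with open(meta_p) as fh:
        raw_meta = yaml.safe_load(fh)
    try:
        mouse_id = str(raw_meta["mouse_id"])
        group = str(raw_meta["group"])
        day = int(raw_meta["day"])
        frame_rate = float(raw_meta["frame_rate_hz"])
        belt_length = float(raw_meta["belt_length_cm"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed metadata sidecar {meta_p}: {exc}") from exc

    tab = pd.read_csv(traces_p)
    if list(tab.columns[:2]) != ["time_s", "position_cm"]:
        raise FormatError("trace table must start with time_s,position_cm columns")
    cell_ids = tuple(str(c) for c in tab.columns[2:])
    time = tab["time_s"].to_numpy(dtype=float)
    position = tab["position_cm"].to_numpy(dtype=float)
    dff = tab.iloc[:, 2:].to_numpy(dtype=float).T

    events = None
    if events_p.exists():
        etab = pd.read_csv(events_p)
        if len(etab) != len(tab):
            raise FormatError("row-count mismatch between trace and event tables")
        if tuple(str(c) for c in etab.columns[2:]) != cell_ids:
            raise FormatError("event table cell columns do not match trace table")
        events = etab.iloc[:, 2:].to_numpy(dtype=float).T

    meta = SessionMeta(
        mouse_id=mouse_id,
        group=group,
        day=day,
        frame_rate=frame_rate,
        belt_length=belt_length,
        n_frames=len(tab),
        n_cells=len(cell_ids),
    )
    track = PositionTrack.from_position(position, time, belt_length)
    session = Session(meta=meta, track=track, traces=TraceSet(dff, cell_ids, events))
    session.validate()
    return session


def write_session(session: Session, path: str | Path) -> None:
    """Write a session bundle readable by :func:`read_session`.

    Floats are serialized with 17 significant digits so the round trip is
    exact to float64 precision, and two writes of the same session produce
    byte-identical files.
    """
    session.validate()
    traces_p, events_p, meta_p = _bundle_paths(path)
    traces_p.parent.mkdir(parents=True, exist_ok=True)

    meta = session.meta
    with open(meta_p, "w") as fh:
        yaml.safe_dump(
            {
                "mouse_id": meta.mouse_id,
                "group": meta.group,
                "day": meta.day,
                "frame_rate_hz": meta.frame_rate,
                "belt_length_cm": meta.belt_length,
            },
            fh,
            sort_keys=True,
        )

    def _table(matrix: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(matrix.T, columns=list(session.traces.cell_ids))
        df.insert(0, "position_cm", session.track.position)
        df.insert(0, "time_s", session.track.time)
        return df

    _table(session.traces.dff).to_csv(traces_p, index=False, float_format=_FLOAT_FMT)
    if session.traces.events is not None:
        _table(session.traces.events).to_csv(
            events_p, index=False, float_format=_FLOAT_FMT
        )
    elif events_p.exists():
        events_p.unlink()
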
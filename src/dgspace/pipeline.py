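"""End-to-end orchestration: session → per-cell metrics → group statistics.

``run_metrics`` applies the full single-session analysis chain:

1. zero-phase Butterworth lowpass of ΔF/F,
2. rolling-baseline 2σ thresholding of the filtered trace → activity
   (area under the suprathreshold curve / distance run, whole recording),
3. movement-epoch gating,
4. tuning vector and circular tuning index on 100 belt bins (from
   thresholded deconvolved events when available, else the thresholded
   filtered trace),
5. bias-corrected single-cell Fisher information on 20 bins from the
   *unfiltered* ΔF/F, movement frames only.

Cells with undefined tuning or FI are carried with flags, never dropped.
``run_group_comparison`` feeds the pooled per-cell metrics into the nested
bootstrap, one comparison per (metric, day), Bonferroni-corrected across
days.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activity import single_cell_activity
from .bootstrap import BootstrapResult, GroupSample, bonferroni, nested_bootstrap_test
from .fisher import single_cell_fi
from .preprocess import (
    lowpass_filter,
    movement_epochs,
    threshold_events,
    threshold_traces,
)
from .session import AnalysisConfig, Session, read_session
from .tuning import tuning_vector

__all__ = [
    "RunManifest",
    "session_metrics",
    "run_metrics",
    "build_group_samples",
    "run_group_comparison",
]

METRICS = ("activity", "tuning_index", "fi")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run: reruns with an identical
    manifest (same inputs, config, seeds) reproduce identical numbers."""

    config: dict
    inputs: list[dict]  # {"path": ..., "sha256": ...}
    seeds: dict
    version: str
    created_utc: str

    @classmethod
    def create(
        cls, config: AnalysisConfig, input_paths: Iterable[str | Path], seeds: Mapping
    ) -> "RunManifest":
        inputs = []
        for p in sorted(str(p) for p in input_paths):
            digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
            inputs.append({"path": p, "sha256": digest})
        return cls(
            config=asdict(config),
            inputs=inputs,
            seeds=dict(seeds),
            version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def session_metrics(session: Session, config: AnalysisConfig) -> pd.DataFrame:
    """Per-cell metrics table for one session.

    Columns: ``group, mouse_id, day, cell_id, activity, is_active,
    tuning_index, preferred_bin, tuning_defined, tuning_source, fi,
    fi_n_pairs, fi_defined``.
    """
    meta, track, traces = session.meta, session.track, session.traces

    filtered = lowpass_filter(
        traces.dff, meta.frame_rate, config.lowpass_cutoff, config.butterworth_order
    )
    thr_dff = threshold_traces(
        filtered,
        meta.frame_rate,
        config.baseline_window,
        config.threshold_k,
        robust=config.robust_sigma,
    )
    act = single_cell_activity(
        thr_dff,
        track.time,
        track.total_distance / 100.0,  # cm -> m
        time_weighted=config.time_weighted_activity,
    )

    mask = movement_epochs(track, config.speed_threshold, config.min_move_duration)

    if traces.events is not None:
        thr_tuning = threshold_events(traces.events, config.threshold_k)
    else:
        thr_tuning = thr_dff
    tune = tuning_vector(
        thr_tuning, track, mask, config.n_tuning_bins, meta.belt_length
    )
    fish = single_cell_fi(
        traces.dff, track, mask, config.n_fi_bins, meta.belt_length,
        pairs=config.fi_pairs,
    )

    return pd.DataFrame(
        {
            "group": meta.group,
            "mouse_id": meta.mouse_id,
            "day": meta.day,
            "cell_id": list(traces.cell_ids),
            "activity": act.activity,
            "is_active": act.is_active,
            "tuning_index": tune.tuning_index,
            "preferred_bin": tune.preferred_bin,
            "tuning_defined": tune.defined,
            "tuning_source": tune.source,
            "fi": fish.fi,
            "fi_n_pairs": fish.n_usable_pairs,
            "fi_defined": fish.defined,
        }
    )


def run_metrics(
    sessions: Iterable[Session | str | Path], config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Metrics for many sessions (Session objects or bundle prefixes).

    Returns ``(table, failures)`` where failures is a list of
    ``(path, message)`` for sessions that could not be read or analyzed;
    the run continues past per-file errors.
    """
    config = config or AnalysisConfig()
    frames: list[pd.DataFrame] = []
    failures: list[tuple[str, str]] = []
    for item in sessions:
        try:
            session = item if isinstance(item, Session) else read_session(item)
            frames.append(session_metrics(session, config))
        except Exception as exc:  # per-file isolation; reported, not fatal
            failures.append((str(item), str(exc)))
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=[
                "group", "mouse_id", "day", "cell_id", "activity", "is_active",
                "tuning_index", "preferred_bin", "tuning_defined", "tuning_source",
                "fi", "fi_n_pairs", "fi_defined",
            ]
        )
    return table, failures


_DEFINED_FLAG = {"activity": None, "tuning_index": "tuning_defined", "fi": "fi_defined"}


def build_group_samples(
    metrics: pd.DataFrame, metric: str, day: int, groups: Sequence[str]
) -> list[GroupSample]:
    """Per-group nested samples of one metric on one day (defined cells only)."""
    if metric not in _DEFINED_FLAG:
        raise ValueError(f"metric must be one of {sorted(_DEFINED_FLAG)}")
    sub = metrics[metrics["day"] == day]
    flag = _DEFINED_FLAG[metric]
    if flag is not None:
        sub = sub[sub[flag].astype(bool)]
    sub = sub[np.isfinite(sub[metric].astype(float))]
    out = []
    for g in groups:
        gsub = sub[sub["group"] == g]
        if gsub.empty:
            raise ValueError(f"group {g!r} has no defined {metric} values on day {day}")
        per_mouse = {
            str(m): mg[metric].to_numpy(dtype=float)
            for m, mg in gsub.groupby("mouse_id")
        }
        out.append(GroupSample(g, per_mouse))
    return out


def run_group_comparison(
    metrics: pd.DataFrame,
    groups: Sequence[str] = ("young", "aged"),
    metric_names: Sequence[str] = METRICS,
    days: Sequence[int] | None = None,
    config: AnalysisConfig | None = None,
    B: int | None = None,
    seed: int | None = None,
    scheme: str = "cell_pool",
) -> pd.DataFrame:
    """Nested bootstrap comparison per (metric, day), Bonferroni over days.

    For each metric the family of per-day comparisons is corrected with
    m = number of days. Returns one row per comparison with the empirical
    difference (first group − second group), both p conventions, the
    Bonferroni-adjusted two-sided p, and the corrected decision.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are compared")
    config = config or AnalysisConfig()
    B = B if B is not None else config.bootstrap_B
    seed = seed if seed is not None else config.rng_seed
    if metrics.empty:
        raise ValueError("metrics table is empty")
    if days is None:
        days = sorted(int(d) for d in metrics["day"].unique())
    if not days:
        raise ValueError("no days to compare")
    rows = []
    for metric in metric_names:
        per_day: list[BootstrapResult] = []
        for i, day in enumerate(days):
            a, b = build_group_samples(metrics, metric, day, groups)
            sub_seed = seed + 1000 * i + 10 * list(metric_names).index(metric)
            res = nested_bootstrap_test(
                a, b, B=B, alpha=config.alpha, seed=sub_seed,
                scheme=scheme, statistic=config.bootstrap_statistic,
            )
            per_day.append(res)
        adj, decisions = bonferroni(
            [r.p_two_sided for r in per_day], m=len(days), alpha=config.alpha
        )
        for day, res, p_adj, dec in zip(days, per_day, adj, decisions):
            rows.append(
                {
                    "metric": metric,
                    "day": day,
                    "group_a": groups[0],
                    "group_b": groups[1],
                    "empirical_diff": res.empirical_diff,
                    "p_directional": res.p_directional,
                    "p_two_sided": res.p_two_sided,
                    "p_bonferroni": p_adj,
                    "significant_bonferroni": bool(dec),
                    "B": res.B,
                    "seed": res.seed,
                    "scheme": res.scheme,
                    "statistic": res.statistic,
                }
            )
    return pd.DataFrame(rows)
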
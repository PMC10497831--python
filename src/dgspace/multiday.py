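"""Multi-day cell tracking: reactivation rates and reactivated-versus-other
comparisons.

Cross-day cell identity comes from an externally produced match table (ROI
matching is upstream of this package); here a *reactivated* cell is one that
was active on day 1 and, via its match-table row, active again on a later
day. Each later day is evaluated against day 1 independently of the other
days.

Match-table format (delimited text): header
``mouse_id,day,cell_id_day1,cell_id`` with one row per (mouse, day-1 cell,
later day); an empty ``cell_id`` means the cell was not matched or not
active on that day.

Active-flag format: header ``mouse_id,day,cell_id,is_active``, one row per
cell per session; "active" inherits the activity module's definition
(at least one suprathreshold frame).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import GroupSample

__all__ = [
    "load_match_table",
    "save_match_table",
    "validate_match_table",
    "reactivation_rate",
    "reactivated_cells",
    "split_by_reactivation",
    "matched_metric_pairs",
]

MATCH_COLUMNS = ["mouse_id", "day", "cell_id_day1", "cell_id"]


def load_match_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mouse_id": str, "cell_id_day1": str, "cell_id": str})
    validate_match_table(df)
    return df


def save_match_table(match: pd.DataFrame, path: str | Path) -> None:
    validate_match_table(match)
    match.to_csv(path, index=False)


def validate_match_table(match: pd.DataFrame) -> None:
    missing = [c for c in MATCH_COLUMNS if c not in match.columns]
    if missing:
        raise ValueError(f"match table missing columns: {missing}")
    key = match[["mouse_id", "cell_id_day1", "day"]]
    if key.duplicated().any():
        raise ValueError("match table has duplicate (mouse_id, cell_id_day1, day) rows")
    if (match["day"] < 2).any():
        raise ValueError("match table days must be >= 2 (day 1 is the reference)")


def _active_sets(active_flags: pd.DataFrame) -> dict[tuple[str, int], set[str]]:
    """(mouse, day) -> set of active cell ids."""
    act = active_flags[active_flags["is_active"].astype(bool)]
    return {
        (str(m), int(d)): set(g["cell_id"].astype(str))
        for (m, d), g in act.groupby(["mouse_id", "day"])
    }


def reactivation_rate(
    match: pd.DataFrame, active_flags: pd.DataFrame
) -> pd.DataFrame:
    """Per-mouse, per-day reactivation of day-1-active cells.

    For each mouse and day d > 1, rate_percent = 100 × (number of
    day-1-active cells with a match on day d whose matched cell is active
    on day d) / (number of day-1-active cells). Each day is evaluated
    against day 1 independently of the other days. Mice with zero
    day-1-active cells get NaN (flagged undefined).

    Returns columns ``mouse_id, day, n_day1_active, n_reactivated,
    rate_percent``.
    """
    validate_match_table(match)
    active = _active_sets(active_flags)
    days = sorted(int(d) for d in match["day"].unique())
    mice = sorted(str(m) for m in active_flags["mouse_id"].unique())
    rows = []
    for mouse in mice:
        day1_active = active.get((mouse, 1), set())
        for day in days:
            sub = match[
                (match["mouse_id"].astype(str) == mouse) & (match["day"] == day)
            ]
            matched = sub.dropna(subset=["cell_id"])
            later_active = active.get((mouse, day), set())
            n_react = sum(
                1
                for _, r in matched.iterrows()
                if str(r["cell_id_day1"]) in day1_active
                and str(r["cell_id"]) in later_active
            )
            n1 = len(day1_active)
            rows.append(
                {
                    "mouse_id": mouse,
                    "day": day,
                    "n_day1_active": n1,
                    "n_reactivated": n_react,
                    "rate_percent": 100.0 * n_react / n1 if n1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def reactivated_cells(
    match: pd.DataFrame, active_flags: pd.DataFrame, later_day: int = 4
) -> pd.DataFrame:
    """Day-1 cells active on both day 1 and ``later_day`` via the match table.

    Returns columns ``mouse_id, cell_id_day1, cell_id_later``.
    """
    validate_match_table(match)
    active = _active_sets(active_flags)
    sub = match[match["day"] == later_day].dropna(subset=["cell_id"])
    rows = []
    for _, r in sub.iterrows():
        mouse = str(r["mouse_id"])
        if str(r["cell_id_day1"]) in active.get((mouse, 1), set()) and str(
            r["cell_id"]
        ) in active.get((mouse, later_day), set()):
            rows.append(
                {
                    "mouse_id": mouse,
                    "cell_id_day1": str(r["cell_id_day1"]),
                    "cell_id_later": str(r["cell_id"]),
                }
            )
    return pd.DataFrame(rows, columns=["mouse_id", "cell_id_day1", "cell_id_later"])


def split_by_reactivation(
    metrics: pd.DataFrame,
    match: pd.DataFrame,
    active_flags: pd.DataFrame,
    day: int,
    later_day: int = 4,
    value_column: str = "value",
    labels: tuple[str, str] = ("reactivated", "non_reactivated"),
) -> tuple[GroupSample | None, GroupSample | None]:
    """Partition one day's cells into reactivated vs non-reactivated samples.

    ``metrics`` holds that day's defined per-cell values (columns
    ``mouse_id, cell_id`` and ``value_column``). A cell counts as
    reactivated when it was active on day 1 AND on ``later_day`` per the
    match table (the headline day pair is 1 vs 4); ``day`` selects which
    day's metric values are partitioned and must be one of the pair. The
    outputs feed :func:`dgspace.bootstrap.nested_bootstrap_test`; an empty
    partition yields None (rejected later by the test's preconditions).
    """
    if day not in (1, later_day):
        raise ValueError(f"day must be 1 or {later_day}")
    react = reactivated_cells(match, active_flags, later_day)
    col = "cell_id_day1" if day == 1 else "cell_id_later"
    react_ids = {
        (m, c) for m, c in zip(react["mouse_id"], react[col])
    }
    is_react = [
        (str(m), str(c)) in react_ids
        for m, c in zip(metrics["mouse_id"], metrics["cell_id"])
    ]
    is_react = np.asarray(is_react)

    def _sample(sel: np.ndarray, label: str) -> GroupSample | None:
        sub = metrics[sel]
        if sub.empty:
            return None
        per_mouse = {
            str(m): g[value_column].to_numpy(dtype=float)
            for m, g in sub.groupby("mouse_id")
        }
        return GroupSample(label, per_mouse)

    return _sample(is_react, labels[0]), _sample(~is_react, labels[1])


def matched_metric_pairs(
    metrics_day1: pd.DataFrame,
    metrics_later: pd.DataFrame,
    match: pd.DataFrame,
    later_day: int = 4,
    value_column: str = "value",
) -> tuple[pd.DataFrame, int]:
    """Per-cell (day-1 value, later-day value) pairs for matched cells.

    Joins the match table's ``later_day`` rows with both days' metric
    tables. Cells whose value is defined on only one day are excluded and
    counted; returns ``(pairs, n_excluded)`` with pairs columns
    ``mouse_id, cell_id_day1, cell_id_later, value_day1, value_later``.
    """
    validate_match_table(match)
    sub = match[match["day"] == later_day].dropna(subset=["cell_id"]).copy()
    sub["mouse_id"] = sub["mouse_id"].astype(str)

    m1 = metrics_day1.rename(columns={value_column: "value_day1"})[
        ["mouse_id", "cell_id", "value_day1"]
    ].astype({"mouse_id": str, "cell_id": str})
    m2 = metrics_later.rename(columns={value_column: "value_later"})[
        ["mouse_id", "cell_id", "value_later"]
    ].astype({"mouse_id": str, "cell_id": str})

    merged = sub.merge(
        m1, left_on=["mouse_id", "cell_id_day1"], right_on=["mouse_id", "cell_id"],
        how="left", suffixes=("", "_m1"),
    ).drop(columns=["cell_id_m1"], errors="ignore")
    merged = merged.rename(columns={"cell_id": "cell_id_later"})
    merged = merged.merge(
        m2, left_on=["mouse_id", "cell_id_later"], right_on=["mouse_id", "cell_id"],
        how="left",
    ).drop(columns=["cell_id"], errors="ignore")

    ok = merged["value_day1"].notna() & merged["value_later"].notna()
    n_excluded = int((~ok).sum())
    pairs = merged.loc[
        ok, ["mouse_id", "cell_id_day1", "cell_id_later", "value_day1", "value_later"]
    ].reset_index(drop=True)
    return pairs, n_excluded
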
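"""Nested (multi-level) bootstrap test for pooled single-cell metrics.

Cells imaged in the same mouse are not independent observations, so pooled
cell-level comparisons between groups need a resampling scheme that respects
the mouse level. The test here builds a null by resampling, for every mouse
in both groups, that mouse's observed number of cell values with replacement
from the pool of all cells (both groups pooled — the pooling enforces the
null hypothesis of no group difference), recomputing the group statistic for
each surrogate, and comparing the empirical group difference with the B
surrogate differences.

The group statistic defaults to the mean of per-mouse means (equal mouse
weighting, matching the nested framing); a pooled cell mean is available.

Reproducibility contract: all draws come from one ``numpy`` Generator seeded
with ``seed``. Under the ``cell_pool`` scheme the stream is consumed as one
``B × n_m`` block of pool indices per mouse, group *a* mice in insertion
order, then group *b* mice. Under ``hierarchical``, per group (a then b) a
``B × M`` block of mouse-slot identities is drawn first, then per slot a
``B × n_max`` block of pool indices of which the first ``n_m`` are used for
the mouse occupying that slot. A straightforward loop consuming the same
stream reproduces ``null_diffs`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GroupSample",
    "BootstrapResult",
    "group_statistic",
    "nested_bootstrap_test",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupSample:
    """One experimental group: per-mouse lists of per-cell metric values."""

    group_label: str
    per_mouse: Mapping[str, np.ndarray]

    def __post_init__(self):
        cleaned = {}
        for mouse, vals in self.per_mouse.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"mouse {mouse!r} has no values")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"mouse {mouse!r} has non-finite values")
            cleaned[str(mouse)] = arr
        if not cleaned:
            raise ValueError("group must contain at least one mouse")
        object.__setattr__(self, "per_mouse", cleaned)

    @property
    def n_mice(self) -> int:
        return len(self.per_mouse)

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.per_mouse.values()))

    def counts(self) -> np.ndarray:
        return np.array([v.size for v in self.per_mouse.values()])


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of one nested bootstrap comparison.

    ``p_directional`` follows the sign of the empirical difference (the
    convention used for headline p-values); ``significant`` uses the
    two-tailed p at level ``alpha``. Both use add-one smoothing
    ``(count + 1)/(B + 1)`` so p is never 0.
    """

    empirical_diff: float
    null_diffs: np.ndarray
    p_directional: float
    p_two_sided: float
    significant: bool
    B: int
    alpha: float
    seed: int
    scheme: str
    statistic: str


def group_statistic(sample: GroupSample, statistic: str = "mouse_mean") -> float:
    """Group-level summary of nested per-cell values.

    ``"mouse_mean"``: mean over mice of the per-mouse mean (each mouse
    weighted equally regardless of cell count). ``"pooled"``: grand mean
    over all cells.
    """
    if statistic == "mouse_mean":
        return float(np.mean([v.mean() for v in sample.per_mouse.values()]))
    if statistic == "pooled":
        return float(sample.pooled().mean())
    raise ValueError("statistic must be 'mouse_mean' or 'pooled'")


def _surrogate_mouse_means_cell_pool(
    rng: np.random.Generator, pool: np.ndarray, counts: np.ndarray, B: int
) -> np.ndarray:
    """(B, n_mice) surrogate per-mouse means; one index block per mouse."""
    out = np.empty((B, counts.size))
    for m, n_m in enumerate(counts):
        idx = rng.integers(0, pool.size, size=(B, int(n_m)))
        out[:, m] = pool[idx].mean(axis=1)
    return out


def _surrogate_mouse_means_hierarchical(
    rng: np.random.Generator, pool: np.ndarray, counts: np.ndarray, B: int
) -> np.ndarray:
    """(B, n_mice) surrogate slot means with mouse identities resampled."""
    M = counts.size
    n_max = int(counts.max())
    which = rng.integers(0, M, size=(B, M))
    slot_n = counts[which]  # (B, M) cells to draw per slot
    out = np.empty((B, M))
    col = np.arange(n_max)
    for s in range(M):
        idx = rng.integers(0, pool.size, size=(B, n_max))
        vals = pool[idx]
        use = col[None, :] < slot_n[:, s, None]
        out[:, s] = (vals * use).sum(axis=1) / slot_n[:, s]
    return out


def nested_bootstrap_test(
    a: GroupSample,
    b: GroupSample,
    B: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "cell_pool",
    statistic: str = "mouse_mean",
) -> BootstrapResult:
    """Nested bootstrap significance test for the difference a − b.

    For each of B iterations a null surrogate dataset is built by drawing,
    for every mouse in both groups, that mouse's observed cell count with
    replacement from the pool of all cells of both groups; the surrogate
    group statistics' difference forms the null distribution against which
    the empirical difference is compared. ``scheme="hierarchical"``
    additionally resamples mouse identities with replacement within each
    group before drawing cells.

    p_directional = (1 + #{null ≥ d})/(B + 1) for empirical d ≥ 0 (mirrored
    for d < 0); p_two_sided = (1 + #{|null| ≥ |d|})/(B + 1); the
    significance decision is two-tailed at ``alpha``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if statistic not in ("mouse_mean", "pooled"):
        raise ValueError("statistic must be 'mouse_mean' or 'pooled'")
    if scheme not in ("cell_pool", "hierarchical"):
        raise ValueError("scheme must be 'cell_pool' or 'hierarchical'")

    empirical = group_statistic(a, statistic) - group_statistic(b, statistic)
    pool = np.concatenate([a.pooled(), b.pooled()])
    rng = np.random.default_rng(seed)
    surrogate = (
        _surrogate_mouse_means_cell_pool
        if scheme == "cell_pool"
        else _surrogate_mouse_means_hierarchical
    )
    means_a = surrogate(rng, pool, a.counts(), B)
    means_b = surrogate(rng, pool, b.counts(), B)
    if statistic == "mouse_mean":
        stat_a = means_a.mean(axis=1)
        stat_b = means_b.mean(axis=1)
    else:
        wa = a.counts() / a.counts().sum()
        wb = b.counts() / b.counts().sum()
        stat_a = means_a @ wa
        stat_b = means_b @ wb
    null = stat_a - stat_b

    if empirical >= 0:
        p_dir = (1 + int(np.sum(null >= empirical))) / (B + 1)
    else:
        p_dir = (1 + int(np.sum(null <= empirical))) / (B + 1)
    p_two = (1 + int(np.sum(np.abs(null) >= abs(empirical)))) / (B + 1)
    return BootstrapResult(
        empirical_diff=float(empirical),
        null_diffs=null,
        p_directional=p_dir,
        p_two_sided=p_two,
        significant=p_two <= alpha,
        B=B,
        alpha=alpha,
        seed=seed,
        scheme=scheme,
        statistic=statistic,
    )


def bonferroni(
    p_values: Sequence[float], m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction for a family of m comparisons.

    Returns ``(adjusted, decisions)`` with adjusted_i = min(1, m·p_i) and
    decision_i = (p_i ≤ α/m). ``m`` defaults to the number of p-values and
    may exceed it (a family larger than the p-values supplied).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    adjusted = np.minimum(1.0, m * p)
    decisions = p <= alpha / m
    return adjusted, decisions
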
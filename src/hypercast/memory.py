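"""Memory (temporal similarity) statistics of higher-order temporal networks.

Three complementary views of how much a network "remembers" its past:

* **Snapshot Jaccard similarity** ``J_d(Δ)`` — per order ``d``, the Jaccard
  similarity |A ∩ B| / |A ∪ B| between the order-``d`` event sets at steps
  ``t`` and ``t + Δ``, averaged over ``t``.
* **Activity auto-correlation** ``R_ii(Δ)`` — the Pearson correlation of a
  hyperlink's binary activity series with its lag-``Δ`` version, averaged
  over hyperlinks of one order.
* **Cross-correlation with phi-neighbours** ``R_i,phi(Δ)`` — the Pearson
  correlation between a target's activity and the summed activity of its
  phi-neighbours, with the neighbour series leading by ``Δ`` (past neighbour
  activity against current target activity, matching its predictive use).

Zero-variance slices are undefined, not zero: they are excluded from
averages and the contributing sample count is reported alongside each value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AggregatedHypergraph,
    Hyperlink,
    NeighborType,
    TemporalHypergraph,
    enumerate_phi_types,
)

__all__ = [
    "UNDEFINED",
    "jaccard_lag",
    "autocorr_lag",
    "mean_autocorr",
    "crosscorr_phi",
    "mean_crosscorr",
    "MemoryProfile",
    "memory_profile",
]

#: marker for statistics that are undefined on the given input
UNDEFINED = float("nan")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when either slice has zero variance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return UNDEFINED
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def jaccard_lag(H: TemporalHypergraph, d: int, delta: int) -> tuple[float, int]:
    """Mean Jaccard similarity of order-``d`` snapshots a lag ``delta`` apart.

    Time steps where both snapshots are empty (union empty, 0/0) are
    skipped.  Returns ``(value, n_contributing_steps)``; value is NaN when
    every step was skipped.
    """
    if d < 2:
        raise ValueError(f"order must be >= 2, got {d}")
    if not (0 <= delta <= H.horizon - 1):
        raise ValueError(f"delta {delta} outside [0, T-1]")
    total, n = 0.0, 0
    for t in range(1, H.horizon - delta + 1):
        a = H.snapshot_at_order(t, d)
        b = H.snapshot_at_order(t + delta, d)
        union = len(a | b)
        if union == 0:
            continue
        total += len(a & b) / union
        n += 1
    return (total / n if n else UNDEFINED), n


def autocorr_lag(x: Sequence[int] | np.ndarray, delta: int) -> float:
    """Pearson correlation of an activity series with its lag-``delta`` self."""
    x = np.asarray(x, dtype=np.float64)
    T = len(x)
    if not (1 <= delta <= T - 2):
        raise ValueError(f"delta {delta} outside [1, T-2]")
    return _pearson(x[: T - delta], x[delta:])


def mean_autocorr(
    agg: AggregatedHypergraph, d: int, delta: int
) -> tuple[float, int]:
    """Average auto-correlation over all order-``d`` hyperlinks.

    Hyperlinks whose auto-correlation is undefined (constant activity over
    either slice) are excluded; the contributing count is returned.
    """
    values = []
    for h in agg.by_order.get(d, []):
        r = autocorr_lag(agg.activity[h], delta)
        if not math.isnan(r):
            values.append(r)
    if not values:
        return UNDEFINED, 0
    return float(np.mean(values)), len(values)


def crosscorr_phi(
    agg: AggregatedHypergraph,
    target: Hyperlink,
    phi: NeighborType,
    delta: int,
    *,
    lag_direction: str = "neighbor_leads",
) -> float:
    """Pearson correlation between the target activity and the summed
    activity of its phi-neighbours at lag ``delta``.

    With the default ``neighbor_leads`` direction the neighbour sum at ``t``
    is correlated with the target at ``t + delta`` (past neighbours vs
    current target, the direction used for prediction).  Raises when the
    target has no phi-neighbour — callers average only over targets that
    have at least one.
    """
    neighbors = agg.neighbors_of(target, phi)
    if not neighbors:
        raise ValueError(f"target {target} has no phi={phi.label} neighbour")
    s = np.zeros(agg.horizon)
    for h in neighbors:
        s += agg.activity[h]
    x = np.asarray(agg.activity[target], dtype=np.float64)
    T = agg.horizon
    if not (0 <= delta <= T - 2):
        raise ValueError(f"delta {delta} outside [0, T-2]")
    if delta == 0:
        return _pearson(x, s)
    if lag_direction == "neighbor_leads":
        return _pearson(x[delta:], s[: T - delta])
    elif lag_direction == "target_leads":
        return _pearson(x[: T - delta], s[delta:])
    raise ValueError(f"unknown lag_direction {lag_direction!r}")


def mean_crosscorr(
    agg: AggregatedHypergraph, phi: NeighborType, delta: int
) -> tuple[float, int]:
    """Average ``R_i,phi(delta)`` over order-``phi.d`` targets with >= 1
    phi-neighbour and a defined correlation."""
    values = []
    for target in agg.by_order.get(phi.d, []):
        if not agg.neighbors_of(target, phi):
            continue
        r = crosscorr_phi(agg, target, phi, delta)
        if not math.isnan(r):
            values.append(r)
    if not values:
        return UNDEFINED, 0
    return float(np.mean(values)), len(values)


@dataclass
class MemoryProfile:
    """Bundle of memory statistics over a set of lags."""

    lags: list[int]
    jaccard: dict[int, list[float]]
    jaccard_counts: dict[int, list[int]]
    autocorr: dict[int, list[float]]
    autocorr_counts: dict[int, list[int]]
    crosscorr: dict[str, list[float]] = field(default_factory=dict)
    crosscorr_counts: dict[str, list[int]] = field(default_factory=dict)

    def to_table(self) -> str:
        """Tab-separated long-format table of every statistic."""
        rows = ["statistic\torder_or_phi\tdelta\tvalue\tn_samples"]
        for d, vals in self.jaccard.items():
            for lag, v, n in zip(self.lags, vals, self.jaccard_counts[d]):
                rows.append(f"jaccard\t{d}\t{lag}\t{v:.6g}\t{n}")
        for d, vals in self.autocorr.items():
            for lag, v, n in zip(self.lags, vals, self.autocorr_counts[d]):
                rows.append(f"autocorr\t{d}\t{lag}\t{v:.6g}\t{n}")
        for label, vals in self.crosscorr.items():
            for lag, v, n in zip(self.lags, vals, self.crosscorr_counts[label]):
                rows.append(f"crosscorr\t{label}\t{lag}\t{v:.6g}\t{n}")
        return "\n".join(rows) + "\n"


def memory_profile(
    H: TemporalHypergraph,
    *,
    lags: Sequence[int] = range(1, 11),
    orders: Sequence[int] = (2, 3, 4),
    max_order: int = 4,
    include_crosscorr: bool = False,
) -> MemoryProfile:
    """Compute Jaccard, auto- and (optionally) cross-correlation profiles."""
    from .core import aggregate

    agg = aggregate(H)
    lags = list(lags)
    prof = MemoryProfile(
        lags=lags,
        jaccard={}, jaccard_counts={},
        autocorr={}, autocorr_counts={},
    )
    present = [d for d in orders if agg.by_order.get(d)]
    for d in present:
        jvals, jcounts, avals, acounts = [], [], [], []
        for lag in lags:
            jv, jn = jaccard_lag(H, d, lag)
            av, an = mean_autocorr(agg, d, lag)
            jvals.append(jv); jcounts.append(jn)
            avals.append(av); acounts.append(an)
        prof.jaccard[d] = jvals
        prof.jaccard_counts[d] = jcounts
        prof.autocorr[d] = avals
        prof.autocorr_counts[d] = acounts
    if include_crosscorr:
        for d in present:
            for phi in enumerate_phi_types(d, max_order):
                cvals, ccounts = [], []
                for lag in lags:
                    cv, cn = mean_crosscorr(agg, phi, lag)
                    cvals.append(cv); ccounts.append(cn)
                prof.crosscorr[phi.label] = cvals
                prof.crosscorr_counts[phi.label] = ccounts
    return prof
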
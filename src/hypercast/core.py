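"""Canonical temporal-hypergraph data model.

A *hyperlink* is a group of ``d >= 2`` nodes that can jointly interact; its
activation at a discrete time step is an *event* of order ``d``.  A
higher-order temporal network is a sequence of snapshots, each a set of
active hyperlinks over a shared node set.  Equivalently it is the aggregated
hypergraph (the union of all hyperlinks ever active) where each hyperlink
carries a binary activity time series.

Two hyperlinks sharing ``o >= 1`` nodes are *phi-neighbours*, with
``phi = (d, d', o)`` recording the target order, the neighbour order and the
overlap.  The taxonomy splits into the target itself (``d = d' = o``),
sub-hyperlinks (``o = d' < d``), super-hyperlinks (``o = d < d'``) and all
remaining partial overlaps ("other").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import IO, Iterable, Iterator, Mapping

import numpy as np

Node = int | str
Hyperlink = tuple  # canonical: strictly ascending node tuple

__all__ = [
    "Hyperlink",
    "InvalidHyperlinkError",
    "UnknownHyperlinkError",
    "NeighborType",
    "TemporalHypergraph",
    "AggregatedHypergraph",
    "PairwiseTemporalGraph",
    "canonicalize",
    "classify_neighbor",
    "enumerate_phi_types",
    "max_phi_count",
    "decompose_pairwise",
    "aggregate",
    "aggregate_pairwise",
    "read_event_list",
    "write_event_list",
]


class InvalidHyperlinkError(ValueError):
    """Raised when a node collection cannot form a hyperlink."""


class UnknownHyperlinkError(KeyError):
    """Raised when a hyperlink is absent from an aggregated network."""


def canonicalize(nodes: Iterable[Node], *, allow_singleton: bool = False) -> Hyperlink:
    """Return the canonical (strictly ascending, duplicate-free) hyperlink.

    Parameters
    ----------
    nodes
        Collection of node identifiers.  Must contain at least two distinct
        ids (one when ``allow_singleton``, used only for the isolated state
        of the group-change dynamics).
    """
    seq = tuple(sorted(nodes))
    if len(seq) == 0:
        raise InvalidHyperlinkError("empty hyperlink")
    if len(set(seq)) != len(seq):
        raise InvalidHyperlinkError(f"duplicate node ids in {seq!r}")
    if len(seq) < 2 and not allow_singleton:
        raise InvalidHyperlinkError(f"hyperlink needs >= 2 nodes, got {seq!r}")
    return seq


@dataclass(frozen=True)
class NeighborType:
    """Overlap relation phi = (d, d', o) between a target and a neighbour."""

    d: int
    d_prime: int
    o: int

    def __post_init__(self) -> None:
        if not (1 <= self.o <= min(self.d, self.d_prime)):
            raise ValueError(f"invalid overlap in phi={self.label}")

    @property
    def label(self) -> str:
        return f"{self.d}{self.d_prime}{self.o}"

    @property
    def kind(self) -> str:
        """One of ``target``, ``sub``, ``super``, ``other``."""
        if self.d == self.d_prime == self.o:
            return "target"
        if self.d_prime < self.d and self.o == self.d_prime:
            return "sub"
        if self.d_prime > self.d and self.o == self.d:
            return "super"
        return "other"


def classify_neighbor(h: Hyperlink, h2: Hyperlink) -> NeighborType | None:
    """Classify ``h2`` as a phi-neighbour of target ``h``.

    Returns ``None`` when the node sets are disjoint (no relation).
    """
    o = len(set(h) & set(h2))
    if o == 0:
        return None
    return NeighborType(len(h), len(h2), o)


def enumerate_phi_types(d: int, max_order: int) -> list[NeighborType]:
    """All phi = (d, d', o) with ``2 <= d' <= max_order``, ordered by
    (d' ascending, o ascending) so coefficient vectors are reproducible."""
    if d < 2:
        raise ValueError(f"target order must be >= 2, got {d}")
    if d > max_order:
        raise ValueError(f"target order {d} exceeds max_order {max_order}")
    return [
        NeighborType(d, dp, o)
        for dp in range(2, max_order + 1)
        for o in range(1, min(d, dp) + 1)
    ]


def max_phi_count(d: int, d_prime: int, o: int, n_nodes: int) -> int:
    """Number of possible (d, d', o)-neighbours of an order-d target among
    ``n_nodes`` nodes: C(d, o) * C(n_nodes - d, d' - o)."""
    if d_prime - o > n_nodes - d:
        return 0
    return comb(d, o) * comb(n_nodes - d, d_prime - o)


@dataclass
class TemporalHypergraph:
    """Sequence of higher-order snapshots over a horizon ``[1, T]``."""

    node_set: frozenset
    horizon: int
    events_at: dict[int, set]
    step_seconds: float = 20.0

    def __post_init__(self) -> None:
        self.node_set = frozenset(self.node_set)
        for t, events in self.events_at.items():
            if not (1 <= t <= self.horizon):
                raise ValueError(f"time step {t} outside [1, {self.horizon}]")
            for h in events:
                if not self.node_set.issuperset(h):
                    raise ValueError(f"event {h} has nodes outside node_set")

    def snapshot(self, t: int) -> set:
        return self.events_at.get(t, set())

    def snapshot_at_order(self, t: int, d: int) -> set:
        return {h for h in self.snapshot(t) if len(h) == d}

    def all_hyperlinks(self) -> set:
        out: set = set()
        for events in self.events_at.values():
            out |= events
        return out

    def orders(self) -> list[int]:
        return sorted({len(h) for h in self.all_hyperlinks()})

    def event_counts_by_order(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for events in self.events_at.values():
            for h in events:
                counts[len(h)] = counts.get(len(h), 0) + 1
        return dict(sorted(counts.items()))


@dataclass
class PairwiseTemporalGraph:
    """Sequence of pairwise snapshots over ``[1, T]``."""

    node_set: frozenset
    horizon: int
    edges_at: dict[int, set]
    step_seconds: float = 20.0

    def snapshot(self, t: int) -> set:
        return self.edges_at.get(t, set())

    def all_edges(self) -> set:
        out: set = set()
        for edges in self.edges_at.values():
            out |= edges
        return out


class AggregatedHypergraph:
    """Union of all hyperlinks ever active, each with its activity series.

    Provides phi-neighbour lookup against the aggregated hyperlink set
    (the set ``S_i^phi`` of the prediction models, which for the target
    type ``(d, d, d)`` contains the target itself).
    """

    def __init__(self, horizon: int, activity: Mapping[Hyperlink, np.ndarray]):
        self.horizon = horizon
        self.activity: dict[Hyperlink, np.ndarray] = {
            h: np.asarray(x, dtype=np.int8) for h, x in activity.items()
        }
        for h, x in self.activity.items():
            if x.shape != (horizon,):
                raise ValueError(f"activity of {h} has length {x.shape}, T={horizon}")
        self.hyperlinks: list[Hyperlink] = sorted(self.activity, key=lambda h: (len(h), h))
        self.by_order: dict[int, list[Hyperlink]] = {}
        for h in self.hyperlinks:
            self.by_order.setdefault(len(h), []).append(h)
        # node -> hyperlinks containing it, per order (overlap queries)
        self._node_index: dict[int, dict[Node, list[Hyperlink]]] = {}
        for d, links in self.by_order.items():
            idx: dict[Node, list[Hyperlink]] = {}
            for h in links:
                for u in h:
                    idx.setdefault(u, []).append(h)
            self._node_index[d] = idx

    def __contains__(self, h: Hyperlink) -> bool:
        return h in self.activity

    def orders(self) -> list[int]:
        return sorted(self.by_order)

    def neighbors_of(self, target: Hyperlink, phi: NeighborType) -> set:
        """All aggregated hyperlinks of order ``phi.d_prime`` overlapping
        ``target`` in exactly ``phi.o`` nodes.  ``(d, d, d)`` -> {target}."""
        if target not in self.activity:
            raise UnknownHyperlinkError(target)
        if phi.d != len(target):
            raise ValueError(f"phi target order {phi.d} != order of {target}")
        if phi.kind == "target":
            return {target}
        idx = self._node_index.get(phi.d_prime, {})
        tset = set(target)
        candidates: set = set()
        for u in target:
            candidates.update(idx.get(u, ()))
        return {h for h in candidates if len(tset.intersection(h)) == phi.o}

    def neighbor_activity_sum(self, target: Hyperlink, phi: NeighborType) -> np.ndarray:
        """Summed activity series over the phi-neighbour set of ``target``."""
        out = np.zeros(self.horizon, dtype=np.float64)
        for h in self.neighbors_of(target, phi):
            out += self.activity[h]
        return out


def aggregate(H: TemporalHypergraph) -> AggregatedHypergraph:
    """Aggregate a temporal hypergraph into hyperlinks + activity series."""
    activity: dict[Hyperlink, np.ndarray] = {}
    for t, events in H.events_at.items():
        for h in events:
            if h not in activity:
                activity[h] = np.zeros(H.horizon, dtype=np.int8)
            activity[h][t - 1] = 1
    return AggregatedHypergraph(H.horizon, activity)


def aggregate_pairwise(G: PairwiseTemporalGraph) -> AggregatedHypergraph:
    """Aggregate a pairwise temporal graph (edges are order-2 hyperlinks)."""
    activity: dict[Hyperlink, np.ndarray] = {}
    for t, edges in G.edges_at.items():
        for e in edges:
            if e not in activity:
                activity[e] = np.zeros(G.horizon, dtype=np.int8)
            activity[e][t - 1] = 1
    return AggregatedHypergraph(G.horizon, activity)


def decompose_pairwise(H: TemporalHypergraph) -> PairwiseTemporalGraph:
    """View each order-d event as its C(d, 2) pairwise contacts."""
    edges_at: dict[int, set] = {}
    for t, events in H.events_at.items():
        edges = set()
        for h in events:
            edges.update(combinations(h, 2))
        if edges:
            edges_at[t] = edges
    return PairwiseTemporalGraph(
        node_set=H.node_set,
        horizon=H.horizon,
        edges_at=edges_at,
        step_seconds=H.step_seconds,
    )


# ---------------------------------------------------------------------------
# Event-list text format: one event per line, `t<TAB>n1 n2 ... nd`.

def write_event_list(H: TemporalHypergraph, stream: IO[str] | str) -> None:
    """Write events sorted by time then lexicographic node tuple."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_event_list(H, fh)
        return
    for t in sorted(H.events_at):
        for h in sorted(H.events_at[t]):
            stream.write(f"{t}\t{' '.join(str(u) for u in h)}\n")


def _iter_event_lines(stream: IO[str]) -> Iterator[tuple[int, Hyperlink]]:
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: need `t n1 n2 ...`, got {line!r}")
        try:
            t = int(parts[0])
            nodes = [int(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field in {line!r}") from exc
        if t < 1:
            raise ValueError(f"line {lineno}: time step {t} < 1")
        yield t, canonicalize(nodes)


def read_event_list(
    stream: IO[str] | str, *, step_seconds: float = 20.0
) -> TemporalHypergraph:
    """Parse the event-list text format into a :class:`TemporalHypergraph`."""
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_event_list(fh, step_seconds=step_seconds)
    if isinstance(stream, bytes):
        stream = io.StringIO(stream.decode())
    events_at: dict[int, set] = {}
    nodes: set = set()
    horizon = 0
    for t, h in _iter_event_lines(stream):
        events_at.setdefault(t, set()).add(h)
        nodes.update(h)
        horizon = max(horizon, t)
    return TemporalHypergraph(
        node_set=frozenset(nodes),
        horizon=max(horizon, 1),
        events_at=events_at,
        step_seconds=step_seconds,
    )
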
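"""Ingest SocioPatterns-style pairwise contact streams and promote cliques.

Proximity sensors record face-to-face contacts as pairwise records
``t i j`` at a fixed resolution (20 s in the original deployments).  Group
interactions are recovered by *clique promotion*: within each snapshot,
every maximal clique of size ``d`` becomes a single order-``d`` event, and
its sub-cliques are discarded.  A consequence carried through the whole
package is that a hyperlink and its sub-hyperlinks are never active at the
same time step in promoted data.

Preprocessing mirrors common practice for these datasets: restrict to the
largest connected component of the time-aggregated pairwise graph, then
delete long runs of empty snapshots (nights, weekends) and re-index time to
be contiguous.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx

from .core import (
    PairwiseTemporalGraph,
    TemporalHypergraph,
    canonicalize,
)

__all__ = [
    "ContactParseError",
    "PreprocessReport",
    "read_contacts",
    "restrict_to_largest_component",
    "remove_inactivity_gaps",
    "promote_cliques",
    "preprocess_report",
]

#: default inactivity gap: one hour of 20 s steps
DEFAULT_GAP_THRESHOLD = 180


class ContactParseError(ValueError):
    """Malformed contact record (with the offending line number)."""


def _open_maybe_gzip(path: str) -> IO[str]:
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_contacts(
    stream: IO[str] | str,
    *,
    step_seconds: float = 20.0,
    raw_seconds: bool = True,
) -> PairwiseTemporalGraph:
    """Parse whitespace-separated ``t i j [...]`` contact records.

    In ``raw_seconds`` mode the first column holds timestamps in seconds;
    they are divided by ``step_seconds`` and shifted so the earliest contact
    lands at step 1.  Otherwise the first column is taken as a 1-based step
    index already.  Duplicate ``(t, i, j)`` records collapse; extra columns
    (metadata) are ignored.
    """
    if isinstance(stream, str):
        with _open_maybe_gzip(stream) as fh:
            return read_contacts(fh, step_seconds=step_seconds, raw_seconds=raw_seconds)

    records: list[tuple[int, int, int]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ContactParseError(f"line {lineno}: need >= 3 columns, got {line!r}")
        try:
            t_raw, i, j = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ContactParseError(f"line {lineno}: non-numeric field in {line!r}") from exc
        if i == j:
            raise ContactParseError(f"line {lineno}: self-loop contact {i}")
        records.append((t_raw, i, j))

    if not records:
        return PairwiseTemporalGraph(
            node_set=frozenset(), horizon=0, edges_at={}, step_seconds=step_seconds
        )

    if raw_seconds:
        steps = [int(t // step_seconds) for t, _, _ in records]
    else:
        steps = [t for t, _, _ in records]
    shift = min(steps) - 1
    edges_at: dict[int, set] = {}
    nodes: set = set()
    for (t_raw, i, j), step in zip(records, steps):
        t = step - shift
        edges_at.setdefault(t, set()).add(canonicalize((i, j)))
        nodes.update((i, j))
    horizon = max(edges_at)
    return PairwiseTemporalGraph(
        node_set=frozenset(nodes),
        horizon=horizon,
        edges_at=edges_at,
        step_seconds=step_seconds,
    )


def restrict_to_largest_component(G: PairwiseTemporalGraph) -> PairwiseTemporalGraph:
    """Keep only nodes in the largest connected component of the aggregated
    pairwise graph (ties broken by the component holding the smallest id)."""
    agg = nx.Graph()
    agg.add_nodes_from(G.node_set)
    agg.add_edges_from(G.all_edges())
    if agg.number_of_nodes() == 0:
        return G
    components = sorted(
        nx.connected_components(agg), key=lambda c: (-len(c), min(c))
    )
    keep = components[0]
    edges_at = {}
    for t, edges in G.edges_at.items():
        kept = {e for e in edges if e[0] in keep and e[1] in keep}
        if kept:
            edges_at[t] = kept
    return PairwiseTemporalGraph(
        node_set=frozenset(keep),
        horizon=G.horizon,
        edges_at=edges_at,
        step_seconds=G.step_seconds,
    )


def remove_inactivity_gaps(
    G: PairwiseTemporalGraph, gap_threshold: int = DEFAULT_GAP_THRESHOLD
) -> PairwiseTemporalGraph:
    """Delete maximal runs of more than ``gap_threshold`` consecutive empty
    snapshots and re-index time contiguously from 1.

    Shorter empty runs are kept (they are genuine brief lulls, not outliers).
    """
    if gap_threshold < 1:
        raise ValueError("gap_threshold must be >= 1")
    keep: list[int] = []
    run: list[int] = []
    for t in range(1, G.horizon + 1):
        if G.snapshot(t):
            if len(run) <= gap_threshold:
                keep.extend(run)
            run = []
            keep.append(t)
        else:
            run.append(t)
    # trailing empty run: kept only if short (paper trims trailing inactivity)
    if run and len(run) <= gap_threshold:
        keep.extend(run)
    remap = {t: new for new, t in enumerate(keep, start=1)}
    edges_at = {remap[t]: set(G.edges_at[t]) for t in G.edges_at if t in remap}
    return PairwiseTemporalGraph(
        node_set=G.node_set,
        horizon=len(keep),
        edges_at=edges_at,
        step_seconds=G.step_seconds,
    )


def promote_cliques(
    G: PairwiseTemporalGraph, max_order: int | None = None
) -> TemporalHypergraph:
    """Promote each snapshot's maximal cliques to higher-order events.

    Every maximal clique of size ``d`` (all ``C(d,2)`` contacts present)
    becomes one order-``d`` event; sub-cliques are discarded.  Cliques larger
    than ``max_order`` are retained as events of their true order — analysis
    modules exclude them from the phi taxonomy, not the data model.
    """
    events_at: dict[int, set] = {}
    for t, edges in G.edges_at.items():
        if not edges:
            continue
        snap = nx.Graph()
        snap.add_edges_from(edges)
        events = {canonicalize(c) for c in nx.find_cliques(snap)}
        events_at[t] = events
    return TemporalHypergraph(
        node_set=G.node_set,
        horizon=G.horizon,
        events_at=events_at,
        step_seconds=G.step_seconds,
    )


@dataclass
class PreprocessReport:
    """Summary of the ingest pipeline (the per-dataset bookkeeping)."""

    nodes_total: int
    nodes_kept: int
    steps_total: int
    steps_kept: int
    events_per_order: dict[int, int]

    def as_text(self) -> str:
        lines = [
            f"nodes_total\t{self.nodes_total}",
            f"nodes_kept\t{self.nodes_kept}",
            f"steps_total\t{self.steps_total}",
            f"steps_kept\t{self.steps_kept}",
        ]
        for d, n in sorted(self.events_per_order.items()):
            lines.append(f"events_order_{d}\t{n}")
        return "\n".join(lines) + "\n"


def preprocess_report(
    raw: PairwiseTemporalGraph,
    cleaned: PairwiseTemporalGraph,
    H: TemporalHypergraph,
) -> PreprocessReport:
    return PreprocessReport(
        nodes_total=len(raw.node_set),
        nodes_kept=len(cleaned.node_set),
        steps_total=raw.horizon,
        steps_kept=cleaned.horizon,
        events_per_order=H.event_counts_by_order(),
    )
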
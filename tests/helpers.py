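"""Independent brute-force oracles and small generative processes for tests.

Everything here deliberately avoids the package's optimized code paths:
oracles enumerate subsets or loop naively so they can arbitrate.
"""

from __future__ import annotations

from itertools import combinations
from math import exp

import numpy as np

from hypercast.core import TemporalHypergraph, canonicalize


def brute_force_neighbors(hyperlinks, target, d_prime, o):
    """All hyperlinks of order d' overlapping target in exactly o nodes."""
    tset = set(target)
    return {
        h for h in hyperlinks
        if len(h) == d_prime and len(tset & set(h)) == o
    }


def brute_force_max_phi_count(d, d_prime, o, n_nodes):
    """Count (d, d', o)-neighbours of the target (0..d-1) by enumeration."""
    target = set(range(d))
    count = 0
    for nodes in combinations(range(n_nodes), d_prime):
        if len(target & set(nodes)) == o:
            count += 1
    return count


def brute_force_decay(activity_rows, t, L, tau):
    """Naive double loop: sum_k sum_j x_j(k) e^{-tau (t-k)}, 1-based t."""
    total = 0.0
    for k in range(t - L + 1, t + 1):
        for row in activity_rows:
            total += row[k - 1] * exp(-tau * (t - k))
    return total


def brute_force_jaccard(H, d, delta):
    """Direct Eq-by-definition Jaccard average (skipping empty unions)."""
    vals = []
    for t in range(1, H.horizon - delta + 1):
        a = {h for h in H.snapshot(t) if len(h) == d}
        b = {h for h in H.snapshot(t + delta) if len(h) == d}
        if a | b:
            vals.append(len(a & b) / len(a | b))
    return (sum(vals) / len(vals)) if vals else float("nan")


def brute_force_maximal_cliques(edges):
    """All maximal cliques of an edge set by subset enumeration (small N)."""
    nodes = sorted({u for e in edges for u in e})
    eset = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset(p) in eset for p in combinations(sub, 2))

    cliques = []
    for size in range(2, len(nodes) + 1):
        for sub in combinations(nodes, size):
            if is_clique(sub):
                cliques.append(set(sub))
    maximal = [
        c for c in cliques if not any(c < c2 for c2 in cliques)
    ]
    # isolated-in-snapshot nodes cannot occur (edges define the snapshot)
    return {canonicalize(c) for c in maximal}


def random_hypergraph(rng, n_nodes=8, horizon=12, n_links=10, rate=0.4):
    """Uniform random pooled hyperlinks with i.i.d. activity."""
    links = set()
    guard = 0
    while len(links) < n_links and guard < 1000:
        d = int(rng.integers(2, min(4, n_nodes) + 1))
        links.add(canonicalize(rng.choice(n_nodes, size=d, replace=False)))
        guard += 1
    events_at = {}
    for t in range(1, horizon + 1):
        active = {h for h in links if rng.random() < rate}
        if active:
            events_at[t] = active
    return TemporalHypergraph(
        node_set=frozenset(range(n_nodes)), horizon=horizon, events_at=events_at
    )


def paired_reshuffle_network(
    beta, b_d, horizon, seed, k_pairs={2: 8, 3: 6, 4: 5}
):
    """Group dynamics whose observable change hazard follows the model curve.

    Nodes live in permanently paired groups of equal size; each pair
    reshuffles its members atomically with probability
    ``b_d (tau^beta + 1) / N``, so every member's observed group change
    hazard is exactly the model's (all members share the residence time).
    """
    rng = np.random.default_rng(seed)
    pairs = []
    nid = 0
    for d, k in k_pairs.items():
        for _ in range(k):
            pairs.append((d, list(range(nid, nid + 2 * d))))
            nid += 2 * d
    state = [[set(n[:d]), set(n[d:]), 1] for d, n in pairs]
    events_at = {}
    for t in range(1, horizon + 1):
        evs = set()
        for si, (d, nodes) in enumerate(pairs):
            g1, g2, tau = state[si]
            p = b_d[d] * (tau ** beta + 1.0) / nid
            if rng.random() < p:
                while True:
                    sel = set(rng.choice(nodes, size=d, replace=False).tolist())
                    if sel != g1 and sel != g2:
                        break
                state[si] = [sel, set(nodes) - sel, 1]
            else:
                state[si][2] += 1
            evs.add(canonicalize(state[si][0]))
            evs.add(canonicalize(state[si][1]))
        events_at[t] = evs
    return TemporalHypergraph(
        node_set=frozenset(range(nid)), horizon=horizon, events_at=events_at
    )


def static_hypergraph(snapshot, horizon):
    """Same (promotion-consistent) snapshot at every step."""
    events = {canonicalize(h) for h in snapshot}
    nodes = frozenset(u for h in events for u in h)
    return TemporalHypergraph(
        node_set=nodes, horizon=horizon,
        events_at={t: set(events) for t in range(1, horizon + 1)},
    )
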
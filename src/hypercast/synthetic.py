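"""Synthetic temporal hypergraphs with controllable memory structure.

The generators emulate the statistical signatures of face-to-face contact
hypergraphs that the analysis and prediction modules rely on:

* per-hyperlink *time-decaying memory*: each pooled hyperlink follows a
  two-state Markov chain (stay-active probability ``p``, activation
  probability ``q``), whose lag-1 autocorrelation is ``p - q``;
* *cross-order coupling*: a hyperlink's activation odds are boosted by a
  factor ``1 + kappa`` when one of its sub- or super-hyperlinks in the pool
  was active at the previous step;
* the *no-nesting* property of clique-promoted data (optional maximality
  pass removing events nested in a co-occurring event).

Hyperlink pools are fixed aggregated sets — mirroring the prediction
problem's assumption that group friendship (the aggregated network) is
known — and are built top-down so that sub-/super-relations actually occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AggregatedHypergraph,
    Hyperlink,
    TemporalHypergraph,
    canonicalize,
    decompose_pairwise,
)
from .ingest import promote_cliques
from .models import DecayParams, decay_kernel

__all__ = [
    "SynthSpec",
    "build_pool",
    "generate_markov_hypergraph",
    "generate_from_refined_model",
    "generate_clique_contact_stream",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the Markov hypergraph generator.

    Defaults describe a small contact-network-like system: 30 nodes, pools
    of 60/30/10 hyperlinks of orders 2/3/4 (half of each lower-order pool
    nested inside higher-order pool members), strong persistence ``p = 0.9``,
    sparse activation ``q = 0.05``, and moderate cross-order coupling.
    """

    n_nodes: int = 30
    horizon: int = 200
    pool_sizes: Mapping[int, int] = field(default_factory=lambda: {2: 60, 3: 30, 4: 10})
    persistence: float = 0.9
    activation: float = 0.05
    kappa: float = 0.5
    nested_fraction: float = 0.5
    enforce_maximality: bool = False
    step_seconds: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0 and 0.0 <= self.activation <= 1.0):
            raise ValueError("persistence and activation must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_nodes < max(self.pool_sizes, default=2):
            raise ValueError("n_nodes smaller than the largest order")
        if not self.pool_sizes:
            raise ValueError("empty hyperlink pool specification")


def build_pool(spec: SynthSpec, rng: np.random.Generator) -> list[Hyperlink]:
    """Sample the fixed hyperlink pool, top-down so nesting exists.

    Orders are filled from the largest down; a ``nested_fraction`` share of
    each lower order is drawn from sub-hyperlinks of already-pooled larger
    hyperlinks, the rest uniformly from all candidate node subsets.
    """
    nodes = list(range(spec.n_nodes))
    pool: set[Hyperlink] = set()
    by_order: dict[int, set[Hyperlink]] = {}
    for d in sorted(spec.pool_sizes, reverse=True):
        m = spec.pool_sizes[d]
        chosen: set[Hyperlink] = set()
        # nested part: sub-hyperlinks of pooled higher-order links
        supers = [h for dd, hs in by_order.items() if dd > d for h in hs]
        sub_candidates = sorted({
            canonicalize(c) for h in supers for c in combinations(h, d)
        })
        n_nested = min(int(round(spec.nested_fraction * m)), len(sub_candidates))
        if n_nested:
            idx = rng.choice(len(sub_candidates), size=n_nested, replace=False)
            chosen.update(sub_candidates[k] for k in idx)
        # random remainder
        guard = 0
        while len(chosen) < m:
            h = canonicalize(rng.choice(spec.n_nodes, size=d, replace=False))
            chosen.add(h)
            guard += 1
            if guard > 100 * m:
                raise RuntimeError(f"cannot fill order-{d} pool of size {m}")
        by_order[d] = chosen
        pool |= chosen
    return sorted(pool, key=lambda h: (len(h), h))


def _coupling_mates(pool: Sequence[Hyperlink]) -> list[list[int]]:
    """Indices of sub-/super-hyperlinks (strict nesting) per pool member."""
    sets = [set(h) for h in pool]
    mates: list[list[int]] = [[] for _ in pool]
    for i, si in enumerate(sets):
        for j in range(i + 1, len(sets)):
            sj = sets[j]
            if len(si) == len(sj):
                continue
            small, big = (si, sj) if len(si) < len(sj) else (sj, si)
            if small <= big:
                mates[i].append(j)
                mates[j].append(i)
    return mates


def _strip_nested(events: set) -> set:
    """Maximality pass: drop events nested in a co-occurring larger event."""
    keep = set()
    for h in events:
        hs = set(h)
        if not any(h2 != h and hs < set(h2) for h2 in events):
            keep.add(h)
    return keep


def generate_markov_hypergraph(spec: SynthSpec) -> TemporalHypergraph:
    """Evolve every pooled hyperlink as a coupled two-state Markov chain.

    Active links stay active with probability ``p``; inactive links activate
    with probability ``q``, multiplied by ``1 + kappa`` (clipped at 1) when
    any nested pool-mate was active at the previous step.  Initial states are
    drawn from the uncoupled chain's stationary distribution.
    """
    rng = np.random.default_rng(spec.seed)
    pool = build_pool(spec, rng)
    mates = _coupling_mates(pool)
    p, q, kappa = spec.persistence, spec.activation, spec.kappa
    n = len(pool)
    stationary = q / (q + (1.0 - p)) if (q + 1.0 - p) > 0 else 0.0
    x = (rng.random(n) < stationary).astype(np.int8)
    events_at: dict[int, set] = {}
    for t in range(1, spec.horizon + 1):
        if t > 1:
            boosted = np.array([
                any(x_prev[j] for j in mates[i]) for i in range(n)
            ])
            q_eff = np.where(boosted, np.minimum(q * (1.0 + kappa), 1.0), q)
            u = rng.random(n)
            x = np.where(x_prev == 1, (u < p), (u < q_eff)).astype(np.int8)
        active = {pool[i] for i in np.flatnonzero(x)}
        if spec.enforce_maximality:
            active = _strip_nested(active)
        if active:
            events_at[t] = active
        x_prev = x.copy()
        if spec.enforce_maximality:
            # the chain itself keeps its state; only the emitted snapshot is pruned
            pass
    return TemporalHypergraph(
        node_set=frozenset(range(spec.n_nodes)),
        horizon=spec.horizon,
        events_at=events_at,
        step_seconds=spec.step_seconds,
    )


def generate_from_refined_model(
    agg_template: AggregatedHypergraph | Sequence[Hyperlink],
    coeffs: Mapping[str, float],
    params: DecayParams,
    base_rate: float,
    seed: int,
    *,
    horizon: int = 500,
    expected_rate: float = 0.15,
) -> TemporalHypergraph:
    """Generate activity whose conditional activation probability is a fixed
    linear function of the refined-model tendency.

    ``coeffs`` maps neighbour kinds (``"target"``, ``"sub"``, ``"super"``) to
    their true weights.  After a burn-in window of i.i.d. Bernoulli
    (``expected_rate``) activity, each hyperlink activates at step ``t`` with
    probability ``base_rate + s_d * w_i(t)``, where ``w_i(t)`` is the decayed
    refined tendency over ``[t-L, t-1]``.  The per-order scale ``s_d`` is set
    analytically so that the self-consistent activity rate equals
    ``expected_rate``: if every link is active with rate ``r``, the expected
    tendency of an order-``d`` link is ``r * W_d`` with ``W_d`` the mean
    coefficient-weighted neighbour count times the kernel mass, so
    ``s_d = (expected_rate - base_rate) / (expected_rate * W_d)``.  A fixed
    scale keeps the activation probability a linear function of the
    features, which makes coefficient recovery well-posed; ``base_rate``
    also sets the loop damping (the closed-loop gain is
    ``1 - base_rate / expected_rate``), so keep it a substantial fraction of
    ``expected_rate``.
    """
    if isinstance(agg_template, AggregatedHypergraph):
        pool = list(agg_template.hyperlinks)
    else:
        pool = sorted(agg_template, key=lambda h: (len(h), h))
    rng = np.random.default_rng(seed)
    n = len(pool)
    if n == 0:
        raise ValueError("empty template pool")
    L, T = params.L, horizon
    kernel = decay_kernel(params)

    sets = [set(h) for h in pool]
    orders = np.array([len(h) for h in pool])
    kinds = ("target", "sub", "super")
    # membership matrices: M[kind][i, j] = 1 if j in S_i^phi for a phi of that kind
    M = {k: np.zeros((n, n)) for k in kinds}
    M["target"][:] = np.eye(n)
    for i, si in enumerate(sets):
        for j, sj in enumerate(sets):
            if i == j or len(si) == len(sj):
                continue
            if sj < si:
                M["sub"][i, j] = 1.0
            elif si < sj:
                M["super"][i, j] = 1.0

    X = np.zeros((n, T))
    X[:, :L] = (rng.random((n, L)) < expected_rate)
    S = {k: np.zeros((n, T)) for k in kinds}
    for k in kinds:
        S[k][:, :L] = M[k] @ X[:, :L]

    # analytic per-order scale at the expected-rate fixed point
    kernel_mass = float(kernel.sum())
    weighted_degree = sum(
        coeffs.get(k, 0.0) * M[k].sum(axis=1) for k in kinds
    ) * kernel_mass
    scale: dict[int, float] = {}
    for d in np.unique(orders):
        W_d = float(weighted_degree[orders == d].mean())
        if expected_rate > 0 and W_d > 0:
            scale[d] = (expected_rate - base_rate) / (expected_rate * W_d)
        else:
            scale[d] = 0.0

    for t in range(L, T):
        w = np.zeros(n)
        for k in kinds:
            window = S[k][:, t - L : t][:, ::-1]  # most recent column first
            w += coeffs.get(k, 0.0) * (window @ kernel)
        prob = np.full(n, base_rate)
        for d in np.unique(orders):
            mask = orders == d
            prob[mask] += scale[d] * w[mask]
        prob = np.clip(prob, 0.0, 1.0)
        X[:, t] = rng.random(n) < prob
        for k in kinds:
            S[k][:, t] = M[k] @ X[:, t]

    events_at: dict[int, set] = {}
    for t in range(T):
        active = {pool[i] for i in np.flatnonzero(X[:, t])}
        if active:
            events_at[t + 1] = active
    nodes = frozenset(u for h in pool for u in h)
    return TemporalHypergraph(node_set=nodes, horizon=T, events_at=events_at)


def generate_clique_contact_stream(
    spec: SynthSpec,
) -> tuple[list[str], TemporalHypergraph]:
    """Emit a SocioPatterns-dialect contact stream with known planted truth.

    Snapshots come from the Markov generator; each snapshot's planted events
    are the maximal cliques of its own pairwise decomposition (so promotion
    recovers them exactly).  Lines are ``<seconds> <i> <j>`` at the spec's
    step resolution.  Returns ``(lines, planted_truth)`` with the truth
    expressed in the re-indexed time coordinates a reader will produce.
    """
    raw = generate_markov_hypergraph(spec)
    promoted = promote_cliques(decompose_pairwise(raw))
    active_steps = sorted(t for t in promoted.events_at if promoted.events_at[t])
    if not active_steps:
        return [], TemporalHypergraph(
            node_set=raw.node_set, horizon=1, events_at={},
            step_seconds=spec.step_seconds,
        )
    shift = active_steps[0] - 1
    lines: list[str] = []
    events_at: dict[int, set] = {}
    for t in active_steps:
        events = promoted.events_at[t]
        events_at[t - shift] = set(events)
        pairs = sorted({pair for h in events for pair in combinations(h, 2)})
        for i, j in pairs:
            lines.append(f"{int(t * spec.step_seconds)} {i} {j}")
    truth = TemporalHypergraph(
        node_set=frozenset(u for es in events_at.values() for h in es for u in h),
        horizon=max(events_at),
        events_at=events_at,
        step_seconds=spec.step_seconds,
    )
    return lines, truth
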
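"""Non-memory baselines: activity-driven sampling and group-change dynamics.

*Higher-order activity-driven model.*  Each node gets a per-order activity
potential ``a_i^(d)``: the fraction of all order-``d`` events that involve
node ``i``.  Each predicted order-``d`` event is generated by sampling a node
proportionally to its potential and then picking uniformly one of the
aggregated order-``d`` hyperlinks containing that node.

*Group-change model.*  Every node sits in exactly one group (possibly a
singleton, i.e. isolated).  At each step a node in a group of size ``d``
with residence time ``tau`` (consecutive steps spent in that group) changes
group with probability

    p_d(tau) = b_d (tau^beta + 1) / N,

with ``beta < 0`` fitted from the empirical change frequencies and the
per-order amplitudes smoothed by the logistic ``b_d = d0 / (1 + exp(-a(d-1)))``.
A changing node joins a currently active group with probability proportional
to the fraction of its members the node encountered in the recent window, or
becomes isolated (the empty set participates with multiplicity ``epsilon``);
the group it leaves is disbanded.  Non-singleton groups of the resulting
partition are the predicted events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    AggregatedHypergraph,
    Hyperlink,
    TemporalHypergraph,
    canonicalize,
)

__all__ = [
    "ActivityPotentials",
    "activity_potentials",
    "sample_activity_driven",
    "ActivityDrivenModel",
    "GroupChangeParams",
    "GroupState",
    "group_state_from_history",
    "fit_group_change",
    "change_probability",
    "step_group_change",
    "GroupChangeModel",
]


# ---------------------------------------------------------------------------
# Activity-driven baseline

@dataclass
class ActivityPotentials:
    """Per-order node activity potentials ``a_i^(d)``."""

    potentials: dict[int, dict]  # d -> node -> probability

    def for_order(self, d: int) -> dict:
        return self.potentials[d]


def activity_potentials(H: TemporalHypergraph, orders: Sequence[int] = (2, 3, 4)) -> ActivityPotentials:
    """Fraction of order-``d`` events involving each node (sums to ``d``)."""
    totals: dict[int, int] = {d: 0 for d in orders}
    counts: dict[int, dict] = {d: {u: 0 for u in H.node_set} for d in orders}
    for events in H.events_at.values():
        for h in events:
            d = len(h)
            if d in totals:
                totals[d] += 1
                for u in h:
                    counts[d][u] += 1
    out: dict[int, dict] = {}
    for d in orders:
        if totals[d] == 0:
            warnings.warn(f"no order-{d} events; order omitted from potentials")
            continue
        out[d] = {u: counts[d][u] / totals[d] for u in H.node_set}
    return ActivityPotentials(out)


def sample_activity_driven(
    agg: AggregatedHypergraph,
    potentials: ActivityPotentials,
    per_order_counts: Mapping[int, int],
    rng: np.random.Generator,
) -> dict[int, set]:
    """Draw ``n_d`` distinct hyperlinks per order (duplicates redrawn)."""
    out: dict[int, set] = {}
    for d, n in per_order_counts.items():
        candidates = agg.by_order.get(d, [])
        if n > len(candidates):
            warnings.warn(f"order {d}: requested {n} events, only {len(candidates)} candidates")
            n = len(candidates)
        if n == 0 or d not in potentials.potentials:
            out[d] = set()
            continue
        pot = potentials.for_order(d)
        nodes = [u for u in pot if pot[u] > 0]
        weights = np.array([pot[u] for u in nodes])
        weights = weights / weights.sum()
        by_node: dict = {}
        for h in candidates:
            for u in h:
                by_node.setdefault(u, []).append(h)
        chosen: set = set()
        while len(chosen) < n:
            u = nodes[rng.choice(len(nodes), p=weights)]
            pool = by_node.get(u)
            if not pool:
                continue  # node never in an aggregated order-d hyperlink: redraw
            h = pool[rng.integers(len(pool))]
            chosen.add(h)  # duplicate draws are no-ops (redraw)
        out[d] = chosen
    return out


class ActivityDrivenModel:
    """Activity-driven baseline bound to one observed network."""

    def __init__(self, H: TemporalHypergraph, orders: Sequence[int] = (2, 3, 4)):
        from .core import aggregate

        self.H = H
        self.agg = aggregate(H)
        self.potentials = activity_potentials(H, orders)

    def predict(
        self, t: int, per_order_counts: Mapping[int, int], rng: np.random.Generator
    ) -> dict[int, set]:
        return sample_activity_driven(self.agg, self.potentials, per_order_counts, rng)


# ---------------------------------------------------------------------------
# Group-change baseline

@dataclass
class GroupChangeParams:
    """Fitted parameters of the group-change dynamics."""

    beta: float
    b_d: dict[int, float]
    d0: float
    alpha_logistic: float
    epsilon: int = 100
    L: int = 30
    variant: str = "plus_one"  # p = b_d (tau^beta + 1)/N; alt: b_d tau^(beta+1)/N
    diagnostics: dict = field(default_factory=dict)


def change_probability(params: GroupChangeParams, d: int, tau: int, n_nodes: int) -> float:
    """``p_d(tau)``, clipped to [0, 1]; orders beyond the fitted set reuse
    the largest fitted order's amplitude."""
    b = params.b_d.get(d)
    if b is None:
        b = params.b_d[max(params.b_d)]
    if params.variant == "plus_one":
        p = b * (tau ** params.beta + 1.0) / n_nodes
    elif params.variant == "exponent_plus_one":
        p = b * tau ** (params.beta + 1.0) / n_nodes
    else:
        raise ValueError(f"unknown variant {params.variant!r}")
    return float(min(max(p, 0.0), 1.0))


@dataclass
class GroupState:
    """Partition of the node set into groups plus residence counters."""

    groups: dict[int, set]          # group id -> node set (size >= 1)
    membership: dict                # node -> group id
    residence: dict                 # node -> consecutive steps in current group

    def check_partition(self, node_set: frozenset) -> None:
        seen: set = set()
        for gid, members in self.groups.items():
            if not members:
                raise AssertionError(f"empty group {gid}")
            if seen & members:
                raise AssertionError("overlapping groups")
            seen |= members
        if seen != set(node_set):
            raise AssertionError("partition does not cover the node set")
        for u, tau in self.residence.items():
            if tau < 1:
                raise AssertionError(f"residence of {u} < 1")

    def events(self) -> set:
        """Non-singleton groups as canonical hyperlinks."""
        return {canonicalize(g) for g in self.groups.values() if len(g) >= 2}


def _group_assignment(H: TemporalHypergraph, t: int) -> dict:
    """Node -> its group (canonical tuple) at step ``t``.

    Promoted snapshots may place a node in several maximal cliques; the
    node's group is the largest event containing it (ties: lexicographically
    smallest).  Nodes in no event are isolated (singleton group).
    """
    assign: dict = {}
    for h in sorted(H.snapshot(t), key=lambda h: (-len(h), h)):
        for u in h:
            assign.setdefault(u, h)
    for u in H.node_set:
        assign.setdefault(u, (u,))
    return assign


def group_state_from_history(H: TemporalHypergraph, t: int) -> GroupState:
    """Reconstruct the group partition and residence times at step ``t``."""
    assign = _group_assignment(H, t)
    residence: dict = {}
    prev_assign: dict[int, dict] = {t: assign}
    for u in H.node_set:
        tau = 1
        s = t - 1
        while s >= 1:
            if s not in prev_assign:
                prev_assign[s] = _group_assignment(H, s)
            if prev_assign[s].get(u) != assign[u]:
                break
            tau += 1
            s -= 1
        residence[u] = tau
    groups: dict[int, set] = {}
    membership: dict = {}
    gid_of: dict = {}
    next_gid = 0
    for u in sorted(H.node_set):
        g = assign[u]
        if g not in gid_of:
            gid_of[g] = next_gid
            groups[next_gid] = set()
            next_gid += 1
        gid = gid_of[g]
        groups[gid].add(u)
        membership[u] = gid
    return GroupState(groups, membership, residence)


def fit_group_change(
    H: TemporalHypergraph,
    L: int = 30,
    *,
    epsilon: int = 100,
    variant: str = "plus_one",
    max_order: int = 4,
) -> GroupChangeParams:
    """Estimate ``beta``, per-order amplitudes ``b_d`` and the logistic fit.

    The empirical probability that a node changes group, as a function of its
    residence time, is pooled over nodes and steps and fitted by a power law
    on the log-log scale to obtain ``beta``; given ``beta``, each order's
    amplitude ``b_d`` is the weighted least-squares fit of the model curve to
    the per-order frequencies, then smoothed by the logistic in ``d``.
    """
    N = len(H.node_set)
    assigns = {t: _group_assignment(H, t) for t in range(1, H.horizon + 1)}
    # residence at t, change indicator at t -> t+1
    obs: dict[tuple[int, int], list[int]] = {}   # (d, tau) -> change flags
    residence = {u: 1 for u in H.node_set}
    for t in range(1, H.horizon):
        cur, nxt = assigns[t], assigns[t + 1]
        for u in H.node_set:
            d = len(cur[u])
            tau = residence[u]
            changed = int(nxt[u] != cur[u])
            obs.setdefault((min(d, max_order), tau), []).append(changed)
            residence[u] = 1 if changed else tau + 1

    pooled: dict[int, tuple[int, int]] = {}
    for (d, tau), flags in obs.items():
        n, c = pooled.get(tau, (0, 0))
        pooled[tau] = (n + len(flags), c + sum(flags))
    taus = np.array(sorted(tau for tau, (n, c) in pooled.items() if c > 0 and n >= 5))
    if len(taus) < 3:
        raise ValueError("insufficient residence-time spread to fit beta")
    freqs = np.array([pooled[tau][1] / pooled[tau][0] for tau in taus])
    wts = np.array([pooled[tau][0] for tau in taus], dtype=float)
    # weighted fit of the pooled change frequency by the model-form decaying
    # power law itself (amplitude and exponent); inverting the same curve the
    # simulator uses keeps the estimator consistent
    if variant == "plus_one":
        curve = lambda tau, a, beta: a * (tau ** beta + 1.0)
    else:
        curve = lambda tau, a, beta: a * tau ** (beta + 1.0)
    try:
        (a_hat, beta), _ = curve_fit(
            curve, taus.astype(float), freqs,
            p0=[freqs[-1] / 2.0 if freqs[-1] > 0 else freqs.mean(), -0.5],
            sigma=1.0 / np.sqrt(wts),
            bounds=([0.0, -5.0], [np.inf, 0.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError("power-law fit of change frequencies failed") from exc
    beta = float(beta)

    shape = (taus ** beta + 1.0) if variant == "plus_one" else taus ** (beta + 1.0)
    b_raw: dict[int, float] = {}
    for d in sorted({d for d, _ in obs}):
        f_d, w_d, s_d = [], [], []
        for tau, s in zip(taus, shape):
            flags = obs.get((d, tau))
            if flags:
                f_d.append(sum(flags) / len(flags))
                w_d.append(len(flags))
                s_d.append(s)
        if not f_d:
            continue
        f_d, w_d, s_d = map(np.asarray, (f_d, w_d, s_d))
        denom = float(np.sum(w_d * (s_d / N) ** 2))
        if denom == 0:
            continue
        b_raw[d] = float(np.sum(w_d * f_d * (s_d / N)) / denom)

    ds = np.array(sorted(b_raw))
    bs = np.array([b_raw[d] for d in ds])
    logistic = lambda d, d0, a: d0 / (1.0 + np.exp(-a * (d - 1.0)))
    if len(ds) >= 2:
        try:
            (d0, a), _ = curve_fit(
                logistic, ds.astype(float), bs, p0=[max(bs.max(), 1e-6) * 2, 1.0],
                maxfev=10000,
            )
        except RuntimeError:
            d0, a = float(bs.max() * 2), 1.0
    else:
        d0, a = float(bs[0] * 2), 1.0
    b_smooth = {int(d): float(logistic(float(d), d0, a)) for d in range(1, max_order + 1)}
    return GroupChangeParams(
        beta=beta, b_d=b_smooth, d0=float(d0), alpha_logistic=float(a),
        epsilon=epsilon, L=L, variant=variant,
        diagnostics={"b_raw": b_raw, "n_taus": len(taus)},
    )


def _encounter_sets(H: TemporalHypergraph, t: int, L: int) -> dict:
    """Node -> set of nodes co-present in >= 1 event within ``[t-L, t]``."""
    enc: dict = {u: set() for u in H.node_set}
    for s in range(max(1, t - L), t + 1):
        for h in H.snapshot(s):
            for u in h:
                enc[u].update(h)
    for u in enc:
        enc[u].discard(u)
    return enc


def step_group_change(
    state: GroupState,
    H_context: TemporalHypergraph,
    params: GroupChangeParams,
    t: int,
    rng: np.random.Generator,
    *,
    encounters: dict | None = None,
) -> GroupState:
    """Advance the group configuration by one step.

    Nodes update sequentially in a random permutation, each seeing the
    current configuration.  A changer joins a candidate active group with
    probability proportional to the fraction of its members encountered in
    ``[t-L, t]``; each of the ``epsilon`` empty-set copies has unit weight,
    so large ``epsilon`` drives changers to isolation.  The changer's old
    group disbands to singletons.
    """
    N = len(H_context.node_set)
    if encounters is None:
        encounters = _encounter_sets(H_context, t, params.L)
    groups = {gid: set(g) for gid, g in state.groups.items()}
    membership = dict(state.membership)
    residence = dict(state.residence)
    changed: set = set()
    next_gid = max(groups, default=-1) + 1

    def disband(gid: int, keep: object | None) -> None:
        nonlocal next_gid
        members = groups.pop(gid)
        for v in sorted(members):
            if v == keep:
                continue
            groups[next_gid] = {v}
            membership[v] = next_gid
            changed.add(v)
            next_gid += 1

    order = rng.permutation(sorted(H_context.node_set))
    for u in order:
        gid = membership[u]
        d = len(groups[gid])
        tau = residence[u]
        p = change_probability(params, d, tau, N)
        if rng.random() >= p:
            continue
        # every other group is a candidate, singletons included: joining an
        # isolated node is how new pairs form
        candidates = [g for g in groups if g != gid]
        weights = []
        for g in candidates:
            members = groups[g]
            known = len(encounters.get(u, set()) & members)
            weights.append(known / len(members))
        weights.append(float(params.epsilon))  # epsilon unit-weight empty copies
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        old_gid = gid
        if total <= 0:
            target = None  # nothing to join: become isolated
        else:
            k = rng.choice(len(weights), p=weights / total)
            target = candidates[k] if k < len(candidates) else None
        # leave: old group disbands (changer removed first)
        groups[old_gid].discard(u)
        if groups[old_gid]:
            disband(old_gid, keep=None)
        else:
            del groups[old_gid]
        if target is None:
            groups[next_gid] = {u}
            membership[u] = next_gid
            next_gid += 1
        else:
            groups[target].add(u)
            membership[u] = target
        changed.add(u)

    for u in membership:
        residence[u] = 1 if u in changed else residence[u] + 1
    return GroupState(groups, membership, residence)


def simulate_group_change(
    n_nodes: int,
    params: GroupChangeParams,
    horizon: int,
    rng: np.random.Generator,
    *,
    init_group_sizes: Sequence[int] = (2, 2, 3, 3, 4),
) -> TemporalHypergraph:
    """Run the group-change dynamics forward as a generative process.

    Starts from a partition with the given group sizes (remaining nodes
    isolated) and records the non-singleton groups at every step as events.
    Encounter memory is taken from the generated history itself.
    """
    nodes = list(range(n_nodes))
    if sum(init_group_sizes) > n_nodes:
        raise ValueError("initial groups need more nodes than available")
    groups: dict[int, set] = {}
    membership: dict = {}
    gid = 0
    k = 0
    for size in init_group_sizes:
        groups[gid] = set(nodes[k : k + size])
        for u in groups[gid]:
            membership[u] = gid
        k += size
        gid += 1
    for u in nodes[k:]:
        groups[gid] = {u}
        membership[u] = gid
        gid += 1
    state = GroupState(groups, membership, {u: 1 for u in nodes})

    events_at: dict[int, set] = {}
    node_set = frozenset(nodes)
    H = TemporalHypergraph(node_set=node_set, horizon=horizon, events_at=events_at)
    for t in range(1, horizon + 1):
        ev = state.events()
        if ev:
            events_at[t] = ev
        if t < horizon:
            state = step_group_change(state, H, params, t, rng)
    return TemporalHypergraph(node_set=node_set, horizon=horizon,
                              events_at=events_at)


class GroupChangeModel:
    """Group-change baseline bound to one observed network."""

    def __init__(
        self,
        H: TemporalHypergraph,
        params: GroupChangeParams | None = None,
        *,
        L: int = 30,
        epsilon: int = 100,
    ):
        self.H = H
        self.params = params if params is not None else fit_group_change(H, L, epsilon=epsilon)
        self._state_cache: dict[int, GroupState] = {}
        self._encounter_cache: dict[int, dict] = {}

    def predict(self, t: int, rng: np.random.Generator) -> dict[int, set]:
        """One stochastic step from the true configuration at ``t``."""
        if t not in self._state_cache:
            self._state_cache[t] = group_state_from_history(self.H, t)
            self._encounter_cache[t] = _encounter_sets(self.H, t, self.params.L)
        state = self._state_cache[t]
        new = step_group_change(
            state, self.H, self.params, t, rng,
            encounters=self._encounter_cache[t],
        )
        out: dict[int, set] = {}
        for h in new.events():
            out.setdefault(len(h), set()).add(h)
        return out
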
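"""Memory-based predictors of next-step hyperlink activity.

The *activation tendency* of hyperlink ``i`` of order ``d`` at prediction
step ``t + 1`` is modelled as a linear function of exponentially time-decayed
neighbour activity:

    w_i(t+1) = sum_phi c_phi * y_i^phi(t) + c_d,
    y_i^phi(t) = sum_{k=t-L+1}^{t} sum_{j in S_i^phi} x_j(k) * exp(-tau (t-k)),

where ``S_i^phi`` is the set of phi-neighbours of ``i`` in the aggregated
network (for the target type ``(d,d,d)`` it is ``{i}`` itself), ``L`` is the
observation window and ``tau`` the decay factor.  The coefficients are
learned per order by Lasso regression over every prediction step of the
observation window; given the true number ``n_d`` of order-``d`` events at
``t + 1``, the ``n_d`` hyperlinks with the highest tendency are predicted
active (boundary ties resolved uniformly at random).

The *general* model uses all neighbour types ``Phi_d``; the *refined* model
keeps only the target itself and its sub-/super-hyperlinks.  The *self-driven*
pairwise model scores each pairwise link by its own decayed activity
(no coefficients), predicts the true number of pairwise contacts and promotes
maximal cliques of the predicted edge set back to higher-order events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .core import (
    AggregatedHypergraph,
    Hyperlink,
    NeighborType,
    TemporalHypergraph,
    aggregate,
    aggregate_pairwise,
    canonicalize,
    decompose_pairwise,
    enumerate_phi_types,
)

__all__ = [
    "DecayParams",
    "ModelCoefficients",
    "UnfittedModelError",
    "InsufficientHistoryError",
    "default_alpha_grid",
    "decay_kernel",
    "decay_feature",
    "tendency_self_driven",
    "tendency_general",
    "refined_phi_set",
    "fit_lasso",
    "predict_topn",
    "TendencyModel",
    "SelfDrivenModel",
]


class UnfittedModelError(RuntimeError):
    """Prediction requested before coefficients were fitted."""


class InsufficientHistoryError(ValueError):
    """Prediction step earlier than the observation window allows."""


@dataclass(frozen=True)
class DecayParams:
    """Observation window length ``L`` (steps) and decay factor ``tau``."""

    L: int = 30
    tau: float = 5.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not np.isfinite(self.tau) or self.tau < 0:
            raise ValueError("tau must be finite and >= 0")


def decay_kernel(params: DecayParams) -> np.ndarray:
    """Weights ``exp(-tau * m)`` for lags ``m = 0 .. L-1`` (most recent first)."""
    return np.exp(-params.tau * np.arange(params.L, dtype=np.float64))


def default_alpha_grid(lo: float = 1e-19, hi: float = 10.0, num: int = 200) -> np.ndarray:
    """Logarithmically spaced L1-penalty grid (endpoints included)."""
    return np.logspace(np.log10(lo), np.log10(hi), num)


def _windowed_decay(series: np.ndarray, params: DecayParams) -> np.ndarray:
    """Decayed window sums ``y(t) = sum_{m=0}^{L-1} s(t-m) e^{-tau m}`` for
    every 1-based ``t`` in ``[L, T]``; returned array index 0 is ``t = L``."""
    kernel = decay_kernel(params)
    conv = np.convolve(np.asarray(series, dtype=np.float64), kernel)
    return conv[params.L - 1 : len(series)]


def decay_feature(
    agg: AggregatedHypergraph,
    target: Hyperlink,
    phi: NeighborType,
    t: int,
    params: DecayParams,
) -> float:
    """``y_i^phi(t)``: decayed summed activity of the phi-neighbours of
    ``target`` over the window ``[t-L+1, t]`` (1-based ``t``, full window
    required).  Zero when the target has no phi-neighbour."""
    if t < params.L:
        raise InsufficientHistoryError(f"t={t} < L={params.L}")
    if t > agg.horizon:
        raise ValueError(f"t={t} beyond horizon {agg.horizon}")
    s = agg.neighbor_activity_sum(target, phi)
    kernel = decay_kernel(params)
    window = s[t - params.L : t][::-1]  # most recent first
    return float(window @ kernel)


def tendency_self_driven(
    agg_pairwise: AggregatedHypergraph,
    link: Hyperlink,
    t: int,
    params: DecayParams,
) -> float:
    """Self-driven pairwise tendency: the link's own decayed activity."""
    if t < params.L:
        raise InsufficientHistoryError(f"t={t} < L={params.L}")
    x = np.asarray(agg_pairwise.activity[link], dtype=np.float64)
    window = x[t - params.L : t][::-1]
    return float(window @ decay_kernel(params))


@dataclass
class ModelCoefficients:
    """Fitted per-order linear coefficients ``c_phi`` plus intercept ``c_d``."""

    d: int
    intercept: float
    coeffs: dict[str, float]  # phi label (e.g. "322") -> c_phi
    phi_set: list[NeighborType]
    params: DecayParams
    alpha: float
    metadata: dict = field(default_factory=dict)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coeffs[phi.label] for phi in self.phi_set])

    def as_text(self) -> str:
        lines = [f"order\t{self.d}", f"alpha\t{self.alpha:.6g}",
                 f"intercept\t{self.intercept:.6g}"]
        for phi in self.phi_set:
            lines.append(f"c{phi.label}\t{self.coeffs[phi.label]:.6g}")
        return "\n".join(lines) + "\n"


def refined_phi_set(d: int, max_order: int = 4) -> list[NeighborType]:
    """Target, sub- and super-hyperlink types for an order-``d`` target."""
    return [
        phi for phi in enumerate_phi_types(d, max_order)
        if phi.kind in ("target", "sub", "super")
    ]


def tendency_general(
    agg: AggregatedHypergraph,
    target: Hyperlink,
    t: int,
    params: DecayParams,
    coeffs: ModelCoefficients,
) -> float:
    """``w_i(t+1)`` for one target hyperlink from fitted coefficients."""
    if coeffs is None:
        raise UnfittedModelError("coefficients not fitted")
    if coeffs.d != len(target):
        raise UnfittedModelError(
            f"coefficients fitted for order {coeffs.d}, target has order {len(target)}"
        )
    w = coeffs.intercept
    for phi in coeffs.phi_set:
        w += coeffs.coeffs[phi.label] * decay_feature(agg, target, phi, t, params)
    return float(w)


def _feature_tensor(
    agg: AggregatedHypergraph,
    d: int,
    params: DecayParams,
    phi_set: Sequence[NeighborType],
) -> tuple[list[Hyperlink], np.ndarray]:
    """Features for every order-``d`` hyperlink at every full-window step.

    Returns ``(links, Y)`` with ``Y[i, s, p] = y_i^phi_p(t)`` where
    ``t = L + s`` (1-based), ``s = 0 .. T - L``.
    """
    links = agg.by_order.get(d, [])
    n_steps = agg.horizon - params.L + 1
    Y = np.zeros((len(links), n_steps, len(phi_set)))
    for li, link in enumerate(links):
        for pi, phi in enumerate(phi_set):
            s = agg.neighbor_activity_sum(link, phi)
            Y[li, :, pi] = _windowed_decay(s, params)
    return links, Y


# The L1 penalty uses the standard per-sample-normalized convention
# (objective (1/2n)||x - w||^2 + alpha * sum|c|): on the published grid
# [1e-19, 10] the top of the range then genuinely drives every coefficient
# to zero, which an unnormalized sum-of-squares objective would not.


def fit_lasso(
    H: TemporalHypergraph | None,
    agg: AggregatedHypergraph,
    d: int,
    params: DecayParams,
    phi_set: Sequence[NeighborType] | None = None,
    alpha_grid: Sequence[float] | None = None,
    *,
    max_order: int = 4,
    cv: int = 5,
    standardize: bool = False,
    penalize_intercept: bool = False,
    seed: int | None = 0,
) -> ModelCoefficients:
    """Fit per-order tendency coefficients by L1-regularized least squares.

    Training rows are every (hyperlink, prediction step) pair with
    ``t + 1 in [L+1, T]``: features are the decayed phi-neighbour activities
    ``y_i^phi(t)``, the label is the true activity ``x_i(t+1)``.  The penalty
    strength is selected from ``alpha_grid`` by ``cv``-fold cross-validated
    mean squared error (grid default: 200 log-spaced points in [1e-19, 10]).
    The intercept is unpenalized unless ``penalize_intercept``.
    """
    if agg.horizon < params.L + 2:
        raise ValueError(f"need T >= L + 2, got T={agg.horizon}, L={params.L}")
    if not agg.by_order.get(d):
        raise ValueError(f"no order-{d} hyperlink in the aggregated network")
    if phi_set is None:
        phi_set = enumerate_phi_types(d, max_order)
    phi_set = list(phi_set)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(sorted(alpha_grid))

    links, Y = _feature_tensor(agg, d, params, phi_set)
    # rows: steps t = L .. T-1 (predicting t+1 = L+1 .. T)
    X = Y[:, :-1, :].reshape(-1, len(phi_set))
    labels = np.stack([np.asarray(agg.activity[h], dtype=np.float64) for h in links])
    y = labels[:, params.L :].reshape(-1)

    meta: dict = {"n_rows": len(y), "cv": cv, "standardize": standardize,
                  "penalize_intercept": penalize_intercept}
    if standardize:
        mu, sigma = X.mean(axis=0), X.std(axis=0)
        sigma[sigma == 0.0] = 1.0
        X = (X - mu) / sigma

    if np.all(y == y[0]):
        warnings.warn("degenerate labels (all equal); intercept-only model")
        coeffs = {phi.label: 0.0 for phi in phi_set}
        return ModelCoefficients(d, float(y[0]), coeffs, phi_set, params,
                                 float(alpha_grid[0]), meta | {"degenerate": True})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalize_intercept:
            best_alpha, best_mse = None, np.inf
            Xc = np.hstack([X, np.ones((len(y), 1))])
            kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
            for a in alpha_grid:
                mses = []
                for tr, te in kf.split(Xc):
                    m = Lasso(alpha=a, fit_intercept=False, max_iter=5000)
                    m.fit(Xc[tr], y[tr])
                    mses.append(np.mean((m.predict(Xc[te]) - y[te]) ** 2))
                mse = float(np.mean(mses))
                if mse < best_mse:
                    best_alpha, best_mse = float(a), mse
            m = Lasso(alpha=best_alpha, fit_intercept=False, max_iter=50000)
            m.fit(Xc, y)
            coef, intercept = m.coef_[:-1], float(m.coef_[-1])
            alpha_sel = best_alpha
            meta["cv_mse"] = best_mse
        elif len(alpha_grid) == 1:
            m = Lasso(alpha=float(alpha_grid[0]), fit_intercept=True, max_iter=50000)
            m.fit(X, y)
            coef, intercept = m.coef_, float(m.intercept_)
            alpha_sel = float(alpha_grid[0])
        else:
            kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
            model = LassoCV(alphas=alpha_grid, fit_intercept=True, cv=kf,
                            max_iter=5000)
            model.fit(X, y)
            # refit at the selected alpha with a tighter budget
            m = Lasso(alpha=model.alpha_, fit_intercept=True, max_iter=50000)
            m.fit(X, y)
            coef, intercept = m.coef_, float(m.intercept_)
            alpha_sel = float(model.alpha_)
            meta["cv_mse"] = float(np.atleast_2d(model.mse_path_).mean(axis=-1).min())

    if standardize:
        coef = coef / sigma
        intercept = intercept - float(coef @ mu)
    coeffs = {phi.label: float(c) for phi, c in zip(phi_set, coef)}
    return ModelCoefficients(d, intercept, coeffs, phi_set, params, alpha_sel, meta)


def coefficient_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float],
    *,
    standardize: bool = True,
) -> np.ndarray:
    """Lasso coefficients at each penalty of ``alpha_grid`` (paper scale).

    Returns an array of shape ``(len(alpha_grid), n_features)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if standardize:
        mu, sigma = X.mean(axis=0), X.std(axis=0)
        sigma[sigma == 0.0] = 1.0
        X = (X - mu) / sigma
    out = np.zeros((len(alpha_grid), X.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, a in enumerate(alpha_grid):
            m = Lasso(alpha=a, fit_intercept=True, max_iter=20000)
            m.fit(X, y)
            out[i] = m.coef_
    return out


def training_matrix(
    agg: AggregatedHypergraph,
    d: int,
    params: DecayParams,
    phi_set: Sequence[NeighborType] | None = None,
    *,
    max_order: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and labels used by :func:`fit_lasso` (exposed for
    diagnostics such as coefficient paths)."""
    if phi_set is None:
        phi_set = enumerate_phi_types(d, max_order)
    links, Y = _feature_tensor(agg, d, params, list(phi_set))
    X = Y[:, :-1, :].reshape(-1, len(phi_set))
    labels = np.stack([np.asarray(agg.activity[h], dtype=np.float64) for h in links])
    y = labels[:, params.L :].reshape(-1)
    return X, y


def predict_topn(
    tendencies: Mapping[Hyperlink, float], n: int, rng: np.random.Generator
) -> set:
    """The ``n`` hyperlinks with the highest tendency.

    Candidates strictly above the selection boundary are always included;
    remaining slots are filled uniformly at random among candidates tied at
    the boundary value.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    items = list(tendencies.items())
    if n >= len(items):
        if n > len(items):
            warnings.warn(f"requested top {n} of {len(items)} candidates; predicting all")
        return {h for h, _ in items}
    if n == 0:
        return set()
    values = np.array([w for _, w in items])
    order = np.argsort(-values, kind="stable")
    boundary = values[order[n - 1]]
    above = [items[k][0] for k in order if values[k] > boundary]
    tied = [items[k][0] for k in order if values[k] == boundary]
    slots = n - len(above)
    chosen = rng.choice(len(tied), size=slots, replace=False)
    return set(above) | {tied[k] for k in chosen}


class TendencyModel:
    """General or refined memory model over an observed temporal hypergraph.

    Precomputes the decayed feature tensor once, fits Lasso coefficients per
    order, and serves per-step predictions.  ``mode`` is ``"general"`` (all
    phi types) or ``"refined"`` (target + sub + super only).
    """

    def __init__(
        self,
        H: TemporalHypergraph,
        params: DecayParams = DecayParams(),
        *,
        mode: str = "general",
        max_order: int = 4,
        orders: Sequence[int] | None = None,
    ):
        if mode not in ("general", "refined"):
            raise ValueError(f"unknown mode {mode!r}")
        self.H = H
        self.params = params
        self.mode = mode
        self.max_order = max_order
        self.agg = aggregate(H)
        self.orders = [
            d for d in (orders or self.agg.orders())
            if 2 <= d <= max_order and self.agg.by_order.get(d)
        ]
        self.coefficients: dict[int, ModelCoefficients] = {}
        self._links: dict[int, list[Hyperlink]] = {}
        self._features: dict[int, np.ndarray] = {}

    def phi_set(self, d: int) -> list[NeighborType]:
        if self.mode == "refined":
            return refined_phi_set(d, self.max_order)
        return enumerate_phi_types(d, self.max_order)

    def fit(self, alpha_grid: Sequence[float] | None = None, *,
            cv: int = 5, seed: int | None = 0, standardize: bool = False,
            train_until: int | None = None) -> "TendencyModel":
        """Fit coefficients for every analysed order.

        ``train_until`` restricts training labels to ``t + 1 <= train_until``
        for honest past-only fitting; default uses the whole horizon, as the
        reference evaluation protocol does.
        """
        for d in self.orders:
            agg = self.agg
            if train_until is not None:
                agg = _truncate(self.agg, train_until)
            self.coefficients[d] = fit_lasso(
                None, agg, d, self.params, self.phi_set(d), alpha_grid,
                max_order=self.max_order, cv=cv, seed=seed,
                standardize=standardize,
            )
        return self

    def set_coefficients(self, coeffs: Mapping[int, ModelCoefficients]) -> "TendencyModel":
        """Install externally chosen coefficients (e.g. a sweep grid point)."""
        self.coefficients = dict(coeffs)
        return self

    def _ensure_features(self, d: int) -> None:
        if d not in self._features:
            links, Y = _feature_tensor(self.agg, d, self.params, self.phi_set(d))
            self._links[d] = links
            self._features[d] = Y

    def tendencies(self, d: int, t: int) -> dict[Hyperlink, float]:
        """``w_i(t+1)`` for every aggregated order-``d`` hyperlink."""
        if d not in self.coefficients:
            raise UnfittedModelError(f"no coefficients for order {d}")
        if t < self.params.L:
            raise InsufficientHistoryError(f"t={t} < L={self.params.L}")
        self._ensure_features(d)
        c = self.coefficients[d]
        w = self._features[d][:, t - self.params.L, :] @ c.coef_vector() + c.intercept
        return dict(zip(self._links[d], w))

    def predict(
        self,
        t: int,
        per_order_counts: Mapping[int, int],
        rng: np.random.Generator,
    ) -> dict[int, set]:
        """Top-``n_d`` prediction for step ``t + 1``, independently per order."""
        out: dict[int, set] = {}
        for d in self.orders:
            if d not in per_order_counts:
                raise ValueError(f"per_order_counts missing order {d}")
            out[d] = predict_topn(self.tendencies(d, t), per_order_counts[d], rng)
        return out


class SelfDrivenModel:
    """Pairwise self-driven baseline promoted back to higher orders.

    Decomposes the observed hypergraph into pairwise contacts, scores every
    aggregated pairwise link by its own decayed activity, predicts the true
    number of pairwise contacts at ``t + 1`` and promotes maximal cliques of
    the predicted edge set; per-order counts of the output are emergent.
    """

    def __init__(self, H: TemporalHypergraph, params: DecayParams = DecayParams()):
        self.H = H
        self.params = params
        self.pairwise = decompose_pairwise(H)
        self.agg_pairwise = aggregate_pairwise(self.pairwise)
        self._links = self.agg_pairwise.by_order.get(2, [])
        self._scores = np.stack(
            [_windowed_decay(self.agg_pairwise.activity[e], params) for e in self._links]
        ) if self._links else np.zeros((0, 0))

    def true_pairwise_count(self, t_plus_1: int) -> int:
        return len(self.pairwise.snapshot(t_plus_1))

    def predict_edges(self, t: int, n_edges: int, rng: np.random.Generator) -> set:
        if t < self.params.L:
            raise InsufficientHistoryError(f"t={t} < L={self.params.L}")
        col = self._scores[:, t - self.params.L]
        return predict_topn(dict(zip(self._links, col)), n_edges, rng)

    def predict(self, t: int, rng: np.random.Generator) -> dict[int, set]:
        """Predicted events of every order at ``t + 1``."""
        edges = self.predict_edges(t, self.true_pairwise_count(t + 1), rng)
        if not edges:
            return {}
        g = nx.Graph()
        g.add_edges_from(edges)
        out: dict[int, set] = {}
        for clique in nx.find_cliques(g):
            h = canonicalize(clique)
            out.setdefault(len(h), set()).add(h)
        return out


def _truncate(agg: AggregatedHypergraph, horizon: int) -> AggregatedHypergraph:
    activity = {h: x[:horizon] for h, x in agg.activity.items() if x[:horizon].any()}
    return AggregatedHypergraph(horizon, activity)
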
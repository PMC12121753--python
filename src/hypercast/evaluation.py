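"""Prediction-quality evaluation, count diagnostics and parameter sweeps.

Accuracy of a prediction for one order at one step is the fraction of true
events recovered: ``|predicted ∩ truth| / |truth|``.  Steps with no true
event of that order are skipped (the ratio is undefined).  Because tie-broken
and probabilistic models are stochastic, accuracy is averaged over
realizations at each step — each realization drawing from a fresh,
deterministic substream of a root seed — and then over prediction steps
``t + 1 in [L+1, T]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .baselines import ActivityDrivenModel, GroupChangeModel
from .core import TemporalHypergraph
from .models import (
    DecayParams,
    ModelCoefficients,
    SelfDrivenModel,
    TendencyModel,
    refined_phi_set,
)

__all__ = [
    "accuracy",
    "AccuracyReport",
    "evaluate_model",
    "predicted_count_distribution",
    "sweep_coefficients",
    "sweep_params",
    "DEFAULT_REALIZATIONS",
]

#: realizations per prediction step: tendency/activity-driven vs group-change
DEFAULT_REALIZATIONS = {"tendency": 100, "activity": 100, "group_change": 10}


def accuracy(predicted: set, truth: set) -> float:
    """Fraction of true events recovered (``truth`` must be non-empty)."""
    if not truth:
        raise ValueError("accuracy undefined for empty truth")
    return len(set(predicted) & set(truth)) / len(truth)


@dataclass
class AccuracyReport:
    """Mean prediction accuracy per order plus per-step series."""

    model: str
    mean_accuracy: dict[int, float]
    per_step: dict[int, np.ndarray]        # order -> accuracy per evaluated step
    steps: dict[int, list[int]]            # order -> prediction steps t+1 used
    realizations: int
    params: dict = field(default_factory=dict)

    def to_table(self) -> str:
        rows = ["model\torder\tmean_accuracy\tn_steps\tn_realizations"]
        for d in sorted(self.mean_accuracy):
            rows.append(
                f"{self.model}\t{d}\t{self.mean_accuracy[d]:.6g}"
                f"\t{len(self.steps[d])}\t{self.realizations}"
            )
        return "\n".join(rows) + "\n"


def _needs_counts(model) -> bool:
    return isinstance(model, (TendencyModel, ActivityDrivenModel))


def _model_kind(model) -> str:
    if isinstance(model, GroupChangeModel):
        return "group_change"
    if isinstance(model, ActivityDrivenModel):
        return "activity"
    return "tendency"


def _predict(model, t: int, counts: Mapping[int, int], rng: np.random.Generator) -> dict[int, set]:
    if _needs_counts(model):
        return model.predict(t, counts, rng)
    return model.predict(t, rng)


def evaluate_model(
    model,
    H: TemporalHypergraph,
    L: int,
    *,
    orders: Sequence[int] = (2, 3, 4),
    realizations: int | None = None,
    seed: int = 0,
    name: str | None = None,
) -> AccuracyReport:
    """Average per-order accuracy over prediction steps and realizations.

    For each prediction step ``t + 1 in [L+1, T]`` the true per-order event
    counts are read from ``H`` (the evaluation protocol assumes they are
    known) and accuracy is averaged over ``realizations`` stochastic
    predictions; each (step, realization) pair uses the substream
    ``default_rng([seed, t, r])``.
    """
    if H.horizon < L + 2:
        raise ValueError(f"need T >= L + 2, got T={H.horizon}")
    realizations = realizations if realizations is not None else \
        DEFAULT_REALIZATIONS[_model_kind(model)]
    orders = [d for d in orders]
    per_step: dict[int, list[float]] = {d: [] for d in orders}
    steps: dict[int, list[int]] = {d: [] for d in orders}
    for t in range(L, H.horizon):
        truth = {d: H.snapshot_at_order(t + 1, d) for d in orders}
        counts = {d: len(truth[d]) for d in orders}
        acc_sums = {d: 0.0 for d in orders if counts[d] > 0}
        if acc_sums:
            for r in range(realizations):
                rng = np.random.default_rng([seed, t, r])
                pred = _predict(model, t, counts, rng)
                for d in acc_sums:
                    a = accuracy(pred.get(d, set()), truth[d])
                    acc_sums[d] += a
                    if _needs_counts(model):
                        assert len(pred.get(d, set())) == counts[d]
        for d in acc_sums:
            per_step[d].append(acc_sums[d] / realizations)
            steps[d].append(t + 1)
    mean = {
        d: float(np.mean(per_step[d])) for d in orders if per_step[d]
    }
    return AccuracyReport(
        model=name or type(model).__name__,
        mean_accuracy=mean,
        per_step={d: np.asarray(v) for d, v in per_step.items() if v},
        steps={d: s for d, s in steps.items() if s},
        realizations=realizations,
        params={"L": L, "seed": seed},
    )


def predicted_count_distribution(
    model,
    H: TemporalHypergraph,
    L: int,
    *,
    orders: Sequence[int] = (2, 3, 4),
    seed: int = 0,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-order predicted vs true event counts across prediction steps.

    Intended for the count-unconstrained models (self-driven, group-change);
    count-constrained models reproduce the truth histogram by construction.
    """
    out: dict[int, tuple[list[int], list[int]]] = {d: ([], []) for d in orders}
    for t in range(L, H.horizon):
        rng = np.random.default_rng([seed, t, 0])
        counts = {d: len(H.snapshot_at_order(t + 1, d)) for d in orders}
        pred = _predict(model, t, counts, rng)
        for d in orders:
            out[d][0].append(counts[d])
            out[d][1].append(len(pred.get(d, set())))
    return {
        d: (np.asarray(true), np.asarray(p)) for d, (true, p) in out.items()
    }


def sweep_coefficients(
    H: TemporalHypergraph,
    params: DecayParams,
    grid: Sequence[float],
    *,
    orders: Sequence[int] = (2, 3, 4),
    max_order: int = 4,
    realizations: int = 10,
    seed: int = 0,
) -> dict[tuple[float, float], AccuracyReport]:
    """Refined-model accuracy over a (c_sub, c_super) grid with c_target = 1.

    Every sub-type coefficient of an order takes the value ``c_sub`` and
    every super-type coefficient ``c_super``; the intercept is 0.
    """
    base = TendencyModel(H, params, mode="refined", max_order=max_order,
                         orders=list(orders))
    out: dict[tuple[float, float], AccuracyReport] = {}
    for c_sub in grid:
        for c_super in grid:
            coeffs: dict[int, ModelCoefficients] = {}
            for d in base.orders:
                phi_set = refined_phi_set(d, max_order)
                cmap = {}
                for phi in phi_set:
                    cmap[phi.label] = {"target": 1.0, "sub": c_sub,
                                       "super": c_super}[phi.kind]
                coeffs[d] = ModelCoefficients(
                    d, 0.0, cmap, phi_set, params, alpha=0.0,
                    metadata={"sweep": True},
                )
            base.set_coefficients(coeffs)
            out[(float(c_sub), float(c_super))] = evaluate_model(
                base, H, params.L, orders=base.orders,
                realizations=realizations, seed=seed,
                name=f"refined(c_sub={c_sub}, c_super={c_super})",
            )
    return out


def sweep_params(
    H: TemporalHypergraph,
    mode: str,
    tau_values: Sequence[float],
    L_values: Sequence[int],
    *,
    orders: Sequence[int] = (2, 3, 4),
    alpha_grid: Sequence[float] | None = None,
    realizations: int = 10,
    seed: int = 0,
) -> dict[tuple[float, int], AccuracyReport]:
    """Refit and evaluate a tendency model over a (tau, L) grid."""
    out: dict[tuple[float, int], AccuracyReport] = {}
    for tau in tau_values:
        for L in L_values:
            params = DecayParams(L=L, tau=tau)
            model = TendencyModel(H, params, mode=mode, orders=list(orders))
            model.fit(alpha_grid, seed=seed)
            out[(float(tau), int(L))] = evaluate_model(
                model, H, L, orders=model.orders,
                realizations=realizations, seed=seed,
                name=f"{mode}(tau={tau}, L={L})",
            )
    return out
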
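"""Derringer–Suich desirability optimization over fitted response surfaces.

Each response is mapped to an individual desirability d in [0, 1] (0 =
unacceptable, 1 = ideal) by a piecewise-power transform anchored at a lower
and upper value; the overall desirability D is the weighted geometric mean
of the individual d's, so any single unacceptable response drives D to 0.
The optimum is the coded point maximizing D over a rectangular search
region, found by a dense deterministic grid scan followed by a bounded
local polish — no randomness, so results are exactly reproducible.

By default the anchors for a maximized response are its fitted minimum and
maximum over the search region ("auto"), weights are equal, and the region
is the factorial square [-1, +1] per factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import DesignSpec, code_to_actual
from .rsm import QuadraticFit, predict

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimumResult",
    "individual_desirability",
    "overall_desirability",
    "optimize",
    "desirability_grid",
]

GOALS = ("maximize", "minimize", "target")


@dataclass(frozen=True)
class ResponseGoal:
    """Goal for one response: direction, anchor values and weight.

    ``lower``/``upper`` of ``None`` mean "auto": use the response's fitted
    min/max over the search region. ``target`` is required only for the
    two-sided goal. ``weight`` is the desirability exponent (>1 demands
    values closer to the ideal before d rises).
    """

    goal: str = "maximize"
    lower: float | None = None
    upper: float | None = None
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in GOALS:
            raise ValueError(f"goal must be one of {GOALS}, got {self.goal!r}")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError("lower anchor must be below upper anchor")
        if self.goal == "target" and self.target is None:
            raise ValueError("target goal requires a target value")


@dataclass(frozen=True)
class DesirabilitySpec:
    """Per-response goals plus the coded search region."""

    goals: Mapping[str, ResponseGoal]
    bounds: tuple[tuple[float, float], ...] | None = None

    def region(self, k: int) -> tuple[tuple[float, float], ...]:
        if self.bounds is None:
            return tuple((-1.0, 1.0) for _ in range(k))
        if len(self.bounds) != k:
            raise ValueError(f"bounds have length {len(self.bounds)}, expected {k}")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError("each bound must be finite with lower < upper")
        return tuple(self.bounds)


@dataclass
class OptimumResult:
    coded: np.ndarray
    actual: np.ndarray | None
    overall: float
    individual: dict[str, float]
    predicted: dict[str, float]


def individual_desirability(value, goal="maximize", lower=0.0, upper=1.0,
                            weight=1.0, target=None):
    """Map a response value to a desirability in [0, 1].

    maximize: 0 at/below ``lower``, 1 at/above ``upper``, rising as
    ``((y - lower)/(upper - lower))**weight`` between. minimize is the
    mirror image. target rises from ``lower`` to 1 at ``target`` then
    falls back to 0 at ``upper``.
    """
    if not lower < upper:
        raise ValueError("lower anchor must be below upper anchor")
    if not weight > 0:
        raise ValueError("weight must be positive")
    y = np.asarray(value, dtype=float)
    span = upper - lower
    if goal == "maximize":
        d = np.clip((y - lower) / span, 0.0, 1.0) ** weight
    elif goal == "minimize":
        d = np.clip((upper - y) / span, 0.0, 1.0) ** weight
    elif goal == "target":
        if target is None or not (lower < target < upper):
            raise ValueError("target must lie strictly between the anchors")
        rise = np.clip((y - lower) / (target - lower), 0.0, 1.0)
        fall = np.clip((upper - y) / (upper - target), 0.0, 1.0)
        d = np.minimum(rise, fall) ** weight
    else:
        raise ValueError(f"goal must be one of {GOALS}, got {goal!r}")
    return float(d) if d.ndim == 0 else d


def overall_desirability(d_values, weights=None):
    """Weighted geometric mean of individual desirabilities.

    ``D = (prod d_i**w_i)**(1/sum w_i)``; 0 if any d_i is 0.
    """
    d = np.atleast_2d(np.asarray(d_values, dtype=float))
    if d.shape[-1] == 0:
        raise ValueError("need at least one desirability value")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    w = np.ones(d.shape[-1]) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    # geometric mean in log space; log(0) -> -inf -> D = 0
    with np.errstate(divide="ignore"):
        out = np.exp(np.where(
            np.any(d == 0.0, axis=-1),
            -np.inf,
            (np.log(np.where(d > 0, d, 1.0)) @ w) / w.sum(),
        ))
    out = np.asarray(out)
    return float(out[0]) if out.size == 1 and np.ndim(d_values) <= 1 else out


def _resolve_anchors(
    fits: Sequence[QuadraticFit],
    spec: DesirabilitySpec,
    grid_pts: np.ndarray,
) -> dict[str, tuple[float, float]]:
    anchors = {}
    for fit in fits:
        goal = spec.goals[fit.response_name]
        lo, hi = goal.lower, goal.upper
        if lo is None or hi is None:
            pred = predict(fit, grid_pts)
            lo = float(pred.min()) if lo is None else lo
            hi = float(pred.max()) if hi is None else hi
            if not lo < hi:  # flat surface: degenerate anchor window
                hi = lo + 1e-12
        anchors[fit.response_name] = (lo, hi)
    return anchors


def _check_fits(fits: Sequence[QuadraticFit], spec: DesirabilitySpec) -> None:
    if not fits:
        raise ValueError("need at least one fitted response")
    names0 = fits[0].factor_names
    for fit in fits:
        if fit.factor_names != names0:
            raise ValueError("all fits must share the same design factors")
        if fit.response_name not in spec.goals:
            raise ValueError(f"no goal specified for response {fit.response_name!r}")


def _grid_points(region, resolution):
    axes = [np.linspace(lo, hi, resolution) for lo, hi in region]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def _overall_at(fits, spec, anchors, pts):
    d_cols = []
    for fit in fits:
        g = spec.goals[fit.response_name]
        lo, hi = anchors[fit.response_name]
        d_cols.append(
            individual_desirability(
                predict(fit, pts), g.goal, lo, hi, g.weight, g.target
            )
        )
    d = np.column_stack(d_cols)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    # weight exponents are already inside individual_desirability; combine
    # with plain geometric mean over responses
    D = np.exp(logd.mean(axis=1))
    D[np.any(d == 0.0, axis=1)] = 0.0
    return D, d


def optimize(
    fits: Sequence[QuadraticFit],
    spec: DesirabilitySpec,
    resolution: int = 201,
    design_spec: DesignSpec | None = None,
) -> OptimumResult:
    """Maximize overall desirability over the coded search region.

    Deterministic: a ``resolution``-per-axis grid scan locates the basin
    (ties broken by first-found lexicographic grid order), then L-BFGS-B
    polishes within the bounds. When *design_spec* is given, the optimum is
    also reported on the actual factor scale.
    """
    _check_fits(fits, spec)
    k = fits[0].k
    region = spec.region(k)
    pts = _grid_points(region, resolution)
    anchors = _resolve_anchors(fits, spec, pts)

    D, _ = _overall_at(fits, spec, anchors, pts)
    best = int(np.argmax(D))  # argmax takes the first maximum: lexicographic ties
    x0 = pts[best]

    def negD(x):
        val, _ = _overall_at(fits, spec, anchors, x[None, :])
        return -val[0]

    res = minimize(negD, x0, method="L-BFGS-B", bounds=list(region))
    x_opt = res.x if -res.fun >= D[best] else x0

    D_opt, d_opt = _overall_at(fits, spec, anchors, x_opt[None, :])
    individual = {
        f.response_name: float(d_opt[0, i]) for i, f in enumerate(fits)
    }
    predicted = {f.response_name: float(predict(f, x_opt)) for f in fits}
    actual = code_to_actual(design_spec, x_opt) if design_spec is not None else None
    return OptimumResult(
        coded=x_opt,
        actual=actual,
        overall=float(D_opt[0]),
        individual=individual,
        predicted=predicted,
    )


def desirability_grid(
    fits: Sequence[QuadraticFit],
    spec: DesirabilitySpec,
    resolution: int = 101,
) -> pd.DataFrame:
    """Overall and individual desirabilities on a dense coded grid.

    Long-format frame with one column per factor, ``D`` for the overall
    desirability and ``d_<response>`` per response; regions above a
    threshold (e.g. D > 0.8) can be extracted by boolean selection.
    """
    _check_fits(fits, spec)
    k = fits[0].k
    region = spec.region(k)
    pts = _grid_points(region, resolution)
    anchors = _resolve_anchors(fits, spec, pts)
    D, d = _overall_at(fits, spec, anchors, pts)
    out = {name: pts[:, i] for i, name in enumerate(fits[0].factor_names)}
    out["D"] = D
    for i, fit in enumerate(fits):
        out[f"d_{fit.response_name}"] = d[:, i]
    return pd.DataFrame(out)
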
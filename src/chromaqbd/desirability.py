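"""Derringer-Suich desirability scoring and multi-response optimization.

Each response is mapped to an individual desirability d in [0, 1] by a
ramp determined by its goal; the overall desirability D is the
importance-weighted geometric mean of the individual scores.  The
optimizer scans a regular grid over the factor ranges and optionally
polishes the best cell by coordinate descent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .designs import Factor
from .rsm import FittedModel, predict

__all__ = [
    "DesirabilityGoal",
    "individual_desirability",
    "overall_desirability",
    "optimize_desirability",
    "OptimizationResult",
]

_GOALS = ("maximize", "minimize", "in_range", "at_least", "at_most", "target")


@dataclass(frozen=True)
class DesirabilityGoal:
    """Optimization goal for one CMA.

    ``lower``/``upper`` bound the desirability ramp; for one-sided goals
    (at_least / at_most) the threshold is the nearer limit and the other
    limit is where d saturates at 1.  ``weight`` is the ramp exponent,
    ``importance`` the geometric-mean weight.
    """

    cma: str
    goal: str
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in _GOALS:
            raise ValueError(f"unknown goal {self.goal!r}; expected one of {_GOALS}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.cma}: lower must be < upper")
        if self.target is not None and not self.lower <= self.target <= self.upper:
            raise ValueError(f"{self.cma}: target outside [lower, upper]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.importance <= 0:
            raise ValueError("importance must be positive")


def individual_desirability(y, goal: DesirabilityGoal) -> np.ndarray:
    """Map response values to d in [0, 1] according to the goal's ramp."""
    y = np.asarray(y, dtype=float)
    lo, hi, w = goal.lower, goal.upper, goal.weight
    kind = goal.goal
    if kind in ("maximize", "at_least"):
        d = np.clip((y - lo) / (hi - lo), 0.0, 1.0) ** w
    elif kind in ("minimize", "at_most"):
        d = np.clip((hi - y) / (hi - lo), 0.0, 1.0) ** w
    elif kind == "in_range":
        d = ((y >= lo) & (y <= hi)).astype(float)
    else:  # target
        t = goal.target if goal.target is not None else (lo + hi) / 2.0
        left = np.clip((y - lo) / (t - lo), 0.0, 1.0) if t > lo else (y >= t).astype(float)
        right = np.clip((hi - y) / (hi - t), 0.0, 1.0) if t < hi else (y <= t).astype(float)
        d = np.where(y <= t, left, right) ** w
    return d


def overall_desirability(d, importance=None) -> float | np.ndarray:
    """Importance-weighted geometric mean D = (prod d_i^v_i)^(1/sum v_i).

    ``d`` is an array whose last axis indexes the CMAs; any d of 0 vetoes
    the point (D = 0).
    """
    d = np.asarray(d, dtype=float)
    v = np.ones(d.shape[-1]) if importance is None else np.asarray(importance, float)
    if np.any(v < 0):
        raise ValueError("importance weights must be non-negative")
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.maximum(d, 1e-300)), -np.inf)
        out = np.exp((logd * v).sum(axis=-1) / v.sum())
    out = np.where(np.isfinite(out), out, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class OptimizationResult:
    best: dict[str, float]
    D: float
    predictions: dict[str, float]
    grid_best: dict[str, float]
    grid_D: float


def _evaluate_D(
    models: dict[str, FittedModel],
    goals: list[DesirabilityGoal],
    points: pd.DataFrame,
) -> np.ndarray:
    d = np.empty((len(points), len(goals)))
    for j, g in enumerate(goals):
        d[:, j] = individual_desirability(predict(models[g.cma], points), g)
    return overall_desirability(d, [g.importance for g in goals])


def optimize_desirability(
    models: dict[str, FittedModel],
    goals: list[DesirabilityGoal],
    ranges: list[Factor],
    grid: int = 51,
    polish: bool = True,
    seed: int = 0,
) -> OptimizationResult:
    """Maximize overall desirability over the factor box.

    Exhaustively evaluates D on a ``grid``-point-per-factor lattice and
    (optionally) polishes the best cell by cyclic coordinate descent with
    bounded golden-section line searches (tolerance 1e-8 in coded units).
    Ties on the grid are broken by first-in-scan order; deterministic for
    a given grid.  An everywhere-zero D is reported, not raised.
    """
    missing = [g.cma for g in goals if g.cma not in models]
    if missing:
        raise KeyError(f"no fitted model for goal CMA(s): {missing}")
    if grid < 2:
        raise ValueError("grid must have at least 2 points per factor")

    axes = [np.linspace(f.low, f.high, grid) for f in ranges]
    names = [f.name for f in ranges]
    mesh = np.array(list(itertools.product(*axes)))
    pts = pd.DataFrame(mesh, columns=names)
    D = _evaluate_D(models, goals, pts)
    i_best = int(np.argmax(D))  # first max in scan order
    grid_best = dict(zip(names, mesh[i_best]))
    grid_D = float(D[i_best])

    best = dict(grid_best)
    best_D = grid_D
    if polish and grid_D > 0:
        x = np.array([grid_best[n] for n in names])
        tol = 1e-8
        for _ in range(200):
            moved = 0.0
            for j, f in enumerate(ranges):
                def neg(v, j=j):
                    xx = x.copy()
                    xx[j] = v
                    return -_evaluate_D(
                        models, goals, pd.DataFrame([xx], columns=names)
                    )[0]

                res = minimize_scalar(
                    neg,
                    bounds=(f.low, f.high),
                    method="bounded",
                    options={"xatol": tol * f.half_range},
                )
                if -res.fun > best_D + 1e-15:
                    moved = max(moved, abs(res.x - x[j]) / f.half_range)
                    x[j] = res.x
                    best_D = -res.fun
            if moved < tol:
                break
        best = dict(zip(names, x))

    preds = {
        g.cma: float(predict(models[g.cma], pd.DataFrame([best]))[0]) for g in goals
    }
    return OptimizationResult(
        best=best, D=float(best_D), predictions=preds,
        grid_best=grid_best, grid_D=grid_D,
    )
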
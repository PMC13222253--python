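"""Calibration: recover unpublished transition inputs from lifetime targets.

The published analysis reports lifetime discounted costs and QALYs per
strategy but not the transition probabilities behind them. This stage fits
chosen free parameters (typically remission entry and relapse per
strategy, optionally a mortality hazard ratio) so that the model's
lifetime outputs match a set of targets, minimising the weighted squared
*relative* error — scale-free, so US$ and QALY targets mix cleanly:

    objective(x) = sum_j w_j * ((model_j(x) - target_j) / target_j) ** 2

Optimisation is a coarse grid scan followed by Nelder-Mead simplex
refinement (bounds enforced by clamping with a quadratic penalty) and a
bounded least-squares polish of the residual vector for the final digits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .economics import run_strategy
from .errors import CalibrationFailure, ValidationError
from .parameters import ParameterBundle, with_params
from .states import Perspective

__all__ = ["CalibrationTarget", "CalibrationResult", "calibrate",
           "profile_objective", "targets_from_bundle", "read_targets_csv"]

QUANTITIES = ("total_cost", "total_qaly")


@dataclass(frozen=True)
class CalibrationTarget:
    """One lifetime quantity the fitted model should reproduce."""

    quantity: str  # "total_cost" or "total_qaly"
    strategy: str
    perspective: Perspective
    value: float
    weight: float = 1.0

    def __post_init__(self):
        if self.quantity not in QUANTITIES:
            raise ValidationError(f"quantity must be one of {QUANTITIES}",
                                  field="targets.quantity")
        if self.weight < 0:
            raise ValidationError("weight must be >= 0", field="targets.weight")
        if self.value == 0:
            raise ValidationError("target value must be nonzero for the "
                                  "relative-error objective", field="targets.value")


@dataclass
class CalibrationResult:
    params: dict[str, float]
    objective: float
    converged: bool
    iterations: int
    residuals: dict[tuple[str, str, str], float]  # (quantity, strategy, persp)
    n_evaluations: int = 0
    grid_best: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "objective": self.objective,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_evaluations": self.n_evaluations,
            "residuals": {"/".join(k): v for k, v in self.residuals.items()},
        }


def _model_quantities(bundle: ParameterBundle,
                      targets: list[CalibrationTarget]) -> dict:
    """Model values for every (strategy, perspective, quantity) a target needs."""
    needed = {(t.strategy, t.perspective) for t in targets}
    values = {}
    for strategy, persp in needed:
        out = run_strategy(bundle, strategy, persp)
        values[("total_cost", strategy, persp)] = out.total_cost
        values[("total_qaly", strategy, persp)] = out.total_qaly
    return values


def _residual_vector(bundle: ParameterBundle, paths: list[str],
                     x: np.ndarray, targets: list[CalibrationTarget],
                     ) -> np.ndarray:
    b = with_params(bundle, dict(zip(paths, x)))
    b.validate()
    values = _model_quantities(b, targets)
    res = []
    for t in targets:
        model = values[(t.quantity, t.strategy, t.perspective)]
        res.append(np.sqrt(t.weight) * (model - t.value) / t.value)
    return np.asarray(res)


def _check_targets(targets: list[CalibrationTarget], n_free: int) -> None:
    if not targets:
        raise ValidationError("no calibration targets", field="targets")
    if all(t.weight == 0 for t in targets):
        raise ValidationError("all target weights are zero", field="targets.weight")
    if sum(1 for t in targets if t.weight > 0) < n_free:
        raise ValidationError(
            "need at least as many (positively weighted) targets as free "
            "parameters", field="targets")


def calibrate(bundle: ParameterBundle,
              free_params: list[tuple[str, float, float]],
              targets: list[CalibrationTarget],
              grid_points: int = 11,
              max_grid_evals: int = 20000,
              xatol: float = 1e-9, fatol: float = 1e-16,
              maxiter: int = 4000,
              polish: bool = True) -> CalibrationResult:
    """Fit ``free_params`` (list of ``(path, low, high)``) to ``targets``.

    Deterministic: the grid scan, simplex refinement and least-squares
    polish involve no randomness. Returns the best point found with
    convergence diagnostics and per-target relative residuals.
    """
    paths = [p for p, _, _ in free_params]
    lo = np.array([l for _, l, _ in free_params], dtype=float)
    hi = np.array([h for _, _, h in free_params], dtype=float)
    if np.any(lo > hi):
        raise ValidationError("lower bound exceeds upper bound",
                              field="free_params")
    _check_targets(targets, len(paths))

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        xc = np.clip(x, lo, hi)
        penalty = float(np.sum((x - xc) ** 2)) * 1e3
        try:
            r = _residual_vector(bundle, paths, xc, targets)
        except Exception:
            return np.inf
        return float(np.dot(r, r)) + penalty

    # coarse grid seed (points per dimension shrunk to respect the eval cap)
    d = len(paths)
    pts = grid_points
    while pts > 2 and pts ** d > max_grid_evals:
        pts -= 1
    axes = [np.linspace(l, h, pts) if h > l else np.array([l])
            for l, h in zip(lo, hi)]
    best_x, best_f = None, np.inf
    for combo in itertools.product(*axes):
        f = objective(np.asarray(combo))
        if f < best_f:
            best_x, best_f = np.asarray(combo), f
    if best_x is None or not np.isfinite(best_f):
        raise CalibrationFailure(
            "objective non-finite at every grid point "
            f"({pts} points per dimension over {d} dimensions)")
    grid_best = dict(zip(paths, (float(v) for v in best_x)))

    res = optimize.minimize(
        objective, best_x, method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter,
                 "maxfev": maxiter})
    x = np.clip(res.x, lo, hi)
    f = objective(x)
    iterations = int(res.nit)
    converged = bool(res.success)

    if polish and np.isfinite(f):
        try:
            ls = optimize.least_squares(
                lambda v: _residual_vector(bundle, paths, v, targets),
                x, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=200 * max(d, 1))
            if 2 * ls.cost <= f:  # keep only if it improved
                x, f = ls.x, float(2 * ls.cost)
                converged = converged or ls.status > 0
        except Exception:
            pass

    r = _residual_vector(bundle, paths, x, targets)
    residuals = {(t.quantity, t.strategy, t.perspective.value): float(ri)
                 for t, ri in zip(targets, r)}
    return CalibrationResult(
        params=dict(zip(paths, (float(v) for v in x))),
        objective=float(np.dot(r, r)), converged=converged,
        iterations=iterations, residuals=residuals,
        n_evaluations=n_eval, grid_best=grid_best)


def profile_objective(bundle: ParameterBundle, path: str, grid,
                      targets: list[CalibrationTarget],
                      ) -> list[tuple[float, float]]:
    """Objective along one parameter's grid, everything else held fixed."""
    grid = list(grid)
    if not grid:
        raise ValidationError("empty profile grid", field=path)
    _check_targets(targets, 1)
    out = []
    for v in grid:
        try:
            r = _residual_vector(bundle, [path], np.array([float(v)]), targets)
            out.append((float(v), float(np.dot(r, r))))
        except Exception:
            out.append((float(v), float("inf")))
    return out


def targets_from_bundle(bundle: ParameterBundle,
                        strategies=None,
                        perspective: Perspective | None = None,
                        weight: float = 1.0) -> list[CalibrationTarget]:
    """Noiseless targets generated from a bundle's own lifetime outputs.

    Used by the simulate-then-recover tests and as a convenience for
    constructing synthetic calibration problems.
    """
    persp = Perspective(perspective or bundle.config.perspective)
    out = []
    for sid in (strategies or bundle.strategies):
        o = run_strategy(bundle, sid, persp)
        out.append(CalibrationTarget("total_cost", sid, persp, o.total_cost, weight))
        out.append(CalibrationTarget("total_qaly", sid, persp, o.total_qaly, weight))
    return out


def read_targets_csv(path) -> list[CalibrationTarget]:
    """Targets from CSV with columns quantity,strategy,perspective,value,weight."""
    df = pd.read_csv(path)
    needed = {"quantity", "strategy", "perspective", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"targets file missing columns {sorted(missing)}",
                              field="targets.path")
    out = []
    for _, row in df.iterrows():
        out.append(CalibrationTarget(
            quantity=str(row["quantity"]), strategy=str(row["strategy"]),
            perspective=Perspective(str(row["perspective"])),
            value=float(row["value"]),
            weight=float(row.get("weight", 1.0)) if "weight" in df.columns else 1.0))
    return out
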
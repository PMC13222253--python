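"""Probabilistic sensitivity analysis.

Second-order parameter uncertainty is expressed with method-of-moments
Beta distributions for quantities bounded in [0, 1] (probabilities,
utilities) and Gamma distributions for non-negative quantities (costs).
Each draw resamples every uncertain parameter independently, rebuilds the
bundle, runs both strategies, and records the incremental cost and QALY;
the draws feed the cost-effectiveness acceptability curve (CEAC) and the
cost-effectiveness plane scatter.

Seed management: one master seed; the child seed for draw ``i`` is derived
as ``numpy.random.SeedSequence([master_seed, i])``, so any single draw can
be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import evaluate
from .errors import InfeasibleMomentsError, ValidationError
from .parameters import ParameterBundle, with_params
from .states import Perspective

__all__ = ["DistributionSpec", "fit_beta_moments", "fit_gamma_moments",
           "PsaRun", "run_psa", "ceac"]


def fit_beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) matching a given mean and standard error.

    alpha = mean * nu, beta = (1 - mean) * nu with
    nu = mean * (1 - mean) / se**2 - 1. Requires se**2 < mean * (1 - mean).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise InfeasibleMomentsError(f"standard error must be positive, got {se}")
    var = se * se
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise InfeasibleMomentsError(
            f"variance {var:.6g} >= mean*(1-mean) = {bound:.6g}: "
            "no beta distribution has these moments")
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, scale) matching a given mean and standard error.

    shape = mean**2 / se**2, scale = se**2 / mean.
    """
    if mean <= 0 or se <= 0:
        raise InfeasibleMomentsError(
            f"gamma moments must be positive, got mean={mean}, se={se}")
    return mean * mean / (se * se), se * se / mean


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty assigned to one dot-path parameter."""

    path: str
    family: str  # "beta", "gamma" or "fixed"
    mean: float
    se: float

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"unknown family {self.family!r}",
                                  field=self.path)

    def shape_params(self) -> tuple[float, float] | None:
        """Derived distribution parameters ((alpha, beta) or (shape, scale))."""
        if self.family == "beta":
            return fit_beta_moments(self.mean, self.se)
        if self.family == "gamma":
            return fit_gamma_moments(self.mean, self.se)
        return None

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        a, b = self.shape_params()
        if self.family == "beta":
            return float(rng.beta(a, b))
        return float(rng.gamma(a, b))


@dataclass
class PsaRun:
    """Result container for one PSA run."""

    n_iterations: int
    seed: int
    records: pd.DataFrame  # draw, delta_cost, delta_qaly
    params: pd.DataFrame  # one column per sampled parameter
    n_resampled: int = 0
    wtp_grid: tuple[float, ...] = field(default_factory=tuple)

    def mean_increment(self) -> tuple[float, float]:
        return (float(self.records["delta_cost"].mean()),
                float(self.records["delta_qaly"].mean()))


def run_psa(bundle: ParameterBundle, specs: list[DistributionSpec],
            n_iterations: int = 1000, seed: int | None = None,
            perspective: Perspective | None = None,
            max_resamples_per_draw: int = 100) -> PsaRun:
    """Monte-Carlo parameter uncertainty analysis.

    Per draw: sample every spec independently, rebuild the bundle, evaluate
    both strategies, record (delta cost, delta QALY). A draw whose sampled
    bundle fails validation (e.g. a composed exit probability leaving
    [0, 1]) is resampled with a fresh child seed; the resample count is
    reported on the result.

    Deterministic for fixed ``seed`` (defaults to the bundle's master seed).
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1", field="psa.n_iterations")
    master = int(bundle.config.master_seed if seed is None else seed)
    recs = []
    pars = []
    n_resampled = 0
    for i in range(n_iterations):
        for attempt in range(max_resamples_per_draw):
            child = np.random.default_rng(
                np.random.SeedSequence([master, i, attempt]))
            draw = {s.path: s.sample(child) for s in specs}
            try:
                b = with_params(bundle, draw)
                b.validate()
                result = evaluate(b, perspective)
            except Exception:
                n_resampled += 1
                continue
            recs.append((i, result.delta_cost, result.delta_qaly))
            pars.append(draw)
            break
        else:
            raise ValidationError(
                f"draw {i} failed validation {max_resamples_per_draw} times",
                field="psa")
    records = pd.DataFrame(recs, columns=["draw", "delta_cost", "delta_qaly"])
    params = pd.DataFrame(pars)
    return PsaRun(n_iterations=n_iterations, seed=master, records=records,
                  params=params, n_resampled=n_resampled,
                  wtp_grid=bundle.config.wtp_thresholds)


def ceac(records: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    The probability at threshold ``lam`` is the fraction of draws with
    positive incremental net monetary benefit, ``lam * dE - dC > 0``.
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValidationError("empty WTP grid", field="ceac.wtp_grid")
    if len(records) == 0:
        raise ValidationError("no PSA records", field="ceac.records")
    de = records["delta_qaly"].to_numpy()
    dc = records["delta_cost"].to_numpy()
    prob = [(lam * de - dc > 0).mean() for lam in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})
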
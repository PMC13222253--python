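"""High-level modelling interface.

:class:`CostUtilityModel` is the front door of the package, in the spirit
of the estimator/results split used by statistical modelling libraries: a
model object is built from a parameter bundle (base case, config file, or
programmatically), ``run()`` returns a :class:`CEAResults` carrying the
strategy outcomes, the incremental comparison and a summary table, and
``fit()`` calibrates free parameters to lifetime targets and returns a
:class:`CalibrationResults` from which the calibrated model can be taken.

Example
-------
>>> from remarkov import CostUtilityModel
>>> model = CostUtilityModel.base_case("SUT")
>>> res = model.run()
>>> print(res.summary())              # doctest: +SKIP
>>> res.result.icer                   # US$/QALY, full precision
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calibration as _cal
from . import dsa as _dsa
from . import psa as _psa
from .economics import CEResult, StrategyOutcome, run_strategy, compare
from .engine import CohortTrace, run_cohort, run_microsim, MicrosimResult
from .parameters import ParameterBundle
from .states import Perspective

__all__ = ["CostUtilityModel", "CEAResults", "CalibrationResults"]


@dataclass
class CEAResults:
    """Results of one deterministic cost-utility evaluation."""

    outcomes: dict[str, StrategyOutcome]
    result: CEResult
    traces: dict[str, CohortTrace]
    perspective: Perspective
    cohort_size: int = 1000

    def to_frame(self) -> pd.DataFrame:
        """Per-strategy table mirroring a standard CEA results layout."""
        comp, intv = self.result.comparator, self.result.intervention
        rows = []
        for sid in (comp, intv):
            o = self.outcomes[sid]
            rows.append({
                "strategy": sid,
                "total_cost": o.total_cost,
                "incremental_cost": self.result.delta_cost if sid == intv else None,
                "total_qalys": o.total_qaly,
                "incremental_qalys": self.result.delta_qaly if sid == intv else None,
                "cost_per_qaly": o.total_cost / o.total_qaly,
                "icer": self.result.icer if sid == intv else None,
            })
        return pd.DataFrame(rows)

    def ce_plane_frame(self) -> pd.DataFrame:
        """Incremental (delta_qaly, delta_cost) point(s) for the CE plane."""
        return pd.DataFrame([{"intervention": self.result.intervention,
                              "comparator": self.result.comparator,
                              "delta_qaly": self.result.delta_qaly,
                              "delta_cost": self.result.delta_cost}])

    def summary(self) -> str:
        r = self.result
        lines = [
            "Cost-utility analysis"
            f" — perspective {self.perspective.value},"
            f" {r.intervention} vs {r.comparator}",
            "=" * 72,
        ]
        df = self.to_frame().copy()
        for col in ("total_cost", "incremental_cost", "cost_per_qaly", "icer"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:,.2f}")
        for col in ("total_qalys", "incremental_qalys"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        lines.append(df.to_string(index=False))
        lines.append("-" * 72)
        lines.append(f"ICER: {r.icer_display(0)} US$/QALY"
                     f"   dominance: {r.dominance}")
        for lam, v in r.incremental_nmb.items():
            dec = "cost-effective" if v > 0 else "not cost-effective"
            lines.append(f"incremental NMB at WTP {lam:>10,.0f}: "
                         f"{v:>14,.2f} US$  ({dec})")
        lines.append(f"(per-patient values; cohort of {self.cohort_size:,} "
                     "scales report aggregates only)")
        return "\n".join(lines)


@dataclass
class CalibrationResults:
    """Calibration outcome plus the calibrated model."""

    result: _cal.CalibrationResult
    model: "CostUtilityModel"
    targets: list[_cal.CalibrationTarget] = field(default_factory=list)

    def summary(self) -> str:
        r = self.result
        lines = ["Calibration to lifetime targets", "=" * 48]
        for path, v in r.params.items():
            lines.append(f"  {path:<40s} {v:.6f}")
        lines.append(f"objective (weighted squared relative error): {r.objective:.3e}")
        lines.append(f"converged: {r.converged}   simplex iterations: {r.iterations}"
                     f"   model evaluations: {r.n_evaluations}")
        for key, res in r.residuals.items():
            lines.append(f"  residual {'/'.join(key):<32s} {res:+.4%}")
        return "\n".join(lines)


class CostUtilityModel:
    """Three-state Markov cohort cost-utility model of T2DM remission.

    Parameters
    ----------
    bundle
        A validated :class:`~remarkov.parameters.ParameterBundle`. Use
        :meth:`base_case` for the published 2023 Turkish inputs or
        :meth:`from_config` to load a YAML run configuration.
    """

    def __init__(self, bundle: ParameterBundle):
        bundle.validate()
        self.bundle = bundle

    # ------------------------------------------------------------ constructors
    @classmethod
    def base_case(cls, perspective: Perspective | str = Perspective.SUT,
                  life_table=None) -> "CostUtilityModel":
        from .basecase import base_case_bundle
        return cls(base_case_bundle(perspective, life_table=life_table))

    @classmethod
    def from_config(cls, path: str | Path) -> "CostUtilityModel":
        from .config_io import load_config
        return cls(load_config(path))

    # ------------------------------------------------------------- evaluation
    def run(self, perspective: Perspective | str | None = None,
            comparator: str = "PT", intervention: str = "SG") -> CEAResults:
        """Deterministic cohort evaluation of both strategies."""
        persp = Perspective(perspective or self.bundle.config.perspective)
        outcomes = {}
        traces = {}
        for sid in (comparator, intervention):
            traces[sid] = run_cohort(self.bundle.transitions[sid],
                                     self.bundle.life_table,
                                     self.bundle.config, strategy=sid)
            from .economics import accrue
            outcomes[sid] = accrue(traces[sid], self.bundle.schedule(sid, persp),
                                   self.bundle.utilities, self.bundle.config)
        result = compare(outcomes[comparator], outcomes[intervention],
                         wtp=self.bundle.config.wtp_thresholds)
        return CEAResults(outcomes=outcomes, result=result, traces=traces,
                          perspective=persp,
                          cohort_size=self.bundle.config.cohort_size)

    def microsimulate(self, strategy: str, n_individuals: int = 1000,
                      seed: int | None = None,
                      perspective: Perspective | str | None = None,
                      ) -> MicrosimResult:
        """Individual-level simulation of one strategy (first-order noise)."""
        persp = Perspective(perspective or self.bundle.config.perspective)
        return run_microsim(
            self.bundle.transitions[strategy], self.bundle.life_table,
            self.bundle.config, self.bundle.schedule(strategy, persp),
            self.bundle.utilities, n_individuals,
            self.bundle.config.master_seed if seed is None else seed)

    # ------------------------------------------------------------ calibration
    def fit(self, targets: list[_cal.CalibrationTarget],
            free_params: list[tuple[str, float, float]] | None = None,
            **settings) -> CalibrationResults:
        """Calibrate free parameters to lifetime (cost, QALY) targets.

        By default the four strategy transition probabilities are fitted
        over their plausible boxes; pass ``free_params`` as a list of
        ``(dot_path, low, high)`` to change that.
        """
        if free_params is None:
            free_params = [(f"transitions.{sid}.{name}", 0.0, 0.6 if
                            name == "p_remission" else 0.15)
                           for sid in self.bundle.strategies
                           for name in ("p_remission", "p_relapse")]
        result = _cal.calibrate(self.bundle, free_params, targets, **settings)
        from .parameters import with_params
        fitted = with_params(self.bundle, result.params)
        return CalibrationResults(result=result,
                                  model=CostUtilityModel(fitted),
                                  targets=list(targets))

    # ------------------------------------------------------ sensitivity layers
    def one_way(self, ranges: list[_dsa.ParamRange] | None = None,
                metric: str = "inmb", wtp: float = 39330.0,
                perspective: Perspective | str | None = None):
        persp = Perspective(perspective or self.bundle.config.perspective)
        if ranges is None:
            ranges = _dsa.default_ranges(self.bundle, perspective=persp)
        return _dsa.one_way(self.bundle, ranges, metric=metric, wtp=wtp,
                            perspective=persp)

    def scenario(self, overrides: dict[str, float],
                 perspective: Perspective | str | None = None) -> CEResult:
        return _dsa.scenario(self.bundle, overrides,
                             Perspective(perspective
                                         or self.bundle.config.perspective))

    def best_worst(self, ranges: list[_dsa.ParamRange] | None = None,
                   wtp: float = 39330.0,
                   perspective: Perspective | str | None = None):
        persp = Perspective(perspective or self.bundle.config.perspective)
        if ranges is None:
            ranges = _dsa.default_ranges(self.bundle, perspective=persp)
        return _dsa.best_worst(self.bundle, ranges, wtp=wtp, perspective=persp)

    def psa(self, specs: list[_psa.DistributionSpec] | None = None,
            n_iterations: int = 1000, seed: int | None = None,
            perspective: Perspective | str | None = None) -> _psa.PsaRun:
        """Probabilistic sensitivity analysis (default fixture: 10% SEs)."""
        persp = Perspective(perspective or self.bundle.config.perspective)
        if specs is None:
            from .synthetic import make_psa_fixture
            specs = make_psa_fixture(self.bundle)
        return _psa.run_psa(self.bundle, specs, n_iterations=n_iterations,
                            seed=seed, perspective=persp)
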
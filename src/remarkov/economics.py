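"""Economic evaluation: discounted accrual, ICER, net monetary benefit.

Accrual convention
------------------
The reward for cycle ``t`` is paid on the occupancy *after* the cycle-``t``
transition (trace row ``t``): members must survive a cycle to accrue its
annual cost and utility. With the two-cycle remission lockout this means
remission utility is first earned in cycle 3, i.e. after two full years of
treatment. The discount factor for cycle ``t`` is ``(1 + r) ** -(t - 1)``
under the default first-cycle-undiscounted convention, or
``(1 + r) ** -t`` under the end-of-cycle convention. An optional
half-cycle correction halves the first and last cycle weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CohortTrace, run_cohort
from .errors import ValidationError
from .parameters import (
    FIRST_CYCLE_UNDISCOUNTED,
    END_OF_CYCLE,
    CostSchedule,
    ModelConfig,
    ParameterBundle,
    UtilitySet,
)
from .states import STATE_INDEX, HealthState, Perspective

__all__ = ["discount_factor", "accrue", "compare", "threshold_defaults",
           "StrategyOutcome", "CEResult", "run_strategy", "evaluate"]

ICER_UNDEFINED = "undefined (zero QALY difference)"


def discount_factor(rate: float, cycle: int,
                    timing: str = FIRST_CYCLE_UNDISCOUNTED) -> float:
    """Discount factor applied to the accrual of 1-based ``cycle``."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0", field="discount_rate")
    if cycle < 1:
        raise ValidationError("cycle must be >= 1", field="cycle")
    if timing == FIRST_CYCLE_UNDISCOUNTED:
        exponent = cycle - 1
    elif timing == END_OF_CYCLE:
        exponent = cycle
    else:
        raise ValidationError(f"unknown discount timing {timing!r}",
                              field="discount_timing")
    return float((1.0 + rate) ** -exponent)


@dataclass
class StrategyOutcome:
    """Discounted lifetime cost and QALY per patient for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    per_cycle: pd.DataFrame  # cycle, cost, qaly (undiscounted), discount factor
    perspective: Perspective | None = None

    def undiscounted(self) -> tuple[float, float]:
        w = self.per_cycle["weight"].to_numpy()
        return (float((self.per_cycle["cost"] * w).sum()),
                float((self.per_cycle["qaly"] * w).sum()))


def accrue(trace: CohortTrace, schedule: CostSchedule, utilities: UtilitySet,
           config: ModelConfig) -> StrategyOutcome:
    """Fold a cohort trace into discounted lifetime cost and QALYs.

    cycle-t cost  = sum over states of occupancy(t, state) x annual cost
    cycle-t QALY  = sum over states of occupancy(t, state) x utility x cycle length
    totals        = sum over cycles of accrual x weight x discount factor
    """
    horizon = config.horizon
    if trace.n_cycles != horizon:
        raise ValidationError(
            f"trace has {trace.n_cycles} cycles but config.horizon={horizon}",
            field="run.horizon")
    u_vec = utilities.as_vector()
    rows = []
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, horizon + 1):
        occ = trace.occupancy[t]
        c_vec = np.array([schedule.cycle_cost(HealthState.T2DM, t),
                          schedule.cycle_cost(HealthState.REMISSION, t), 0.0])
        cost_t = float(occ @ c_vec)
        qaly_t = float(occ @ u_vec) * config.cycle_length
        df = discount_factor(config.discount_rate, t, config.discount_timing)
        w = 1.0
        if config.half_cycle_correction and t in (1, horizon):
            w = 0.5
        total_cost += w * cost_t * df
        total_qaly += w * qaly_t * df
        rows.append((t, cost_t, qaly_t, df, w))
    per_cycle = pd.DataFrame(rows, columns=["cycle", "cost", "qaly",
                                            "discount_factor", "weight"])
    return StrategyOutcome(strategy=trace.strategy or schedule.strategy,
                           total_cost=total_cost, total_qaly=total_qaly,
                           per_cycle=per_cycle,
                           perspective=Perspective(schedule.perspective))


@dataclass
class CEResult:
    """Incremental comparison of an intervention against a comparator."""

    comparator: str
    intervention: str
    delta_cost: float
    delta_qaly: float
    icer: float | None  # None when delta_qaly == 0
    nmb: dict[float, dict[str, float]]  # wtp -> strategy -> lambda*E - C
    incremental_nmb: dict[float, float]  # wtp -> lambda*dE - dC
    dominance: str
    comparator_outcome: StrategyOutcome | None = field(default=None, repr=False)
    intervention_outcome: StrategyOutcome | None = field(default=None, repr=False)

    def icer_display(self, ndigits: int = 0) -> str:
        if self.icer is None:
            return ICER_UNDEFINED
        return f"{round(self.icer, ndigits):,.{ndigits}f}"


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly >= 0 and delta_cost <= 0 and (delta_qaly > 0 or delta_cost < 0):
        return "intervention dominant"
    if delta_qaly <= 0 and delta_cost >= 0 and (delta_qaly < 0 or delta_cost > 0):
        return "comparator dominant"
    if delta_qaly > 0 and delta_cost > 0:
        return "trade-off NE quadrant"
    if delta_qaly < 0 and delta_cost < 0:
        return "trade-off SW quadrant"
    return "equivalent"


def compare(comparator: StrategyOutcome, intervention: StrategyOutcome,
            wtp: tuple[float, ...] = (10994.0, 39330.0)) -> CEResult:
    """ICER, per-strategy NMB and dominance for intervention vs comparator.

    The ICER is the difference in total costs divided by the difference in
    QALYs; it is left undefined (``None``) when the QALY difference is
    exactly zero, in which case the NMB comparison still applies.
    """
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    icer = None if d_qaly == 0 else d_cost / d_qaly
    nmb = {}
    inmb = {}
    for lam in wtp:
        lam = float(lam)
        nmb[lam] = {
            comparator.strategy: lam * comparator.total_qaly - comparator.total_cost,
            intervention.strategy: (lam * intervention.total_qaly
                                    - intervention.total_cost),
        }
        inmb[lam] = lam * d_qaly - d_cost
    return CEResult(comparator=comparator.strategy,
                    intervention=intervention.strategy,
                    delta_cost=d_cost, delta_qaly=d_qaly, icer=icer,
                    nmb=nmb, incremental_nmb=inmb,
                    dominance=_dominance(d_cost, d_qaly),
                    comparator_outcome=comparator,
                    intervention_outcome=intervention)


def threshold_defaults(gdp_per_capita: float) -> tuple[float, float]:
    """WTP thresholds at 1x and 3x GDP per capita (US$/QALY)."""
    if gdp_per_capita <= 0:
        raise ValidationError("GDP per capita must be positive",
                              field="gdp_per_capita")
    return (float(gdp_per_capita), 3.0 * float(gdp_per_capita))


def run_strategy(bundle: ParameterBundle, strategy: str,
                 perspective: Perspective | None = None) -> StrategyOutcome:
    """Cohort trace + accrual for one strategy of a bundle."""
    trace = run_cohort(bundle.transitions[strategy], bundle.life_table,
                       bundle.config, strategy=strategy)
    sched = bundle.schedule(strategy, perspective)
    return accrue(trace, sched, bundle.utilities, bundle.config)


def evaluate(bundle: ParameterBundle,
             perspective: Perspective | None = None,
             comparator: str = "PT", intervention: str = "SG") -> CEResult:
    """Full base-case comparison of two strategies of a bundle."""
    out_c = run_strategy(bundle, comparator, perspective)
    out_i = run_strategy(bundle, intervention, perspective)
    return compare(out_c, out_i, wtp=bundle.config.wtp_thresholds)
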
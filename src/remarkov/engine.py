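"""Markov engine: transition matrices, cohort trace, microsimulation.

State transitions are composed *death-first* within each annual cycle: the
background death probability for the attained age (times the state's
hazard-ratio multiplier, capped at 1) is applied before the surviving mass
is split between staying and moving between the live states. This keeps
every row an exact probability distribution without renormalisation.

Remission entry is blocked during the treatment lockout (default: the
first two cycles), so the earliest possible remission occupancy is the
trace row after cycle ``lockout_cycles + 1``. The attained age during
cycle ``t`` is ``start_age + t - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import LifeTable, ModelConfig, TransitionParams
from .states import STATE_INDEX, STATE_ORDER, HealthState

__all__ = ["TransitionMatrixError", "transition_matrix", "run_cohort",
           "CohortTrace", "run_microsim", "MicrosimResult"]

_I_T2DM = STATE_INDEX[HealthState.T2DM]
_I_REM = STATE_INDEX[HealthState.REMISSION]
_I_DEAD = STATE_INDEX[HealthState.DEAD]


class TransitionMatrixError(ValueError):
    pass


def transition_matrix(params: TransitionParams, cycle: int, age: int,
                      life_table: LifeTable) -> np.ndarray:
    """The 3x3 transition matrix for one cycle at one attained age.

    Parameters
    ----------
    params
        Strategy transition inputs. ``p_periop_death`` (if any) applies in
        cycle 1 only, composed before the background death probability.
    cycle
        1-based model cycle.
    age
        Attained age during the cycle; must be covered by ``life_table``.

    Returns
    -------
    ndarray of shape (3, 3) indexed (from-state, to-state) in the order
    T2DM, REMISSION, DEAD. Rows sum to 1 exactly (up to float rounding);
    the DEAD row is the unit vector on DEAD.
    """
    if cycle < 1:
        raise TransitionMatrixError(f"cycle must be >= 1, got {cycle}")
    qx = life_table.qx_at(age)

    q_t2dm = min(qx * params.mortality_hr_t2dm, 1.0)
    q_rem = min(qx * params.mortality_hr_remission, 1.0)
    if cycle == 1 and params.p_periop_death > 0:
        # operative mortality composes with background mortality
        q_t2dm = 1.0 - (1.0 - params.p_periop_death) * (1.0 - q_t2dm)

    p_rem = params.p_remission if cycle > params.lockout_cycles else 0.0
    p_rel = params.p_relapse

    m = np.zeros((3, 3))
    m[_I_T2DM, _I_DEAD] = q_t2dm
    m[_I_T2DM, _I_REM] = (1.0 - q_t2dm) * p_rem
    m[_I_T2DM, _I_T2DM] = (1.0 - q_t2dm) * (1.0 - p_rem)
    m[_I_REM, _I_DEAD] = q_rem
    m[_I_REM, _I_T2DM] = (1.0 - q_rem) * p_rel
    m[_I_REM, _I_REM] = (1.0 - q_rem) * (1.0 - p_rel)
    m[_I_DEAD, _I_DEAD] = 1.0
    return m


@dataclass
class CohortTrace:
    """Occupancy proportions over the horizon.

    ``occupancy`` has ``horizon + 1`` rows; row 0 is the initial
    distribution (everyone in T2DM) and row ``t`` the distribution after
    cycle ``t``. ``ages[t]`` is the attained age during cycle ``t``
    (``start_age`` for row 0).
    """

    occupancy: np.ndarray
    ages: np.ndarray
    strategy: str = ""

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.occupancy.shape[0]),
            "age": self.ages,
            "prop_t2dm": self.occupancy[:, _I_T2DM],
            "prop_remission": self.occupancy[:, _I_REM],
            "prop_dead": self.occupancy[:, _I_DEAD],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(params: TransitionParams, life_table: LifeTable,
               config: ModelConfig, strategy: str = "") -> CohortTrace:
    """Propagate the cohort deterministically over the full horizon.

    Row ``t`` is row ``t - 1`` right-multiplied by the cycle-``t``
    transition matrix. The result is the exact expectation of the
    individual-level process simulated by :func:`run_microsim`.
    """
    horizon = config.horizon
    occ = np.zeros((horizon + 1, 3))
    occ[0, _I_T2DM] = 1.0
    ages = np.empty(horizon + 1, dtype=int)
    ages[0] = config.start_age
    for t in range(1, horizon + 1):
        age = config.start_age + t - 1
        ages[t] = age
        m = transition_matrix(params, t, age, life_table)
        occ[t] = occ[t - 1] @ m
    return CohortTrace(occupancy=occ, ages=ages, strategy=strategy)


@dataclass
class MicrosimResult:
    """Individual-level simulation output.

    ``paths`` is an ``(n_individuals, horizon + 1)`` int8 array of state
    indices (T2DM=0, REMISSION=1, DEAD=2). Summary statistics are means
    over individuals with Monte-Carlo standard errors; cost/QALY use the
    same accrual and discounting conventions as the cohort expectation
    (state after each cycle's transition, annual discounting).
    """

    paths: np.ndarray
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_life_years: float
    se_life_years: float
    seed: int


def run_microsim(params: TransitionParams, life_table: LifeTable,
                 config: ModelConfig, schedule, utilities,
                 n_individuals: int, seed: int) -> MicrosimResult:
    """Simulate individual state paths from the same per-cycle transition rows.

    Each individual draws its next state from the categorical distribution
    given by its current row of the cycle's transition matrix. For fixed
    ``seed`` the paths are exactly reproducible.
    """
    from .economics import discount_factor  # avoid import cycle at module load

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    horizon = config.horizon
    n = n_individuals

    paths = np.zeros((n, horizon + 1), dtype=np.int8)  # all start in T2DM
    cost = np.zeros(n)
    qaly = np.zeros(n)
    life_years = np.zeros(n)
    u_vec = utilities.as_vector()

    weights = np.ones(horizon)
    if config.half_cycle_correction:
        weights[0] = 0.5
        weights[-1] = 0.5

    for t in range(1, horizon + 1):
        age = config.start_age + t - 1
        m = transition_matrix(params, t, age, life_table)
        cum = np.cumsum(m, axis=1)
        state = paths[:, t - 1]
        u = rng.random(n)
        new = state.copy()
        for s in (_I_T2DM, _I_REM):
            sel = state == s
            if sel.any():
                new[sel] = np.searchsorted(cum[s], u[sel], side="right")
        new[state == _I_DEAD] = _I_DEAD
        np.clip(new, 0, 2, out=new)
        paths[:, t] = new

        df = discount_factor(config.discount_rate, t, config.discount_timing)
        c_vec = np.array([schedule.cycle_cost(HealthState.T2DM, t),
                          schedule.cycle_cost(HealthState.REMISSION, t), 0.0])
        w = weights[t - 1]
        cost += w * df * c_vec[new]
        qaly += w * df * u_vec[new] * config.cycle_length
        life_years += (new != _I_DEAD) * config.cycle_length

    def mse(x):
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    mc, sc = mse(cost)
    mq, sq = mse(qaly)
    ml, sl = mse(life_years)
    return MicrosimResult(paths=paths, mean_cost=mc, se_cost=sc,
                         mean_qaly=mq, se_qaly=sq,
                         mean_life_years=ml, se_life_years=sl, seed=seed)
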
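"""Parameter containers: costs, utilities, transitions, life table, run settings.

All quantities are stored at full precision in 2023 US dollars (the source
tariffs are TRY-denominated; the fixed conversion rate is recorded on the
run settings so reports can restate amounts in TRY). Cost *components* are
canonical: band totals are always recomputed by summation, never stored as
independent values. Printed totals from the source tables travel along only
as validation annotations (see :func:`remarkov.basecase.validate_cost_tables`).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BandLookupError,
    ConfigurationError,
    CoverageError,
    ValidationError,
)
from .states import STRATEGIES, HealthState, Perspective

__all__ = [
    "BandDef",
    "CostComponent",
    "CostSchedule",
    "UtilitySet",
    "TransitionParams",
    "LifeTable",
    "ModelConfig",
    "ParameterBundle",
    "read_life_table",
    "write_life_table",
]

#: Default discount-timing convention: the first cycle is undiscounted,
#: i.e. the factor for cycle t is (1 + r) ** -(t - 1).
FIRST_CYCLE_UNDISCOUNTED = "first-cycle-undiscounted"
END_OF_CYCLE = "end-of-cycle"
DISCOUNT_TIMINGS = (FIRST_CYCLE_UNDISCOUNTED, END_OF_CYCLE)


@dataclass(frozen=True)
class BandDef:
    """A contiguous run of model cycles sharing one annual cost.

    ``last_cycle`` of ``None`` means "through the end of the horizon".
    Cycle indices are 1-based, mirroring the source tables ("Year 1",
    "Year 3 and beyond", ...).
    """

    name: str
    first_cycle: int
    last_cycle: int | None

    def contains(self, cycle: int) -> bool:
        if cycle < self.first_cycle:
            return False
        return self.last_cycle is None or cycle <= self.last_cycle


@dataclass(frozen=True)
class CostComponent:
    """One labelled annual cost line (e.g. ``operation``, ``strip``)."""

    label: str
    amount: float  # US$ per year, >= 0

    def __post_init__(self):
        if self.amount < 0:
            raise ValidationError("cost component amount must be >= 0",
                                  field=self.label)


@dataclass
class CostSchedule:
    """Per-strategy, per-perspective annual direct medical costs.

    ``bands`` maps ``(state, band name)`` to the component list priced for
    that state while the band is active. The DEAD state never appears: it
    accrues zero cost by construction. ``printed_totals`` carries the
    totals as printed in the source tables, used only for the discrepancy
    report.
    """

    strategy: str
    perspective: Perspective
    band_defs: tuple[BandDef, ...]
    bands: dict[tuple[HealthState, str], tuple[CostComponent, ...]]
    printed_totals: dict[tuple[HealthState, str], float] = field(default_factory=dict)

    def band_for_cycle(self, cycle: int) -> str:
        for bd in self.band_defs:
            if bd.contains(cycle):
                return bd.name
        raise BandLookupError(
            f"no cost band covers cycle {cycle} for strategy {self.strategy}")

    def band_total(self, state: HealthState, band: str) -> float:
        """Sum of component amounts for (state, band), full precision."""
        state = HealthState(state)
        if state is HealthState.DEAD:
            return 0.0
        key = (state, band)
        if key not in self.bands:
            raise BandLookupError(
                f"unknown band {band!r} for ({self.strategy}, {state.value})")
        return float(sum(c.amount for c in self.bands[key]))

    def cycle_cost(self, state: HealthState, cycle: int) -> float:
        """Annual cost accrued in ``cycle`` by a member of ``state``."""
        if HealthState(state) is HealthState.DEAD:
            return 0.0
        return self.band_total(state, self.band_for_cycle(cycle))

    def validate(self, horizon: int, prefix: str = "costs") -> None:
        covered = set()
        for bd in self.band_defs:
            last = bd.last_cycle if bd.last_cycle is not None else horizon
            covered.update(range(bd.first_cycle, last + 1))
        missing = sorted(set(range(1, horizon + 1)) - covered)
        if missing:
            raise ValidationError(
                f"bands do not cover cycles {missing[:5]}...",
                field=f"{prefix}.{self.strategy}.{self.perspective.value}.bands")
        for state in (HealthState.T2DM, HealthState.REMISSION):
            for bd in self.band_defs:
                if (state, bd.name) not in self.bands:
                    raise ValidationError(
                        f"missing component list for state {state.value}",
                        field=(f"{prefix}.{self.strategy}."
                               f"{self.perspective.value}.{state.value}.{bd.name}"))


@dataclass
class UtilitySet:
    """Health-state utility weights (QALY weight per year in state)."""

    u_t2dm: float = 0.772
    u_remission: float = 0.812
    u_dead: float = 0.0

    def value(self, state: HealthState) -> float:
        return {HealthState.T2DM: self.u_t2dm,
                HealthState.REMISSION: self.u_remission,
                HealthState.DEAD: self.u_dead}[HealthState(state)]

    def as_vector(self) -> np.ndarray:
        return np.array([self.u_t2dm, self.u_remission, self.u_dead])

    def validate(self, prefix: str = "utilities") -> None:
        for name, u in (("u_t2dm", self.u_t2dm),
                        ("u_remission", self.u_remission),
                        ("u_dead", self.u_dead)):
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"utility {u} outside [0, 1]",
                                      field=f"{prefix}.{name}")
        if self.u_dead != 0.0:
            raise ValidationError("utility of death must be 0",
                                  field=f"{prefix}.u_dead")


@dataclass
class TransitionParams:
    """Per-strategy annual transition inputs.

    ``p_remission`` applies from T2DM only once the remission lockout has
    elapsed (``lockout_cycles`` full treatment years, default 2).
    ``p_relapse`` applies from REMISSION back to T2DM. State-specific
    hazard-ratio multipliers scale the background (life-table) death
    probability; ``p_periop_death`` is an additional operative mortality
    applied in cycle 1 only (surgery strategies).
    """

    p_remission: float
    p_relapse: float
    lockout_cycles: int = 2
    mortality_hr_t2dm: float = 1.0
    mortality_hr_remission: float = 1.0
    p_periop_death: float = 0.0

    def validate(self, prefix: str = "transitions") -> None:
        for name in ("p_remission", "p_relapse", "p_periop_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"probability {v} outside [0, 1]",
                                      field=f"{prefix}.{name}")
        if self.lockout_cycles < 0 or int(self.lockout_cycles) != self.lockout_cycles:
            raise ValidationError("lockout_cycles must be a non-negative integer",
                                  field=f"{prefix}.lockout_cycles")
        for name in ("mortality_hr_t2dm", "mortality_hr_remission"):
            if getattr(self, name) < 0:
                raise ValidationError("hazard-ratio multiplier must be >= 0",
                                      field=f"{prefix}.{name}")


@dataclass
class LifeTable:
    """Annual background mortality: probability of death ``qx`` at each age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)

    def qx_at(self, age: int) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise CoverageError(
                f"age {age} outside life-table coverage "
                f"[{self.ages[0]}, {self.ages[-1]}]", field="life_table")
        return float(self.qx[age - self.ages[0]])

    def validate(self, prefix: str = "life_table") -> None:
        if self.ages.size == 0:
            raise ValidationError("life table is empty", field=prefix)
        if self.ages.size != self.qx.size:
            raise ValidationError("age and qx columns differ in length",
                                  field=prefix)
        if not np.array_equal(self.ages, np.arange(self.ages[0],
                                                   self.ages[0] + self.ages.size)):
            raise ValidationError("ages must be contiguous integers",
                                  field=f"{prefix}.age")
        bad = (self.qx < 0) | (self.qx > 1)
        if bad.any():
            age = int(self.ages[np.argmax(bad)])
            raise ValidationError(f"qx outside [0, 1] at age {age}",
                                  field=f"{prefix}.qx")

    def check_coverage(self, start_age: int, horizon: int,
                       prefix: str = "life_table") -> None:
        need_last = start_age + horizon - 1
        if start_age < self.ages[0] or need_last > self.ages[-1]:
            raise CoverageError(
                f"model visits ages {start_age}..{need_last} but table covers "
                f"{self.ages[0]}..{self.ages[-1]}", field=prefix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


@dataclass
class ModelConfig:
    """Run settings for the cohort simulation and economic evaluation."""

    start_age: int = 40
    horizon: int = 60  # cycles (years)
    cycle_length: float = 1.0  # years per cycle
    discount_rate: float = 0.03  # per year, applied to costs and QALYs
    discount_timing: str = FIRST_CYCLE_UNDISCOUNTED
    half_cycle_correction: bool = False
    perspective: Perspective = Perspective.SUT
    cohort_size: int = 1000  # report scaling / microsimulation only
    wtp_thresholds: tuple[float, ...] = (10994.0, 39330.0)  # US$/QALY
    master_seed: int = 20231019
    try_per_usd: float = 28.0153  # fixed 2023 conversion rate

    def __post_init__(self):
        self.perspective = Perspective(self.perspective)
        self.wtp_thresholds = tuple(float(w) for w in self.wtp_thresholds)

    def validate(self, prefix: str = "run") -> None:
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1", field=f"{prefix}.horizon")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValidationError("discount rate must be in [0, 1)",
                                  field=f"{prefix}.discount_rate")
        if self.start_age + self.horizon > 100:
            raise ValidationError(
                "start_age + horizon must not exceed the assumed maximum "
                "life expectancy of 100 years", field=f"{prefix}.horizon")
        if self.discount_timing not in DISCOUNT_TIMINGS:
            raise ValidationError(
                f"discount_timing must be one of {DISCOUNT_TIMINGS}",
                field=f"{prefix}.discount_timing")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be positive",
                                  field=f"{prefix}.cycle_length")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1",
                                  field=f"{prefix}.cohort_size")


@dataclass
class ParameterBundle:
    """Everything one model run needs.

    ``transitions`` maps strategy id to its :class:`TransitionParams`;
    ``costs`` maps ``(strategy, perspective)`` to a :class:`CostSchedule`.
    """

    config: ModelConfig
    utilities: UtilitySet
    transitions: dict[str, TransitionParams]
    costs: dict[tuple[str, Perspective], CostSchedule]
    life_table: LifeTable

    @property
    def strategies(self) -> tuple[str, ...]:
        return tuple(self.transitions)

    def schedule(self, strategy: str,
                 perspective: Perspective | None = None) -> CostSchedule:
        p = Perspective(perspective or self.config.perspective)
        try:
            return self.costs[(strategy, p)]
        except KeyError:
            raise ConfigurationError(
                "no cost schedule defined",
                field=f"costs.{strategy}.{p.value}") from None

    def validate(self) -> None:
        self.config.validate()
        self.utilities.validate()
        if not self.transitions:
            raise ConfigurationError("no strategies defined", field="transitions")
        for sid, tp in self.transitions.items():
            tp.validate(prefix=f"transitions.{sid}")
        self.life_table.validate()
        self.life_table.check_coverage(self.config.start_age, self.config.horizon)
        for (sid, persp), sched in self.costs.items():
            sched.validate(self.config.horizon)
            if sched.strategy != sid or Perspective(sched.perspective) is not persp:
                raise ConfigurationError(
                    "schedule key does not match schedule contents",
                    field=f"costs.{sid}.{persp.value}")
        for sid in self.transitions:
            if (sid, self.config.perspective) not in self.costs:
                raise ConfigurationError(
                    "missing cost schedule for run perspective",
                    field=f"costs.{sid}.{self.config.perspective.value}")

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)


def read_life_table(path: str | Path) -> LifeTable:
    """Read a life table from CSV with header columns ``age,qx``."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"life-table file not found: {path}",
                                 field="life_table.path")
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["age", "qx"]:
        raise ConfigurationError(
            f"expected header 'age,qx', found {list(df.columns)!r}",
            field="life_table.path")
    df.columns = cols
    ages = df["age"].to_numpy()
    if np.any(ages != ages.astype(int)):
        raise ValidationError("ages must be integers", field="life_table.age")
    ages = ages.astype(int)
    if np.any(np.diff(ages) != 1):
        raise ValidationError("ages must be contiguous and strictly increasing",
                              field="life_table.age")
    lt = LifeTable(ages=ages, qx=df["qx"].to_numpy(dtype=float))
    lt.validate()
    return lt


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    lt.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Dot-path access into a bundle, used by sensitivity analysis and calibration.
#
# Grammar:
#   config.<field>                              e.g. config.discount_rate
#   utilities.<u_t2dm|u_remission>
#   transitions.<strategy|*>.<field>            e.g. transitions.SG.p_remission
#   costs.<strategy|*>.<persp|*>.<state>.<band>.<label>
# A '*' segment addresses every strategy / perspective at once (reads return
# the common value and raise if they disagree).
# --------------------------------------------------------------------------

def get_param(bundle: ParameterBundle, path: str) -> float:
    """Read one scalar parameter identified by ``path``."""
    parts = path.split(".")
    root = parts[0]
    if root == "config" and len(parts) == 2:
        return float(getattr(bundle.config, parts[1]))
    if root == "utilities" and len(parts) == 2:
        return float(getattr(bundle.utilities, parts[1]))
    if root == "transitions" and len(parts) == 3:
        sids = bundle.strategies if parts[1] == "*" else (parts[1],)
        vals = {float(getattr(bundle.transitions[s], parts[2])) for s in sids}
        if len(vals) != 1:
            raise ValidationError(f"wildcard path reads differing values {vals}",
                                  field=path)
        return vals.pop()
    if root == "costs" and len(parts) == 6:
        _, sid, persp, state, band, label = parts
        wildcard = sid == "*" or persp == "*"
        vals = set()
        for (s, p), sched in bundle.costs.items():
            if sid not in ("*", s) or persp not in ("*", p.value):
                continue
            comps = sched.bands.get((HealthState(state), band))
            if comps is None:
                if wildcard:  # other strategies may use different band names
                    continue
                raise BandLookupError(path)
            hit = [c.amount for c in comps if c.label == label]
            if not hit:
                if wildcard:
                    continue
                raise BandLookupError(path)
            vals.add(hit[0])
        if not vals:
            raise BandLookupError(path)
        if len(vals) != 1:
            raise ValidationError(
                f"path matches {len(vals)} distinct values", field=path)
        return vals.pop()
    raise ConfigurationError(f"unrecognised parameter path {path!r}", field=path)


def set_param_inplace(bundle: ParameterBundle, path: str, value: float) -> None:
    """Assign ``value`` to the parameter at ``path``, mutating ``bundle``."""
    parts = path.split(".")
    root = parts[0]
    if root == "config" and len(parts) == 2:
        if not hasattr(bundle.config, parts[1]):
            raise ConfigurationError("unknown run setting", field=path)
        setattr(bundle.config, parts[1], type(getattr(bundle.config, parts[1]))(value))
        return
    if root == "utilities" and len(parts) == 2:
        if not hasattr(bundle.utilities, parts[1]):
            raise ConfigurationError("unknown utility", field=path)
        setattr(bundle.utilities, parts[1], float(value))
        return
    if root == "transitions" and len(parts) == 3:
        sids = bundle.strategies if parts[1] == "*" else (parts[1],)
        for s in sids:
            if s not in bundle.transitions:
                raise ConfigurationError("unknown strategy", field=path)
            if not hasattr(bundle.transitions[s], parts[2]):
                raise ConfigurationError("unknown transition field", field=path)
            setattr(bundle.transitions[s], parts[2], float(value))
        return
    if root == "costs" and len(parts) == 6:
        _, sid, persp, state, band, label = parts
        wildcard = sid == "*" or persp == "*"
        hit = False
        for (s, p), sched in bundle.costs.items():
            if sid not in ("*", s) or persp not in ("*", p.value):
                continue
            key = (HealthState(state), band)
            comps = sched.bands.get(key)
            if comps is None or not any(c.label == label for c in comps):
                if wildcard:
                    continue
                raise BandLookupError(path)
            sched.bands[key] = tuple(
                dataclasses.replace(c, amount=float(value)) if c.label == label
                else c for c in comps)
            hit = True
        if not hit:
            raise BandLookupError(path)
        return
    raise ConfigurationError(f"unrecognised parameter path {path!r}", field=path)


def with_params(bundle: ParameterBundle,
                assignments: Mapping[str, float]) -> ParameterBundle:
    """Return a deep copy of ``bundle`` with the given paths reassigned."""
    out = bundle.copy()
    for path, value in assignments.items():
        set_param_inplace(out, path, value)
    return out


def iter_cost_paths(bundle: ParameterBundle,
                    perspective: Perspective | None = None) -> Iterable[str]:
    """Yield a dot path for every cost component of one perspective."""
    p = Perspective(perspective or bundle.config.perspective)
    for (sid, persp), sched in sorted(bundle.costs.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1].value)):
        if persp is not p:
            continue
        for (state, band), comps in sorted(sched.bands.items(),
                                           key=lambda kv: (kv[0][0].value, kv[0][1])):
            for c in comps:
                yield f"costs.{sid}.{persp.value}.{state.value}.{band}.{c.label}"
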
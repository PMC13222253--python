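"""Bundled base case: the published 2023 Turkish cost and utility inputs.

Annual direct medical costs per strategy, payer perspective, health state
and cost band, exactly as published at component level (US$, converted
from TRY at the fixed 2023 rate of 28.0153 TRY/US$). Component amounts are
the canonical data; the published band totals are retained only as
annotations because two of them are arithmetically inconsistent with their
own components (see :func:`validate_cost_tables`).

Strategy-specific transition probabilities were not published; the bundled
defaults here are illustrative placeholders in a clinically plausible range
and are expected to be replaced by user input or by the calibration stage
(:mod:`remarkov.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    BandDef,
    CostComponent,
    CostSchedule,
    ModelConfig,
    ParameterBundle,
    TransitionParams,
    UtilitySet,
)
from .states import STRATEGIES, HealthState, Perspective

__all__ = [
    "base_case_parameters",
    "base_case_bundle",
    "base_case_transitions",
    "validate_cost_tables",
    "Discrepancy",
]

#: Cost bands per strategy (1-based cycles, mirroring the table headings:
#: PT prices years 1-2 and year 3+; SG prices year 1 and year 2+).
BAND_DEFS: dict[str, tuple[BandDef, ...]] = {
    "PT": (BandDef("years1_2", 1, 2), BandDef("year3plus", 3, None)),
    "SG": (BandDef("year1", 1, 1), BandDef("year2plus", 2, None)),
}

_T2DM = HealthState.T2DM
_REM = HealthState.REMISSION

# {strategy: {state: {band: {label: (SUT US$, PHSP US$)}}}}
_PT_Y12 = {
    "outpatient": (39.19, 53.54),
    "consultation": (0.34, 1.68),
    "tests": (7.20, 10.58),
    "t2dm_drugs": (54.26, 75.15),
    "obesity_drugs": (556.45, 772.85),
    "symptomatic_drugs": (38.98, 61.75),
    "strip": (1.45, 3.45),
}
_SG_Y1_T2DM = {
    "outpatient": (71.85, 98.16),
    "operation": (1171.16, 2342.30),
    "consultation": (0.34, 1.68),
    "tests": (7.20, 10.58),
    "t2dm_drugs": (54.26, 75.15),
    "sg_drugs": (47.59, 65.77),
    "symptomatic_drugs": (38.98, 61.75),
    "strip": (1.45, 3.45),
}
# The remission table prints the PHSP operation fee as 2,342.33 (vs 2,342.30
# in the T2DM table); each table is stored as published.
_SG_Y1_REM = dict(_SG_Y1_T2DM, operation=(1171.16, 2342.33))

_COMPONENTS: dict[str, dict[HealthState, dict[str, dict[str, tuple[float, float]]]]] = {
    "PT": {
        _T2DM: {
            "years1_2": _PT_Y12,
            "year3plus": {
                "outpatient": (26.13, 35.69),
                "consultation": (0.34, 1.68),
                "tests": (7.20, 10.58),
                "t2dm_drugs": (54.26, 75.15),
                "symptomatic_drugs": (38.98, 65.77),
                "strip": (1.45, 3.45),
            },
        },
        _REM: {
            "years1_2": _PT_Y12,
            "year3plus": {
                "outpatient": (13.06, 17.85),
                "hba1c": (6.54, 9.07),
                "symptomatic_drugs": (29.23, 46.31),
            },
        },
    },
    "SG": {
        _T2DM: {
            "year1": _SG_Y1_T2DM,
            "year2plus": {
                "outpatient": (32.66, 44.62),
                "consultation": (0.34, 1.68),
                "tests": (7.20, 10.58),
                "t2dm_drugs": (54.26, 75.15),
                "symptomatic_drugs": (38.98, 61.75),
                "strip": (1.45, 3.45),
            },
        },
        _REM: {
            "year1": _SG_Y1_REM,
            "year2plus": {
                "outpatient": (19.60, 26.77),
                "hba1c": (6.54, 9.07),
                "symptomatic_drugs": (29.23, 46.31),
            },
        },
    },
}

#: Band totals as printed in the source tables (annotation only).
_PRINTED_TOTALS: dict[str, dict[HealthState, dict[str, tuple[float, float]]]] = {
    "PT": {
        _T2DM: {"years1_2": (697.88, 975.55), "year3plus": (128.36, 192.32)},
        _REM: {"years1_2": (697.88, 975.55), "year3plus": (48.83, 73.23)},
    },
    "SG": {
        _T2DM: {"year1": (1391.40, 2658.87), "year2plus": (133.45, 197.23)},
        _REM: {"year1": (1391.40, 2658.87), "year2plus": (55.37, 82.15)},
    },
}

#: Annual totals quoted in the running text where they disagree with the
#: table total for the same band (PHSP, PT year 3+): 188.30 vs 192.32.
_TEXT_TOTALS: dict[tuple[str, HealthState, str, Perspective], float] = {
    ("PT", _T2DM, "year3plus", Perspective.PHSP): 188.30,
}

_PIDX = {Perspective.SUT: 0, Perspective.PHSP: 1}


def _schedule(strategy: str, perspective: Perspective) -> CostSchedule:
    i = _PIDX[perspective]
    bands = {}
    printed = {}
    for state, by_band in _COMPONENTS[strategy].items():
        for band, comps in by_band.items():
            bands[(state, band)] = tuple(
                CostComponent(label, amounts[i]) for label, amounts in comps.items())
            printed[(state, band)] = _PRINTED_TOTALS[strategy][state][band][i]
    return CostSchedule(strategy=strategy, perspective=perspective,
                        band_defs=BAND_DEFS[strategy], bands=bands,
                        printed_totals=printed)


def base_case_transitions() -> dict[str, TransitionParams]:
    """Illustrative strategy transition inputs (replace via config or calibration).

    Remission entry is high after sleeve gastrectomy and low under
    pharmacotherapy; relapse is the reverse; uncontrolled T2DM carries a
    moderate excess mortality hazard while remission mortality returns to
    the background rate.
    """
    return {
        "PT": TransitionParams(p_remission=0.05, p_relapse=0.10,
                               mortality_hr_t2dm=1.5),
        "SG": TransitionParams(p_remission=0.35, p_relapse=0.04,
                               mortality_hr_t2dm=1.5),
    }


def base_case_parameters(
    perspective: Perspective | str = Perspective.SUT,
) -> tuple[dict[tuple[str, Perspective], CostSchedule], UtilitySet, ModelConfig]:
    """The published base case for one payer perspective.

    Returns the component-level cost schedules for both strategies, the
    utility set (0.772 T2DM / 0.812 remission) and the default run settings
    (age 40 entry, 60 annual cycles, 3% discount on costs and QALYs).
    """
    p = Perspective(perspective)
    schedules = {(sid, p): _schedule(sid, p) for sid in STRATEGIES}
    return schedules, UtilitySet(), ModelConfig(perspective=p)


def base_case_bundle(
    perspective: Perspective | str = Perspective.SUT,
    life_table=None,
) -> ParameterBundle:
    """Full runnable base case.

    Cost schedules are attached for *both* perspectives so a single bundle
    supports perspective switches. When no life table is given, a synthetic
    Gompertz–Makeham table covering ages 40-99 is generated (see
    :mod:`remarkov.synthetic`).
    """
    p = Perspective(perspective)
    if life_table is None:
        from .synthetic import GompertzMakehamSpec, make_life_table
        life_table = make_life_table(GompertzMakehamSpec())
    costs = {}
    for persp in Perspective:
        for sid in STRATEGIES:
            costs[(sid, persp)] = _schedule(sid, persp)
    bundle = ParameterBundle(
        config=ModelConfig(perspective=p),
        utilities=UtilitySet(),
        transitions=base_case_transitions(),
        costs=costs,
        life_table=life_table,
    )
    bundle.validate()
    return bundle


@dataclass(frozen=True)
class Discrepancy:
    """One inconsistency between published cost figures."""

    strategy: str
    perspective: Perspective
    state: HealthState
    band: str
    component_sum: float
    printed_total: float
    difference: float  # component_sum - printed_total
    kind: str  # "component-total mismatch" or "printed-total ambiguity"
    note: str = ""


def validate_cost_tables(
    schedules: dict[tuple[str, Perspective], CostSchedule] | None = None,
    tolerance: float = 0.05,
) -> list[Discrepancy]:
    """Report where component sums disagree with the published band totals.

    Reporting only — the model always uses component sums. With the bundled
    base case this flags: the PT years-1-2 PHSP total (strip apparently
    excluded from the printed figure), the SG year-1 and year-2+ SUT totals
    (off by roughly the strip cost), the SG year-1 PHSP total under the
    T2DM table's operation fee, and the text-vs-table ambiguity for the PT
    year-3+ PHSP total (188.30 in text, 192.32 in the table).
    """
    if schedules is None:
        schedules = {}
        for persp in Perspective:
            schedules.update(base_case_parameters(persp)[0])
    out: list[Discrepancy] = []
    for (sid, persp), sched in sorted(schedules.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1].value)):
        for (state, band), printed in sorted(
                sched.printed_totals.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1])):
            total = sched.band_total(state, band)
            diff = total - printed
            if abs(diff) > tolerance:
                out.append(Discrepancy(sid, persp, state, band,
                                       round(total, 10), printed, round(diff, 10),
                                       kind="component-total mismatch"))
            text_total = _TEXT_TOTALS.get((sid, state, band, persp))
            if text_total is not None and abs(text_total - printed) > tolerance:
                out.append(Discrepancy(
                    sid, persp, state, band, round(total, 10), printed,
                    round(text_total - printed, 10),
                    kind="printed-total ambiguity",
                    note=f"running text quotes {text_total}, table prints {printed}"))
    return out
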
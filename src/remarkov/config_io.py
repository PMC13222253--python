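"""Run-configuration documents (YAML): schema, loader, writer.

One document describes a complete run. Top-level keys (all snake_case):

``run``
    start_age (years), horizon (annual cycles), cycle_length (years),
    discount_rate (fraction/year), discount_timing
    (``first-cycle-undiscounted`` | ``end-of-cycle``),
    half_cycle_correction (bool), perspective (``SUT`` | ``PHSP``),
    cohort_size, wtp_thresholds (US$/QALY list), master_seed,
    try_per_usd (TRY per US$ conversion rate used for reporting).
``utilities``
    t2dm, remission — QALY weights per year in state.
``transitions``
    per strategy: p_remission, p_relapse (per cycle), lockout_cycles,
    mortality_hr_t2dm, mortality_hr_remission, p_periop_death.
``life_table``
    exactly one of: ``path`` (CSV with header ``age,qx``, resolved
    relative to the config file), ``gompertz_makeham``
    (makeham, gompertz_a, gompertz_b, age_lo, age_hi) or ``inline``
    (start_age plus a qx list, one value per age).
``costs``
    per strategy: ``bands`` (name -> [first_cycle, last_cycle|null]),
    then per perspective, per state, per band a mapping of component
    label -> US$/year; optional ``printed_totals`` annotations mirror
    that nesting.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .parameters import (
    BandDef,
    CostComponent,
    CostSchedule,
    LifeTable,
    ModelConfig,
    ParameterBundle,
    TransitionParams,
    UtilitySet,
    read_life_table,
)
from .states import HealthState, Perspective

__all__ = ["load_config", "write_config", "bundled_config_path"]


def bundled_config_path() -> Path:
    """Path of the packaged base-case configuration document."""
    return Path(resources.files("remarkov").joinpath("data/basecase.yaml"))


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigurationError("missing required field", field=f"{where}.{key}")
    return mapping[key]


def _life_table_from_doc(doc: dict, base_dir: Path) -> LifeTable:
    spec = _require(doc, "life_table", "")
    forms = [k for k in ("path", "gompertz_makeham", "inline") if k in spec]
    if len(forms) != 1:
        raise ConfigurationError(
            "give exactly one of path / gompertz_makeham / inline",
            field="life_table")
    if forms[0] == "path":
        return read_life_table(base_dir / spec["path"])
    if forms[0] == "gompertz_makeham":
        from .synthetic import GompertzMakehamSpec, make_life_table
        return make_life_table(GompertzMakehamSpec(**spec["gompertz_makeham"]))
    inline = spec["inline"]
    start = int(_require(inline, "start_age", "life_table.inline"))
    qx = np.asarray(_require(inline, "qx", "life_table.inline"), dtype=float)
    return LifeTable(ages=np.arange(start, start + qx.size), qx=qx)


def load_config(path: str | Path) -> ParameterBundle:
    """Parse and fully validate a run-configuration document."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")

    run = _require(doc, "run", "")
    known = set(ModelConfig.__dataclass_fields__)
    unknown = set(run) - known
    if unknown:
        raise ConfigurationError(f"unknown run settings {sorted(unknown)}",
                                 field="run")
    config = ModelConfig(**run)

    util = _require(doc, "utilities", "")
    utilities = UtilitySet(u_t2dm=float(_require(util, "t2dm", "utilities")),
                           u_remission=float(_require(util, "remission",
                                                      "utilities")))

    trans_doc = _require(doc, "transitions", "")
    transitions = {}
    for sid, fields in trans_doc.items():
        where = f"transitions.{sid}"
        transitions[sid] = TransitionParams(
            p_remission=float(_require(fields, "p_remission", where)),
            p_relapse=float(_require(fields, "p_relapse", where)),
            lockout_cycles=int(fields.get("lockout_cycles", 2)),
            mortality_hr_t2dm=float(fields.get("mortality_hr_t2dm", 1.0)),
            mortality_hr_remission=float(fields.get("mortality_hr_remission", 1.0)),
            p_periop_death=float(fields.get("p_periop_death", 0.0)),
        )

    life_table = _life_table_from_doc(doc, path.parent)

    costs_doc = _require(doc, "costs", "")
    costs = {}
    for sid, entry in costs_doc.items():
        where = f"costs.{sid}"
        bands_doc = _require(entry, "bands", where)
        band_defs = tuple(
            BandDef(name, int(span[0]),
                    None if span[1] is None else int(span[1]))
            for name, span in bands_doc.items())
        printed_doc = entry.get("printed_totals", {})
        for pkey, by_state in entry.items():
            if pkey in ("bands", "printed_totals"):
                continue
            persp = Perspective(pkey)
            bands = {}
            printed = {}
            for state_name, by_band in by_state.items():
                state = HealthState(state_name)
                for band, comps in by_band.items():
                    bands[(state, band)] = tuple(
                        CostComponent(label, float(amount))
                        for label, amount in comps.items())
                    ann = printed_doc.get(pkey, {}).get(state_name, {}).get(band)
                    if ann is not None:
                        printed[(state, band)] = float(ann)
            costs[(sid, persp)] = CostSchedule(
                strategy=sid, perspective=persp, band_defs=band_defs,
                bands=bands, printed_totals=printed)

    bundle = ParameterBundle(config=config, utilities=utilities,
                             transitions=transitions, costs=costs,
                             life_table=life_table)
    bundle.validate()
    return bundle


def write_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Serialise a bundle back to the documented YAML schema.

    The life table is written inline so the document is self-contained;
    ``load_config(write_config(...))`` reproduces the bundle exactly.
    """
    c = bundle.config
    doc: dict = {
        "run": {
            "start_age": c.start_age, "horizon": c.horizon,
            "cycle_length": c.cycle_length, "discount_rate": c.discount_rate,
            "discount_timing": c.discount_timing,
            "half_cycle_correction": c.half_cycle_correction,
            "perspective": c.perspective.value, "cohort_size": c.cohort_size,
            "wtp_thresholds": list(c.wtp_thresholds),
            "master_seed": c.master_seed, "try_per_usd": c.try_per_usd,
        },
        "utilities": {"t2dm": bundle.utilities.u_t2dm,
                      "remission": bundle.utilities.u_remission},
        "transitions": {
            sid: {"p_remission": tp.p_remission, "p_relapse": tp.p_relapse,
                  "lockout_cycles": tp.lockout_cycles,
                  "mortality_hr_t2dm": tp.mortality_hr_t2dm,
                  "mortality_hr_remission": tp.mortality_hr_remission,
                  "p_periop_death": tp.p_periop_death}
            for sid, tp in bundle.transitions.items()
        },
        "life_table": {"inline": {
            "start_age": int(bundle.life_table.ages[0]),
            "qx": [float(q) for q in bundle.life_table.qx],
        }},
        "costs": {},
    }
    for (sid, persp), sched in sorted(bundle.costs.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1].value)):
        entry = doc["costs"].setdefault(sid, {
            "bands": {bd.name: [bd.first_cycle, bd.last_cycle]
                      for bd in sched.band_defs}})
        by_state: dict = {}
        for (state, band), comps in sorted(
                sched.bands.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            by_state.setdefault(state.value, {})[band] = {
                comp.label: comp.amount for comp in comps}
        entry[persp.value] = by_state
        if sched.printed_totals:
            ann = entry.setdefault("printed_totals", {}).setdefault(persp.value, {})
            for (state, band), total in sorted(
                    sched.printed_totals.items(),
                    key=lambda kv: (kv[0][0].value, kv[0][1])):
                ann.setdefault(state.value, {})[band] = total
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
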
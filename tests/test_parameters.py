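"""Parameter containers, cost tables, config I/O."""

import numpy as np
import pytest

from remarkov.basecase import base_case_parameters, validate_cost_tables
from remarkov.config_io import bundled_config_path, load_config, write_config
from remarkov.errors import (
    BandLookupError,
    ConfigurationError,
    CoverageError,
    ValidationError,
)
from remarkov.parameters import (
    LifeTable,
    get_param,
    read_life_table,
    set_param_inplace,
    with_params,
    write_life_table,
)
from remarkov.states import HealthState, Perspective

from conftest import constant_life_table


# Bands whose published totals are arithmetically consistent with their
# own components (to the printed 2-decimal precision).
CONSISTENT_BANDS = [
    ("PT", Perspective.SUT, HealthState.T2DM, "year3plus", 128.36),
    ("PT", Perspective.PHSP, HealthState.T2DM, "year3plus", 192.32),
    ("PT", Perspective.SUT, HealthState.REMISSION, "year3plus", 48.83),
    ("PT", Perspective.PHSP, HealthState.REMISSION, "year3plus", 73.23),
    ("SG", Perspective.SUT, HealthState.REMISSION, "year2plus", 55.37),
    ("SG", Perspective.PHSP, HealthState.REMISSION, "year2plus", 82.15),
    ("SG", Perspective.PHSP, HealthState.T2DM, "year2plus", 197.23),
    ("SG", Perspective.PHSP, HealthState.REMISSION, "year1", 2658.87),
]


@pytest.mark.parametrize("strategy,persp,state,band,total", CONSISTENT_BANDS)
def test_band_total_is_component_sum(strategy, persp, state, band, total):
    schedules, _, _ = base_case_parameters(persp)
    assert schedules[(strategy, persp)].band_total(state, band) == pytest.approx(
        total, abs=0.005)


def test_dead_state_costs_nothing(bundle):
    sched = bundle.schedule("PT")
    assert sched.band_total(HealthState.DEAD, "year3plus") == 0.0
    assert sched.cycle_cost(HealthState.DEAD, 17) == 0.0


def test_unknown_band_raises(bundle):
    with pytest.raises(BandLookupError):
        bundle.schedule("PT").band_total(HealthState.T2DM, "year9")


def test_band_resolution_covers_horizon(bundle):
    for sid in ("PT", "SG"):
        sched = bundle.schedule(sid)
        for cycle in range(1, bundle.config.horizon + 1):
            assert sched.band_for_cycle(cycle)
    assert bundle.schedule("PT").band_for_cycle(2) == "years1_2"
    assert bundle.schedule("PT").band_for_cycle(3) == "year3plus"
    assert bundle.schedule("SG").band_for_cycle(1) == "year1"
    assert bundle.schedule("SG").band_for_cycle(2) == "year2plus"


def test_cost_table_discrepancy_report():
    """The report flags exactly the published internal inconsistencies."""
    issues = validate_cost_tables()
    flagged = {(d.strategy, d.perspective, d.state, d.band, d.kind)
               for d in issues}
    # strip apparently excluded from the printed PT years-1-2 PHSP total
    assert ("PT", Perspective.PHSP, HealthState.T2DM, "years1_2",
            "component-total mismatch") in flagged
    # SG year-1 SUT printed total is about one strip below the component sum
    assert ("SG", Perspective.SUT, HealthState.T2DM, "year1",
            "component-total mismatch") in flagged
    # text quotes 188.30 for PT year-3+ PHSP while the table prints 192.32
    assert ("PT", Perspective.PHSP, HealthState.T2DM, "year3plus",
            "printed-total ambiguity") in flagged
    # fully consistent bands are not flagged
    assert ("PT", Perspective.SUT, HealthState.T2DM, "year3plus",
            "component-total mismatch") not in flagged
    sg_y1_sut = next(d for d in issues
                     if (d.strategy, d.perspective, d.band, d.kind)
                     == ("SG", Perspective.SUT, "year1",
                         "component-total mismatch"))
    assert sg_y1_sut.component_sum == pytest.approx(1392.83, abs=0.005)
    assert sg_y1_sut.printed_total == 1391.40


def test_bundled_config_loads_published_base_case():
    bundle = load_config(bundled_config_path())
    assert bundle.utilities.u_t2dm == 0.772
    assert bundle.utilities.u_remission == 0.812
    assert bundle.config.discount_rate == 0.03
    assert bundle.config.horizon == 60
    assert bundle.config.start_age == 40
    assert bundle.config.try_per_usd == 28.0153
    assert get_param(bundle, "costs.SG.SUT.T2DM.year1.operation") == 1171.16
    assert get_param(bundle, "costs.SG.PHSP.T2DM.year1.operation") == 2342.30
    assert get_param(bundle, "costs.PT.SUT.T2DM.years1_2.obesity_drugs") == 556.45
    with pytest.raises(BandLookupError):
        get_param(bundle, "costs.PT.SUT.T2DM.years1_2.operation")


def test_config_round_trip(tmp_path, bundle):
    path = tmp_path / "cfg.yaml"
    write_config(bundle, path)
    again = load_config(path)
    assert again.utilities == bundle.utilities
    assert again.transitions == bundle.transitions
    assert again.config == bundle.config
    np.testing.assert_array_equal(again.life_table.qx, bundle.life_table.qx)
    for key, sched in bundle.costs.items():
        assert again.costs[key].bands == sched.bands
        assert again.costs[key].printed_totals == sched.printed_totals
        assert again.costs[key].band_defs == sched.band_defs


def test_load_config_error_paths(tmp_path, bundle):
    import yaml
    path = tmp_path / "cfg.yaml"
    write_config(bundle, path)
    doc = yaml.safe_load(path.read_text())

    broken = dict(doc)
    broken.pop("utilities")
    p = tmp_path / "missing.yaml"
    p.write_text(yaml.safe_dump(broken))
    with pytest.raises(ConfigurationError, match="utilities"):
        load_config(p)

    bad = yaml.safe_load(path.read_text())
    bad["transitions"]["SG"]["p_remission"] = 1.2
    p = tmp_path / "bad_prob.yaml"
    p.write_text(yaml.safe_dump(bad))
    with pytest.raises(ValidationError, match="p_remission"):
        load_config(p)

    short = yaml.safe_load(path.read_text())
    short["life_table"] = {"inline": {"start_age": 40, "qx": [0.01] * 30}}
    p = tmp_path / "short_lt.yaml"
    p.write_text(yaml.safe_dump(short))
    with pytest.raises(CoverageError):
        load_config(p)


def test_read_life_table(tmp_path):
    lt = constant_life_table(0.01)
    path = tmp_path / "lt.csv"
    write_life_table(lt, path)
    again = read_life_table(path)
    assert again.ages.size == 60
    np.testing.assert_allclose(again.qx, 0.01)

    gap = lt.to_frame().drop(17)  # drop age 57
    gap.to_csv(tmp_path / "gap.csv", index=False)
    with pytest.raises(ValidationError, match="contiguous"):
        read_life_table(tmp_path / "gap.csv")

    neg = lt.to_frame()
    neg.loc[0, "qx"] = -0.1
    neg.to_csv(tmp_path / "neg.csv", index=False)
    with pytest.raises(ValidationError, match="qx"):
        read_life_table(tmp_path / "neg.csv")


def test_life_table_coverage_error():
    lt = constant_life_table(0.01, lo=40, hi=80)
    with pytest.raises(CoverageError):
        lt.check_coverage(start_age=40, horizon=60)
    lt99 = constant_life_table(0.01, lo=40, hi=99)
    lt99.check_coverage(start_age=40, horizon=60)  # exact coverage accepted


def test_param_paths_get_set(bundle):
    assert get_param(bundle, "utilities.u_t2dm") == 0.772
    assert get_param(bundle, "config.discount_rate") == 0.03
    new = with_params(bundle, {"transitions.SG.p_remission": 0.4,
                               "costs.*.*.T2DM.year3plus.strip": 2.0})
    assert new.transitions["SG"].p_remission == 0.4
    assert bundle.transitions["SG"].p_remission != 0.4  # original untouched
    assert get_param(new, "costs.PT.SUT.T2DM.year3plus.strip") == 2.0
    assert get_param(new, "costs.PT.PHSP.T2DM.year3plus.strip") == 2.0
    set_param_inplace(bundle, "transitions.*.mortality_hr_t2dm", 1.7)
    assert bundle.transitions["PT"].mortality_hr_t2dm == 1.7
    assert bundle.transitions["SG"].mortality_hr_t2dm == 1.7
    with pytest.raises(ConfigurationError):
        get_param(bundle, "nonsense.path")


def test_bundle_validation_catches_violations(bundle):
    bundle.transitions["PT"].p_relapse = 1.5
    with pytest.raises(ValidationError, match="transitions.PT.p_relapse"):
        bundle.validate()


def test_utility_bounds(bundle):
    bundle.utilities.u_remission = 1.2
    with pytest.raises(ValidationError, match="u_remission"):
        bundle.validate()
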
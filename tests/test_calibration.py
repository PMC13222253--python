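"""Calibration: objective, recovery, profiles."""

import numpy as np
import pytest

from remarkov.calibration import (
    CalibrationTarget,
    calibrate,
    profile_objective,
    read_targets_csv,
    targets_from_bundle,
)
from remarkov.economics import run_strategy
from remarkov.errors import ValidationError
from remarkov.parameters import with_params
from remarkov.states import Perspective
from remarkov.synthetic import make_ground_truth_bundle


def test_targets_require_valid_quantity_and_weight():
    with pytest.raises(ValidationError):
        CalibrationTarget("lifetime_cost", "PT", Perspective.SUT, 100.0)
    with pytest.raises(ValidationError):
        CalibrationTarget("total_cost", "PT", Perspective.SUT, 100.0, weight=-1)


def test_already_optimal_start_keeps_objective_zero():
    bundle, truth = make_ground_truth_bundle(3)
    targets = targets_from_bundle(bundle, strategies=["SG"])
    free = [("transitions.SG.p_remission", 0.0, 0.6),
            ("transitions.SG.p_relapse", 0.0, 0.15)]
    res = calibrate(bundle, free, targets)
    assert res.objective < 1e-14
    assert res.params["transitions.SG.p_remission"] == pytest.approx(
        truth["transitions.SG.p_remission"], abs=1e-4)


def test_simulate_then_recover_from_remote_start():
    bundle, truth = make_ground_truth_bundle(8)
    targets = targets_from_bundle(bundle, strategies=["PT"])
    start = with_params(bundle, {"transitions.PT.p_remission": 0.55,
                                 "transitions.PT.p_relapse": 0.01})
    free = [("transitions.PT.p_remission", 0.0, 0.6),
            ("transitions.PT.p_relapse", 0.0, 0.15)]
    res = calibrate(start, free, targets)
    assert res.objective < 1e-8
    for path in ("transitions.PT.p_remission", "transitions.PT.p_relapse"):
        assert res.params[path] == pytest.approx(truth[path], abs=1e-3)


def test_single_parameter_matches_bisection_oracle():
    """One monotone target: the fitted relapse probability agrees with an
    independent bisection root-finder on the response curve."""
    bundle, truth = make_ground_truth_bundle(5)
    target_qaly = run_strategy(bundle, "SG").total_qaly
    targets = [CalibrationTarget("total_qaly", "SG", Perspective.SUT,
                                 target_qaly)]
    start = with_params(bundle, {"transitions.SG.p_relapse": 0.08})

    def qaly_at(p):
        return run_strategy(
            with_params(start, {"transitions.SG.p_relapse": p}),
            "SG").total_qaly

    lo, hi = 0.0, 0.15
    assert (qaly_at(lo) - target_qaly) * (qaly_at(hi) - target_qaly) < 0
    for _ in range(60):  # bisection to ~1e-18 interval width
        mid = 0.5 * (lo + hi)
        if (qaly_at(mid) - target_qaly) * (qaly_at(lo) - target_qaly) <= 0:
            hi = mid
        else:
            lo = mid
    root = 0.5 * (lo + hi)

    res = calibrate(start, [("transitions.SG.p_relapse", 0.0, 0.15)], targets)
    assert res.params["transitions.SG.p_relapse"] == pytest.approx(root,
                                                                   abs=1e-6)
    assert root == pytest.approx(truth["transitions.SG.p_relapse"], abs=1e-9)


def test_profile_minimum_at_ground_truth_grid_point():
    bundle, truth = make_ground_truth_bundle(11)
    targets = targets_from_bundle(bundle, strategies=["SG"])
    true_p = truth["transitions.SG.p_remission"]
    grid = sorted(set(np.round(np.linspace(0.05, 0.6, 12), 6)) | {true_p})
    prof = profile_objective(bundle, "transitions.SG.p_remission", grid,
                             targets)
    best_value = min(prof, key=lambda vo: vo[1])[0]
    assert best_value == pytest.approx(true_p)


def test_profile_flat_for_parameter_without_effect():
    """A parameter the targets cannot see (PT perioperative mortality when
    only SG outputs are targeted) profiles flat: non-identifiable."""
    bundle, _ = make_ground_truth_bundle(2)
    targets = targets_from_bundle(bundle, strategies=["SG"])
    prof = profile_objective(bundle, "transitions.PT.p_periop_death",
                             [0.0, 0.02, 0.05], targets)
    objs = [o for _, o in prof]
    assert max(objs) - min(objs) == 0.0


def test_profile_empty_grid_rejected():
    bundle, _ = make_ground_truth_bundle(2)
    with pytest.raises(ValidationError):
        profile_objective(bundle, "transitions.SG.p_relapse", [],
                          targets_from_bundle(bundle, strategies=["SG"]))


def test_weight_rescaling_leaves_argmin_unchanged():
    bundle, _ = make_ground_truth_bundle(7)
    t1 = targets_from_bundle(bundle, strategies=["SG"], weight=1.0)
    t9 = targets_from_bundle(bundle, strategies=["SG"], weight=9.0)
    start = with_params(bundle, {"transitions.SG.p_remission": 0.1,
                                 "transitions.SG.p_relapse": 0.12})
    free = [("transitions.SG.p_remission", 0.0, 0.6),
            ("transitions.SG.p_relapse", 0.0, 0.15)]
    r1 = calibrate(start, free, t1)
    r9 = calibrate(start, free, t9)
    for path in r1.params:
        assert r1.params[path] == pytest.approx(r9.params[path], abs=1e-6)


def test_fitted_params_move_continuously_with_targets():
    bundle, _ = make_ground_truth_bundle(4)
    base_targets = targets_from_bundle(bundle, strategies=["SG"])
    bumped = [CalibrationTarget(t.quantity, t.strategy, t.perspective,
                                t.value * (1 + 1e-8), t.weight)
              for t in base_targets]
    free = [("transitions.SG.p_remission", 0.0, 0.6),
            ("transitions.SG.p_relapse", 0.0, 0.15)]
    r0 = calibrate(bundle, free, base_targets)
    r1 = calibrate(bundle, free, bumped)
    for path in r0.params:
        assert abs(r0.params[path] - r1.params[path]) < 1e-3


def test_needs_enough_targets():
    bundle, _ = make_ground_truth_bundle(1)
    one_target = targets_from_bundle(bundle, strategies=["SG"])[:1]
    with pytest.raises(ValidationError):
        calibrate(bundle, [("transitions.SG.p_remission", 0.0, 0.6),
                           ("transitions.SG.p_relapse", 0.0, 0.15)],
                  one_target)


def test_targets_csv_round_trip(tmp_path):
    import pandas as pd
    df = pd.DataFrame({
        "quantity": ["total_cost", "total_qaly"],
        "strategy": ["SG", "SG"],
        "perspective": ["SUT", "SUT"],
        "value": [4043.8, 12.68],
        "weight": [1.0, 2.0],
    })
    path = tmp_path / "targets.csv"
    df.to_csv(path, index=False)
    targets = read_targets_csv(path)
    assert targets[0].value == 4043.8
    assert targets[1].weight == 2.0
    assert targets[1].perspective is Perspective.SUT
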
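"""Transition matrices, cohort trace, microsimulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remarkov.engine import run_cohort, run_microsim, transition_matrix
from remarkov.parameters import ModelConfig, TransitionParams
from remarkov.states import STATE_INDEX, HealthState
from remarkov.synthetic import make_ground_truth_bundle
from remarkov.errors import CoverageError

from conftest import constant_life_table, simple_params

I_T, I_R, I_D = (STATE_INDEX[HealthState.T2DM],
                 STATE_INDEX[HealthState.REMISSION],
                 STATE_INDEX[HealthState.DEAD])


class TestTransitionMatrix:
    def test_lockout_blocks_remission_in_early_cycles(self, immortal_life_table):
        p = simple_params(p_remission=0.3)
        for cycle in (1, 2):
            m = transition_matrix(p, cycle, 40 + cycle - 1, immortal_life_table)
            np.testing.assert_allclose(m[I_T], [1.0, 0.0, 0.0])
        m3 = transition_matrix(p, 3, 42, immortal_life_table)
        assert m3[I_T, I_R] == pytest.approx(0.3)

    def test_death_first_composition(self):
        lt = constant_life_table(0.1)
        p = simple_params(p_remission=0.3)
        m = transition_matrix(p, 3, 42, lt)
        # death first: surviving mass (1-q) splits by p_remission
        np.testing.assert_allclose(m[I_T], [0.63, 0.27, 0.10])

    def test_dead_row_is_absorbing(self):
        lt = constant_life_table(0.2)
        m = transition_matrix(simple_params(0.5, 0.5), 7, 46, lt)
        np.testing.assert_array_equal(m[I_D], [0.0, 0.0, 1.0])

    def test_relapse_row(self):
        lt = constant_life_table(0.1)
        m = transition_matrix(simple_params(0.0, 0.2), 5, 44, lt)
        np.testing.assert_allclose(m[I_R], [0.9 * 0.2, 0.9 * 0.8, 0.1])

    def test_perioperative_mortality_applies_in_cycle_one_only(self):
        lt = constant_life_table(0.1)
        p = simple_params(p_periop_death=0.05)
        m1 = transition_matrix(p, 1, 40, lt)
        assert m1[I_T, I_D] == pytest.approx(1 - 0.95 * 0.9)
        m2 = transition_matrix(p, 2, 41, lt)
        assert m2[I_T, I_D] == pytest.approx(0.1)

    def test_hazard_ratio_scales_and_caps(self):
        lt = constant_life_table(0.4)
        m = transition_matrix(simple_params(mortality_hr_t2dm=3.0), 4, 43, lt)
        assert m[I_T, I_D] == 1.0  # capped at 1

    def test_age_outside_table_raises(self, immortal_life_table):
        with pytest.raises(CoverageError):
            transition_matrix(simple_params(), 1, 120, immortal_life_table)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(p_rem=st.floats(0, 1), p_rel=st.floats(0, 1), q=st.floats(0, 1),
           hr=st.floats(0, 3), cycle=st.integers(1, 60))
    def test_rows_are_distributions(self, p_rem, p_rel, q, hr, cycle):
        lt = constant_life_table(q)
        p = simple_params(p_rem, p_rel, mortality_hr_t2dm=hr,
                          mortality_hr_remission=hr)
        m = transition_matrix(p, cycle, 40 + (cycle - 1) % 60, lt)
        assert np.all(m >= 0) and np.all(m <= 1)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)


class TestCohortTrace:
    def test_no_exits_stays_put(self, immortal_life_table, default_config):
        trace = run_cohort(simple_params(), immortal_life_table, default_config)
        np.testing.assert_array_equal(trace.occupancy[:, I_T], 1.0)
        assert trace.occupancy.shape == (61, 3)

    def test_certain_death_absorbs_immediately(self, default_config):
        lt = constant_life_table(1.0)
        trace = run_cohort(simple_params(), lt, default_config)
        np.testing.assert_array_equal(trace.occupancy[0], [1, 0, 0])
        np.testing.assert_array_equal(trace.occupancy[1:, I_D], 1.0)

    def test_post_lockout_geometric_decay(self, immortal_life_table,
                                          default_config):
        trace = run_cohort(simple_params(p_remission=0.5),
                           immortal_life_table, default_config)
        np.testing.assert_allclose(trace.occupancy[3:6, I_T],
                                   [0.5, 0.25, 0.125])

    def test_attained_ages(self, immortal_life_table, default_config):
        trace = run_cohort(simple_params(), immortal_life_table, default_config)
        assert trace.ages[0] == 40
        assert trace.ages[1] == 40  # age during cycle 1
        assert trace.ages[60] == 99

    def test_trace_frame_schema(self, immortal_life_table, default_config):
        df = run_cohort(simple_params(), immortal_life_table,
                        default_config).to_frame()
        assert list(df.columns) == ["cycle", "age", "prop_t2dm",
                                    "prop_remission", "prop_dead"]
        assert len(df) == 61

    @pytest.mark.parametrize("seed", range(20))
    def test_invariants_on_random_bundles(self, seed):
        bundle, _ = make_ground_truth_bundle(seed)
        for sid in bundle.strategies:
            trace = run_cohort(bundle.transitions[sid], bundle.life_table,
                               bundle.config)
            occ = trace.occupancy
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(occ[:, I_D]) >= 0)
            assert np.all(np.diff(occ[:, I_D])[1:] > 0)  # qx > 0 everywhere
            assert occ[1, I_R] == 0.0 and occ[2, I_R] == 0.0


class TestMicrosim:
    def test_certain_death(self, bundle):
        cfg = ModelConfig(horizon=5)
        lt = constant_life_table(1.0)
        res = run_microsim(simple_params(), lt, cfg, bundle.schedule("PT"),
                           bundle.utilities, 50, seed=1)
        assert np.all(res.paths[:, 1:] == I_D)
        assert res.mean_life_years == 0.0

    def test_same_seed_reproduces_paths(self, bundle):
        args = (bundle.transitions["SG"], bundle.life_table, bundle.config,
                bundle.schedule("SG"), bundle.utilities, 200)
        a = run_microsim(*args, seed=11)
        b = run_microsim(*args, seed=11)
        np.testing.assert_array_equal(a.paths, b.paths)
        assert a.mean_cost == b.mean_cost

    def test_lockout_holds_in_paths(self, bundle):
        res = run_microsim(bundle.transitions["SG"], bundle.life_table,
                           bundle.config, bundle.schedule("SG"),
                           bundle.utilities, 500, seed=3)
        assert np.all(res.paths[:, 0] == I_T)
        assert not np.any(res.paths[:, 1:3] == I_R)
        assert np.any(res.paths[:, 3:] == I_R)  # remission reachable after
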
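"""Unit tests of the perception-decision operations and the engine contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import migrasim as m
from migrasim.dynamics import (
    apply_peer_threshold,
    attitude,
    classify_destination,
    event_impact,
    household_probability,
    migration_probability,
    perceived_impact,
    sample_initial_decision,
)
from migrasim.population import ConfigurationError

from conftest import make_events, make_world


class TestEventImpact:
    def test_unit_denominators(self):
        assert event_impact(1.0, 1, 1.0, tau=3.0, delta=2.0) == pytest.approx(1.0)

    def test_simple_hand_values(self):
        # floors at 1 leave dt=2, ds=4 untouched
        assert event_impact(2.0, 2, 4.0, tau=1.0 + 1e-12, delta=1.0 + 1e-12) == pytest.approx(0.25)
        assert event_impact(3.0, 2, 2.0, tau=2.0, delta=3.0) == pytest.approx(3.0 / (4.0 * 8.0))

    def test_decreasing_in_distance_and_time(self):
        base = event_impact(1.0, 2, 5.0, tau=2.0, delta=2.0)
        assert event_impact(1.0, 3, 5.0, tau=2.0, delta=2.0) < base
        assert event_impact(1.0, 2, 6.0, tau=2.0, delta=2.0) < base

    def test_floors_cap_the_kernel(self):
        near = event_impact(1.0, 1, 0.001, tau=2.0, delta=2.0, ds_floor_km=1.0)
        at_floor = event_impact(1.0, 1, 1.0, tau=2.0, delta=2.0, ds_floor_km=1.0)
        assert near == at_floor

    def test_future_event_rejected(self):
        with pytest.raises(ValueError):
            event_impact(1.0, 0, 1.0, tau=2.0, delta=2.0)


class TestAttitude:
    def _params(self):
        return m.ModelParameters(tau=2.0, delta=2.0)

    def test_no_events_gives_zero(self):
        empty = make_events(0, seed=0) if False else pd.DataFrame(
            columns=["event_id", "day", "latitude", "longitude", "event_type", "fatalities", "intensity"]
        )
        assert attitude(50.0, 30.0, empty, t=5, params=self._params()) == 0.0

    def test_sum_over_events(self):
        events = pd.DataFrame(
            {
                "event_id": [0, 1],
                "day": [1, 1],
                "latitude": [50.0, 50.0],
                "longitude": [30.0, 30.0],
                "event_type": ["battles"] * 2,
                "fatalities": [0, 0],
                "intensity": [1.0, 1.0],
            }
        )
        # same-location events: ds floored to 1 km, dt = 1
        f = attitude(50.0, 30.0, events, t=2, params=self._params())
        assert f == pytest.approx(2.0)

    def test_same_day_event_contributes_nothing(self):
        events = pd.DataFrame(
            {
                "event_id": [0],
                "day": [5],
                "latitude": [50.0],
                "longitude": [30.0],
                "event_type": ["battles"],
                "fatalities": [0],
                "intensity": [10.0],
            }
        )
        assert attitude(50.0, 30.0, events, t=5, params=self._params()) == 0.0

    def test_events_beyond_horizon_dropped(self):
        events = pd.DataFrame(
            {
                "event_id": [0],
                "day": [0],
                "latitude": [50.0],
                "longitude": [30.0],
                "event_type": ["battles"],
                "fatalities": [0],
                "intensity": [10.0],
            }
        )
        p = self._params()
        assert attitude(50.0, 30.0, events, t=p.event_horizon_days + 2, params=p) == 0.0


class TestPerceivedImpact:
    def test_memoryless_case(self):
        assert perceived_impact(2.0, 123.0, beta=0.5, theta=0.0) == pytest.approx(1.0)

    def test_pure_decay(self):
        assert perceived_impact(0.0, 1.0, beta=1.0, theta=0.5) == pytest.approx(0.5)

    def test_geometric_accumulation_closed_form(self):
        # constant f, started at f~(0)=beta*f: f~(t) = beta*f*(1-theta^(t+1))/(1-theta)
        beta, theta, f = 1.0, 0.5, 1.0
        ft = beta * f
        for t in range(1, 10):
            ft = perceived_impact(f, ft, beta, theta)
            closed = beta * f * (1 - theta ** (t + 1)) / (1 - theta)
            assert ft == pytest.approx(closed, abs=1e-12)
        # t = 3 hand value
        ft = beta * f
        for _ in range(3):
            ft = perceived_impact(f, ft, beta, theta)
        assert ft == pytest.approx(1.875, abs=1e-12)

    @given(
        beta=st.floats(0.1, 3.0), theta=st.floats(0.0, 0.95),
        f=st.floats(0.0, 10.0), steps=st.integers(1, 20),
    )
    def test_theta_zero_limit_and_nonnegativity(self, beta, theta, f, steps):
        ft = 0.0
        for _ in range(steps):
            ft = perceived_impact(f, ft, beta, theta)
            assert ft >= 0.0
        if theta == 0.0:
            assert ft == beta * f


class TestMigrationProbability:
    def test_logistic_anchor_at_zero(self):
        assert migration_probability(0.0, v=1.0, Q=1.0) == pytest.approx(0.5)
        assert migration_probability(0.0, v=2.0, Q=3.0) == pytest.approx(0.25)

    def test_hand_value(self):
        assert migration_probability(np.log(3.0), v=1.0, Q=1.0) == pytest.approx(0.75)

    @given(q=st.floats(0.01, 1e6))
    def test_zero_risk_anchor(self, q):
        assert migration_probability(0.0, v=1.0, Q=q) == pytest.approx(1.0 / (1.0 + q))

    @given(v=st.floats(0.01, 5.0), q=st.floats(0.01, 1e3))
    def test_strictly_increasing_and_saturating(self, v, q):
        grid = np.linspace(0.0, 5.0, 30)
        p = migration_probability(grid, v, q)
        assert (np.diff(p) > 0).all()
        assert 0.0 < p[0] <= p[-1] < 1.0
        assert migration_probability(1e6, v, q) == pytest.approx(1.0)


class TestHouseholdProbability:
    def test_mean(self):
        assert household_probability([0.2, 0.4]) == pytest.approx(0.3)
        assert household_probability([0.7]) == 0.7
        assert household_probability([0.0, 0.0, 0.0]) == 0.0

    def test_empty_household_rejected(self):
        with pytest.raises(ValueError):
            household_probability([])


class TestInitialDecision:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        assert all(sample_initial_decision(1.0, rng) == 1 for _ in range(20))
        assert all(sample_initial_decision(0.0, rng) == 0 for _ in range(20))

    def test_sample_mean_within_3_sigma(self):
        rng = np.random.default_rng(1)
        draws = [sample_initial_decision(0.5, rng) for _ in range(10_000)]
        assert 0.485 <= np.mean(draws) <= 0.515

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_initial_decision(1.5, np.random.default_rng(0))


class TestPeerThreshold:
    def test_forced_migration_branch(self):
        assert apply_peer_threshold(0, 5, i_hi=3, i_lo=1) == 1

    def test_forced_stay_branch(self):
        assert apply_peer_threshold(1, 0, i_hi=3, i_lo=1) == 0

    def test_boundary_sums_keep_own_decision(self):
        assert apply_peer_threshold(1, 2, i_hi=3, i_lo=1) == 1
        assert apply_peer_threshold(0, 2, i_hi=3, i_lo=1) == 0
        # boundaries themselves fall to "otherwise"
        assert apply_peer_threshold(1, 3, i_hi=3, i_lo=1) == 1
        assert apply_peer_threshold(0, 1, i_hi=3, i_lo=1) == 0

    @given(own=st.integers(0, 1), s=st.integers(0, 30), hi=st.integers(0, 20), lo=st.integers(0, 20))
    def test_branch_table_property(self, own, s, hi, lo):
        if lo > hi:
            lo, hi = hi, lo
        out = int(apply_peer_threshold(own, s, i_hi=hi, i_lo=lo))
        if s > hi:
            assert out == 1
        elif s < lo:
            assert out == 0
        else:
            assert out == own


class TestClassifyDestination:
    def test_degenerate_probabilities(self):
        assert classify_destination(0.3, refugee_prob=1.0) == "refugee"
        assert classify_destination(0.3, refugee_prob=0.0) == "idp"

    def test_martial_law_forces_idp(self):
        assert classify_destination(
            0.0, refugee_prob=1.0, martial_law=True,
            only_adults_are_conscription_age_males=True,
        ) == "idp"

    def test_refugee_fraction_within_3_sigma(self):
        rng = np.random.default_rng(2)
        n = 10_000
        kinds = [classify_destination(rng.random(), 0.6) for _ in range(n)]
        frac = sum(k == "refugee" for k in kinds) / n
        assert 0.585 <= frac <= 0.615


class TestEngineContracts:
    def test_null_dynamics_without_events(self):
        persons, households, graph = make_world(10, seed=1)
        params = m.ModelParameters(Q=1e9, i_lo=1, i_hi=5)
        events = pd.DataFrame(
            columns=["event_id", "day", "latitude", "longitude", "event_type", "fatalities", "intensity"]
        )
        traj = m.run_simulation(persons, households, graph, events, params, horizon=5, seed=3)
        assert traj.records.empty

    def test_frozen_household_state_unchanged(self, default_params):
        persons, households, graph = make_world(8, seed=4)
        events = make_events(10, seed=5, day_range=(0, 3))
        params = default_params.with_values(Q=2.0, v=2.0)
        traj = m.run_simulation(persons, households, graph, events, params, horizon=5, seed=6, record_state=True)
        hh = traj.household_records()
        assert len(hh) > 0
        # a household appears at most once across all days
        assert not hh["household_id"].duplicated().any()
        migrated_day = dict(zip(hh["household_id"], hh["day"]))
        idx = {h: i for i, h in enumerate(sorted(households["household_id"]))}
        for state in traj.state_history:
            for h, d in migrated_day.items():
                if state["day"] > d:
                    assert not state["m_initial"][idx[h]]
                    assert not state["m_final"][idx[h]]

    def test_saturation_bound_under_intense_conflict(self):
        persons, households, graph = make_world(50, seed=7)
        events = make_events(120, seed=8, day_range=(0, 10), spread_km=2.0)
        params = m.ModelParameters(tau=1.5, delta=1.5, v=5.0, Q=2.0)
        traj = m.run_simulation(persons, households, graph, events, params, horizon=15, seed=9)
        assert traj.migrated_person_count() <= traj.n_persons
        assert len(traj.household_records()) <= traj.n_households
        # near-total displacement expected under these conditions
        assert len(traj.household_records()) > 40

    def test_seeded_determinism(self, default_params):
        persons, households, graph = make_world(12, seed=10)
        events = make_events(8, seed=11, day_range=(0, 4))
        t1 = m.run_simulation(persons, households, graph, events, default_params, 6, seed=12)
        t2 = m.run_simulation(persons, households, graph, events, default_params, 6, seed=12)
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_cumulative_series_nondecreasing_and_members_share_fate(self, default_params):
        persons, households, graph = make_world(15, seed=13)
        events = make_events(12, seed=14, day_range=(0, 5))
        params = default_params.with_values(Q=5.0)
        traj = m.run_simulation(persons, households, graph, events, params, horizon=8, seed=15)
        series = m.daily_series(traj)
        assert (series.cumsum().diff().dropna() >= 0).all()
        for _, grp in traj.records.groupby("household_id"):
            assert grp["day"].nunique() == 1
            assert grp["migration_type"].nunique() == 1
        # every member of a migrated household is recorded
        sizes = persons.groupby("household_id").size()
        for h, grp in traj.records.groupby("household_id"):
            assert len(grp) == sizes[h]

    def test_raising_intensity_never_decreases_day1_probability(self, default_params):
        persons, households, graph = make_world(10, seed=16)
        events = make_events(6, seed=17, day_range=(0, 0))
        boosted = events.assign(intensity=events["intensity"] * 3.0)
        t_base = m.run_simulation(persons, households, graph, events, default_params, 1, seed=18, record_state=True)
        t_boost = m.run_simulation(persons, households, graph, boosted, default_params, 1, seed=18, record_state=True)
        assert (t_boost.state_history[0]["p_prime"] >= t_base.state_history[0]["p_prime"]).all()

    def test_decision_lag_shifts_crossing_day(self, default_params):
        persons, households, graph = make_world(8, seed=19)
        events = make_events(10, seed=20, day_range=(0, 2))
        params = default_params.with_values(Q=2.0, decision_lag=3)
        traj = m.run_simulation(persons, households, graph, events, params, horizon=4, seed=21)
        assert len(traj.records) > 0
        assert (traj.records["crossing_day"] - traj.records["day"] == 3).all()

    def test_martial_law_households_never_refugee(self):
        # one household of a lone 30-year-old male, one of a lone 70-year-old woman
        households = pd.DataFrame(
            {"household_id": [0, 1], "latitude": [50.0, 50.0], "longitude": [30.0, 30.001],
             "admin1": ["A", "A"], "admin2": ["A1", "A1"]}
        )
        persons = pd.DataFrame(
            {"person_id": [0, 1], "household_id": [0, 1], "age": [30, 70],
             "gender": ["male", "female"], "risk_proneness": [1.0, 1.0]}
        )
        graph = m.build_neighborhood(households, radius_km=1.0)
        events = make_events(20, seed=22, center=(50.0, 30.0), day_range=(0, 2), spread_km=1.0)
        params = m.ModelParameters(v=5.0, Q=1.5, refugee_prob=1.0, martial_law=True)
        traj = m.run_simulation(persons, households, graph, events, params, horizon=4, seed=23)
        types = dict(zip(traj.records["household_id"], traj.records["migration_type"]))
        assert types.get(0, "idp") == "idp"
        if 1 in types:
            assert types[1] == "refugee"

    def test_horizon_must_be_positive(self, default_params, small_world, small_events):
        persons, households, graph = small_world
        with pytest.raises(ConfigurationError):
            m.run_simulation(persons, households, graph, small_events, default_params, 0, seed=1)
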
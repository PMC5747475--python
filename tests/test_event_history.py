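import datetime as dt

import pytest

import waitlist_msm as wm
from waitlist_msm.event_history import (
    MalformedRecordError,
    realized_transition_counts,
)
from waitlist_msm.state_space import ActivityStatus

from conftest import make_record


DEATH = 15  # death_or_deteriorated absorbing index


class TestTrajectoryConstruction:
    def test_single_censored_interval(self, space):
        rec = make_record("a", initial_cpra=0, censor_day=365)
        traj = wm.trajectory_from_record(rec, space)
        assert len(traj) == 1
        iv = traj[0]
        assert (iv.state_index, iv.start_day, iv.end_day) == (1, 0, 365)
        assert iv.censored

    def test_status_change_then_death(self, space):
        rec = make_record(
            "a",
            initial_cpra=85,
            updates=[wm.Update(day=30, status=ActivityStatus.INACTIVE)],
            terminal_day=90,
            terminal_state=DEATH,
        )
        traj = wm.trajectory_from_record(rec, space)
        active_85 = space.index_of(3, ActivityStatus.ACTIVE)
        inactive_85 = space.index_of(3, ActivityStatus.INACTIVE)
        assert [(iv.state_index, iv.start_day, iv.end_day) for iv in traj] == [
            (active_85, 0, 30),
            (inactive_85, 30, 90),
        ]
        assert traj[0].end_state == inactive_85
        assert traj[1].end_state == DEATH

    def test_within_category_cpra_update_is_silent(self, space):
        rec = make_record(
            "a",
            initial_cpra=5,
            updates=[wm.Update(day=50, cpra=40)],
            censor_day=200,
        )
        traj = wm.trajectory_from_record(rec, space)
        assert len(traj) == 1
        assert traj[0].end_day == 200

    def test_same_day_updates_merge_into_one_transition(self, space):
        rec = make_record(
            "a",
            initial_cpra=0,
            updates=[
                wm.Update(day=30, cpra=85),
                wm.Update(day=30, status=ActivityStatus.INACTIVE),
            ],
            censor_day=100,
        )
        traj = wm.trajectory_from_record(rec, space)
        assert len(traj) == 2
        assert traj[1].state_index == space.index_of(3, ActivityStatus.INACTIVE)

    def test_terminal_on_listing_day_shifts_half_day(self, space):
        rec = make_record("a", terminal_day=0, terminal_state=DEATH)
        traj = wm.trajectory_from_record(rec, space)
        assert len(traj) == 1
        assert traj[0].end_day == 0.5
        assert traj[0].end_state == DEATH

    def test_update_after_terminal_rejected(self, space):
        with pytest.raises(MalformedRecordError):
            make_record(
                "a",
                updates=[wm.Update(day=120, cpra=90)],
                terminal_day=90,
                terminal_state=DEATH,
            )

    def test_terminal_and_censor_mutually_exclusive(self):
        with pytest.raises(MalformedRecordError):
            make_record("a", terminal_day=10, terminal_state=DEATH, censor_day=20)


class TestCohortFilter:
    def test_eligibility_rules(self):
        inside = dt.date(2010, 6, 1)
        records = [
            make_record("age18", age_at_listing=18.0, censor_day=10, listing_date=inside),
            make_record("multi", multi_organ=True, censor_day=10, listing_date=inside),
            make_record("relist", first_time=False, censor_day=10, listing_date=inside),
            make_record(
                "outside", censor_day=10, listing_date=dt.date(2020, 1, 1)
            ),
            make_record("ok", censor_day=10, listing_date=inside),
        ]
        kept = wm.filter_cohort(records, dt.date(2009, 10, 1), dt.date(2013, 12, 4))
        assert [r.subject_id for r in kept] == ["ok"]


class TestCensoringSchemes:
    def make_death_at_500(self):
        return make_record(
            "a",
            listing_date=dt.date(2014, 1, 1),
            terminal_day=500,
            terminal_state=DEATH,
        )

    def test_policy_censoring_truncates_terminal(self, space):
        rec = self.make_death_at_500()
        scheme = wm.CensoringScheme(
            policy_date=dt.date(2015, 2, 5), censor_at_policy=True  # day 400
        )
        traj = wm.apply_censoring(wm.trajectory_from_record(rec, space), rec, scheme)
        assert len(traj) == 1
        assert traj[0].end_day == 400
        assert traj[0].censored

    def test_lifted_censoring_keeps_terminal(self, space):
        rec = self.make_death_at_500()
        scheme = wm.CensoringScheme(
            policy_date=dt.date(2015, 2, 5), censor_at_policy=False
        )
        traj = wm.apply_censoring(wm.trajectory_from_record(rec, space), rec, scheme)
        assert traj[-1].end_day == 500
        assert traj[-1].end_state == DEATH

    def test_trajectory_before_boundary_unchanged(self, space):
        rec = make_record("a", listing_date=dt.date(2014, 1, 1), censor_day=100)
        scheme = wm.CensoringScheme(
            policy_date=dt.date(2015, 2, 5), censor_at_policy=True
        )
        traj = wm.trajectory_from_record(rec, space)
        assert wm.apply_censoring(traj, rec, scheme) == traj

    def test_policy_before_listing_empties_subject(self, space):
        rec = make_record("a", listing_date=dt.date(2015, 6, 1), censor_day=100)
        scheme = wm.CensoringScheme(
            policy_date=dt.date(2014, 12, 4), censor_at_policy=True
        )
        assert wm.apply_censoring(wm.trajectory_from_record(rec, space), rec, scheme) == []

    @pytest.mark.parametrize("horizon", [None, 250])
    def test_idempotence(self, space, horizon):
        rec = self.make_death_at_500()
        scheme = wm.CensoringScheme(
            policy_date=dt.date(2015, 2, 5),
            censor_at_policy=True,
            admin_horizon_day=horizon,
        )
        once = wm.apply_censoring(wm.trajectory_from_record(rec, space), rec, scheme)
        assert wm.apply_censoring(once, rec, scheme) == once


class TestTransitionTable:
    def test_active_state_expands_to_15_rows(self, structure):
        rec = make_record("a", terminal_day=100, terminal_state=DEATH)
        table = wm.prepare_transition_table([rec], structure)
        assert len(table) == 15
        assert (table["t_start"] == 0).all()
        assert (table["t_stop"] == 100).all()
        assert table["status"].sum() == 1
        assert table.loc[table["status"] == 1, "to_index"].item() == DEATH

    def test_inactive_state_expands_to_14_rows_no_deceased_donor(self, structure):
        rec = make_record(
            "a", initial_status=ActivityStatus.INACTIVE, censor_day=50
        )
        table = wm.prepare_transition_table([rec], structure)
        assert len(table) == 14
        assert 13 not in set(table["to_index"])
        assert table["status"].sum() == 0

    def test_row_validity_invariants(self, val_table, structure):
        assert (val_table["t_start"] < val_table["t_stop"]).all()
        allowed = {(f, t) for f, t, _i in structure.entries}
        assert set(zip(val_table["from_index"], val_table["to_index"])) <= allowed
        per_interval = val_table.groupby(["subject_id", "t_start", "from_index"])[
            "status"
        ].sum()
        assert per_interval.isin([0, 1]).all()

    def test_round_trip_event_counts_match_simulator(self, structure, val_scenario):
        paths = wm.simulate_paths(val_scenario)
        records = wm.simulate_cohort(val_scenario)
        expected: dict[int, int] = {}
        for p in paths:
            for f, t in p.transitions:
                tid = structure.transition_id(f, t)
                expected[tid] = expected.get(tid, 0) + 1
        observed = dict(realized_transition_counts(records, structure))
        assert observed == expected
        table = wm.prepare_transition_table(records, structure)
        from_table = (
            table.loc[table["status"] == 1].groupby("transition_id").size().to_dict()
        )
        assert from_table == expected

    def test_time_at_risk_matches_occupancy(self, structure):
        rec = make_record(
            "a",
            initial_cpra=85,
            updates=[wm.Update(day=30, status=ActivityStatus.INACTIVE)],
            terminal_day=90,
            terminal_state=DEATH,
        )
        table = wm.prepare_transition_table([rec], structure)
        at_risk = (
            table.drop_duplicates(["subject_id", "from_index", "t_start"])
            .assign(dur=lambda d: d["t_stop"] - d["t_start"])
            .groupby("from_index")["dur"]
            .sum()
        )
        assert at_risk.to_dict() == {5: 30.0, 6: 60.0}
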
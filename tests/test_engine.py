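"""Event-loop core: hand-computed timelines, capacity invariants, monotonicity."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from eplabsim import engine
from eplabsim.engine import (
    MINUTES_PER_DAY,
    Patient,
    interleave_admissions,
    plan_procedure_day,
    run_replication,
    schedule_lab_day,
)
from eplabsim.input_model import ArrivalSpec, Horizon, ResourceSet, default_config
from eplabsim.replication_stats import run_batch
from eplabsim.scenarios import (
    DurationModification,
    cls_wards_base,
    validation_scenario,
)


def make_patient(pid, op_minutes, cleanup=10.0, planned_day=2, arrival_day=1,
                 los=3, preop=1):
    return Patient(
        id=pid, patient_class="TEP", arrival_day=arrival_day, los_days=los,
        procedure_class="Test", preop_days=preop, operative_minutes=op_minutes,
        cleanup_minutes=cleanup, planned_day=planned_day, scheduled_day=planned_day,
    )


class TestScheduleLabDayOracle:
    """Timelines on tiny constant-duration instances, checked by hand."""

    def test_single_slot_sequential_with_cleanup(self, cfg):
        # day 2 (Monday): open 08:00.  p0: 08:00-09:00; lab free 09:10 after
        # clean-up, physician free 09:00 -> p1 starts 09:10, ends 10:10.
        cal = cfg.calendar
        q = {"A": deque([make_patient(0, 60.0), make_patient(1, 60.0)])}
        lab_free = [0.0]
        started, rolled = schedule_lab_day(q, lab_free, 2, cal)
        day0 = 2 * MINUTES_PER_DAY
        assert [(p.id, s - day0, e - day0) for p, s, e, _ in started] == [
            (0, 480.0, 540.0),
            (1, 550.0, 610.0),
        ]
        assert rolled == []
        assert lab_free[0] == day0 + 610.0 + 10.0

    def test_two_labs_two_slots_run_in_parallel(self, cfg):
        cal = cfg.calendar
        q = {
            "A": deque([make_patient(0, 120.0)]),
            "B": deque([make_patient(1, 90.0)]),
        }
        started, rolled = schedule_lab_day(q, [0.0, 0.0], 2, cal)
        day0 = 2 * MINUTES_PER_DAY
        times = {p.id: (s - day0, e - day0) for p, s, e, _ in started}
        assert times == {0: (480.0, 600.0), 1: (480.0, 570.0)}

    def test_full_window_procedures_block_second_round(self, cfg):
        # 840-minute procedures fill the whole 08:00-22:00 window: with two
        # labs and two slots exactly two of four queued patients start.
        cal = cfg.calendar
        q = {
            "A": deque([make_patient(0, 840.0), make_patient(2, 840.0)]),
            "B": deque([make_patient(1, 840.0), make_patient(3, 840.0)]),
        }
        started, rolled = schedule_lab_day(q, [0.0, 0.0], 2, cal)
        assert sorted(p.id for p, *_ in started) == [0, 1]
        assert sorted(p.id for p in rolled) == [2, 3]

    def test_last_start_strictly_before_closing(self, cfg):
        # first procedure ends 21:59 with zero clean-up: the next may start
        # 21:59.  With one minute of clean-up the lab frees at 22:00 exactly
        # and the next patient must roll to the following workday.
        cal = cfg.calendar
        day0 = 2 * MINUTES_PER_DAY
        q = {"A": deque([make_patient(0, 839.0, cleanup=0.0), make_patient(1, 60.0)])}
        started, rolled = schedule_lab_day(q, [0.0], 2, cal)
        assert [(p.id, s - day0) for p, s, e, _ in started] == [(0, 480.0), (1, 1319.0)]
        assert started[-1][2] - day0 == 1319.0 + 60.0  # runs past 22:00

        q = {"A": deque([make_patient(0, 839.0, cleanup=1.0), make_patient(1, 60.0)])}
        started, rolled = schedule_lab_day(q, [0.0], 2, cal)
        assert [p.id for p, *_ in started] == [0]
        assert [p.id for p in rolled] == [1]

    def test_fifo_tie_break_across_slots(self, cfg):
        # one lab, both slot heads ready at open: the earlier-planned
        # patient goes first regardless of slot
        cal = cfg.calendar
        early = make_patient(5, 60.0, planned_day=1)
        late = make_patient(2, 60.0, planned_day=2)
        q = {"A": deque([late]), "B": deque([early])}
        started, _ = schedule_lab_day(q, [0.0], 2, cal)
        assert [p.id for p, *_ in started] == [5, 2]


class TestPlanProcedureDay:
    def test_preop_one_day_next_day(self, cfg):
        # day 2 is a Monday in the default calendar
        assert plan_procedure_day(2, 1, cfg.calendar) == 3

    def test_friday_preop_rolls_over_weekend(self, cfg):
        # day 6 = Friday; candidate Saturday -> next Monday (day 9)
        assert plan_procedure_day(6, 1, cfg.calendar) == 9

    def test_zero_preop_same_day(self, cfg):
        assert plan_procedure_day(4, 0, cfg.calendar) == 4

    def test_zero_preop_on_weekend_advances(self, cfg):
        assert plan_procedure_day(7, 0, cfg.calendar) == 9


class TestInterleaveAdmissions:
    def test_one_bed_two_arrivals(self, rng):
        admitted, excess = interleave_admissions({"TEP": 2}, 1, rng)
        assert admitted == {"TEP": 1}
        assert excess == {"TEP": 1}

    def test_no_arrivals_no_change(self, rng):
        admitted, excess = interleave_admissions({"TEP": 0, "NEP": 0}, 5, rng)
        assert admitted == {"TEP": 0, "NEP": 0}
        assert excess == {"TEP": 0, "NEP": 0}

    def test_all_admitted_when_beds_sufficient(self, rng):
        admitted, excess = interleave_admissions({"TEP": 3, "CLEP": 4}, 10, rng)
        assert admitted == {"TEP": 3, "CLEP": 4}
        assert sum(excess.values()) == 0

    def test_interleaving_is_unbiased(self):
        # with 1 bed and one arrival of each class, each class should win
        # the bed about half the time
        rng = np.random.default_rng(0)
        wins = sum(
            interleave_admissions({"TEP": 1, "NEP": 1}, 1, rng)[0]["TEP"]
            for _ in range(4000)
        )
        assert 0.45 < wins / 4000 < 0.55


@pytest.fixture(scope="module")
def traced(small_cfg):
    return {
        "validation": run_replication(
            small_cfg, validation_scenario(), seed=11, trace=True
        ),
        "wards": run_replication(small_cfg, cls_wards_base(), seed=11, trace=True),
    }


class TestReplicationInvariants:
    def test_conservation(self, traced):
        for res in traced.values():
            assert res.total_tep_discharges == res.daily_discharges.sum()
            assert res.total_tep_discharges >= 0

    def test_bed_capacity_never_violated(self, small_cfg, traced):
        for res in traced.values():
            assert res.occupancy.max() <= small_cfg.resources.beds
            assert res.occupancy.min() >= 0

    def test_sampled_durations_within_bounds(self, small_cfg, traced):
        by_name = {pc.name: pc for pc in small_cfg.procedure_classes}
        for res in traced.values():
            for p in res.patients:
                pc = by_name[p.procedure_class]
                assert pc.operative_time.min <= p.operative_minutes <= pc.operative_time.max
                assert pc.length_of_stay.min <= p.los_days <= pc.length_of_stay.max
                assert p.preop_days <= p.los_days
                assert p.preop_days >= min(pc.preop_stay.min, p.los_days)

    def test_procedures_inside_working_hours_on_workdays(self, small_cfg, traced):
        cal = small_cfg.calendar
        for res in traced.values():
            for p in res.patients:
                if p.procedure_day is None:
                    continue
                assert cal.is_workday(p.procedure_day)
                assert cal.lab_open_min <= p.procedure_start < cal.lab_close_min
                assert p.procedure_end == pytest.approx(
                    p.procedure_start + p.operative_minutes
                )

    def test_discharge_day_is_procedure_day_plus_postop(self, traced):
        for res in traced.values():
            for p in res.patients:
                if p.procedure_day is None:
                    continue
                assert p.discharge_day == p.procedure_day + (p.los_days - p.preop_days)

    def test_lab_and_physician_concurrency(self, small_cfg, traced):
        for res in traced.values():
            intervals = []  # lab occupancy: procedure + clean-up
            by_day_slot = {}
            for p in res.patients:
                if p.procedure_day is None:
                    continue
                s = p.procedure_day * MINUTES_PER_DAY + p.procedure_start
                e = s + p.operative_minutes
                intervals.append((s, e + p.cleanup_minutes))
                by_day_slot.setdefault((p.procedure_day, p.physician_slot), []).append(
                    (s, e)
                )
            # physician: one procedure at a time per on-duty slot
            for spans in by_day_slot.values():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert s2 >= e1
            # labs: concurrent occupancy never exceeds the lab count
            edges = [(s, +1) for s, _ in intervals] + [(e, -1) for _, e in intervals]
            load, peak = 0, 0
            for _, delta in sorted(edges, key=lambda t: (t[0], t[1])):
                load += delta
                peak = max(peak, load)
            assert peak <= small_cfg.resources.labs

    def test_saturating_regime_fills_beds(self, small_cfg, traced):
        # once TEP generation starts, the morning census sits at capacity
        res = traced["wards"]
        after_warmup = res.occupancy[small_cfg.horizon.warmup_days:]
        assert (after_warmup == small_cfg.resources.beds).all()

    def test_balk_policy_records_balks(self, small_cfg):
        balk_cfg = replace(small_cfg, bed_policy="balk")
        res = run_replication(balk_cfg, cls_wards_base(), seed=11)
        assert res.queued == {"TEP": 0, "CLEP": 0, "NEP": 0}
        assert sum(res.balked.values()) > 0


class TestDeterminismAndEdgeCases:
    def test_same_seed_same_replication(self, small_cfg):
        a = run_replication(small_cfg, validation_scenario(), seed=99)
        b = run_replication(small_cfg, validation_scenario(), seed=99)
        assert a.total_tep_discharges == b.total_tep_discharges
        np.testing.assert_array_equal(a.daily_discharges, b.daily_discharges)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_vanishing_tep_arrivals_give_zero_discharges(self, small_cfg):
        cfg = replace(
            small_cfg,
            arrivals={
                **small_cfg.arrivals,
                "TEP": ArrivalSpec(patient_class="TEP", mean=1e-9, sd=0.0),
            },
        )
        res = run_replication(cfg, validation_scenario(), seed=3)
        assert res.total_tep_discharges == 0

    def test_no_tep_before_warmup_ends(self, small_cfg):
        res = run_replication(small_cfg, validation_scenario(), seed=21, trace=True)
        assert all(p.arrival_day > small_cfg.horizon.warmup_days for p in res.patients)


class TestMonotonicity:
    """Paired common seeds: more resources never reduce mean throughput."""

    def test_more_beds_more_discharges(self, small_cfg):
        means = []
        for beds in (70, 87, 100):
            cfg = replace(small_cfg, resources=ResourceSet(beds=beds, labs=2))
            means.append(run_batch(cfg, cls_wards_base(), 40, 3).mean_total)
        assert means[0] <= means[1] <= means[2]

    def test_more_labs_more_discharges(self, small_cfg):
        means = []
        for labs in (1, 2, 3):
            cfg = replace(small_cfg, resources=ResourceSet(beds=110, labs=labs))
            means.append(run_batch(cfg, cls_wards_base(), 40, 3).mean_total)
        assert means[0] <= means[1] <= means[2]
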
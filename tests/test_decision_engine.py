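"""Decision rules, weather classification, goal checks and the daily loop."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jitaikit.decision_engine import (
    ActivityGoal,
    ActivitySnapshot,
    DecisionContext,
    ForecastBlock,
    ForecastCoverageError,
    JitaiEngine,
    RuleTableError,
    WeatherForecast,
    classify_weather,
    default_rule_table,
    enumerate_contexts,
    evaluate,
    goal_progress,
    rule_table_from_records,
)
from jitaikit.message_bank import SendHistory
from jitaikit.types import DeliveryStatus, GoalKind, Slot, WeatherClass

from _oracles import expected_rule_id
from conftest import DAY, FnActivitySource


def _forecast(probs, start_hour=0, day=DAY):
    blocks = [
        ForecastBlock(
            dt.datetime.combine(day, dt.time(0, 0)) + dt.timedelta(hours=start_hour + 3 * i),
            p,
        )
        for i, p in enumerate(probs)
    ]
    return WeatherForecast(tuple(blocks))


def _snapshot(steps=0, minutes=0.0, hour=12):
    when = dt.datetime.combine(DAY, dt.time(hour, 0))
    return ActivitySnapshot(
        as_of=when, steps_today=steps, active_minutes_today=minutes,
        last_sync=when - dt.timedelta(minutes=15),
    )


class TestClassifyWeather:
    def test_all_dry_is_good(self):
        fc = _forecast([0.0] * 8)
        start = dt.datetime.combine(DAY, dt.time(12, 30))
        assert classify_weather(fc, start, 4) is WeatherClass.GOOD

    def test_exactly_half_is_bad(self):
        # "good" requires strictly below 50% chance of rain
        fc = _forecast([0.1, 0.1, 0.1, 0.1, 0.5, 0.1, 0.1, 0.1])
        start = dt.datetime.combine(DAY, dt.time(12, 30))  # touches blocks 12-15, 15-18
        assert classify_weather(fc, start, 4) is WeatherClass.BAD

    def test_max_over_intersecting_blocks(self):
        fc = _forecast([0.2, 0.4, 0.45], start_hour=12)
        start = dt.datetime.combine(DAY, dt.time(12, 30))
        assert classify_weather(fc, start, 4) is WeatherClass.GOOD

    def test_uncovered_window_raises(self):
        fc = _forecast([0.2, 0.2], start_hour=0)  # covers 00:00-06:00 only
        start = dt.datetime.combine(DAY, dt.time(12, 30))
        with pytest.raises(ForecastCoverageError):
            classify_weather(fc, start, 4)

    def test_gap_in_coverage_raises(self):
        blocks = _forecast([0.2], start_hour=12).blocks + _forecast([0.2], start_hour=18).blocks
        fc = WeatherForecast(blocks)
        with pytest.raises(ForecastCoverageError):
            classify_weather(fc, dt.datetime.combine(DAY, dt.time(12, 30)), 6)


class TestGoalProgress:
    def test_zero_steps_not_met(self, steps_goal):
        assert goal_progress(_snapshot(steps=0), steps_goal) is False

    def test_boundary_equal_is_met(self, steps_goal):
        assert goal_progress(_snapshot(steps=4950), steps_goal) is True

    def test_minutes_goal_ignores_steps(self):
        goal = ActivityGoal(GoalKind.ACTIVE_MINUTES, 10, baseline=22.0, set_date=DAY)
        assert goal_progress(_snapshot(steps=0, minutes=32.0), goal) is True
        assert goal_progress(_snapshot(steps=99999, minutes=10.0), goal) is False

    @given(steps=st.integers(0, 20_000), extra=st.integers(0, 5_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_raising_steps_never_unmeets(self, steps, extra):
        goal = ActivityGoal(GoalKind.STEPS, 500, baseline=4000.0, set_date=DAY)
        if goal_progress(_snapshot(steps=steps), goal):
            assert goal_progress(_snapshot(steps=steps + extra), goal)


class TestRuleTable:
    def test_structure_1_8_4(self):
        rules = default_rule_table()
        assert len(rules) == 13
        by_option = {opt: sum(r.option == opt for r in rules) for opt in (1, 2, 3)}
        assert by_option == {1: 1, 2: 8, 3: 4}
        assert sorted(r.rule_id for r in rules) == list(range(1, 14))

    def test_agrees_with_truth_table_oracle(self):
        rules = default_rule_table()
        for ctx in enumerate_contexts():
            fired = evaluate(ctx, rules)
            expected = expected_rule_id(
                ctx.slot, ctx.goal_kind, ctx.goal_met, ctx.weather_class,
                ctx.congratulated_today,
            )
            got = fired.rule_id if fired else None
            assert got == expected, f"context {ctx}"

    def test_partition_never_double_fires(self):
        rules = default_rule_table()
        for ctx in enumerate_contexts():
            assert sum(r.matches(ctx) for r in rules) <= 1

    def test_overlapping_table_rejected(self):
        records = [r.to_record() for r in default_rule_table()]
        records[1]["weather"] = None  # steps/midday rule now fires in any weather
        with pytest.raises(RuleTableError, match="not a partition"):
            rule_table_from_records(records)

    def test_roundtrip_through_records(self):
        rules = default_rule_table()
        again = rule_table_from_records([r.to_record() for r in rules])
        assert again == rules

    def test_examples(self):
        rules = default_rule_table()
        met_hourly = DecisionContext(Slot.HOURLY, GoalKind.STEPS, True, None, False)
        assert evaluate(met_hourly, rules).option == 1
        midday = DecisionContext(Slot.MIDDAY, GoalKind.STEPS, False, WeatherClass.GOOD, False)
        fired = evaluate(midday, rules)
        assert fired.option == 2 and fired.pool_id == "steps_midday_good"
        night_met = DecisionContext(Slot.NIGHT, GoalKind.STEPS, True, WeatherClass.GOOD, False)
        assert evaluate(night_met, rules) is None


def _engine(bank, **kw):
    return JitaiEngine(bank=bank, **kw)


def _run(bank, profile, goal, source, weather, seed=3, **kw):
    return _engine(bank, **kw).run_day(
        profile, goal, DAY, source, weather, SendHistory(profile.participant_id),
        np.random.default_rng(seed),
    )


class TestRunDay:
    def test_never_achieving_gets_three_messages(
        self, bank, profile, steps_goal, never_active_source, good_weather
    ):
        events = _run(bank, profile, steps_goal, never_active_source, good_weather)
        messages = [e for e in events if e.is_message_event]
        assert [e.slot for e in messages] == [Slot.MIDDAY, Slot.EVENING, Slot.NIGHT]
        assert all(e.delivery_status is DeliveryStatus.DELIVERED for e in messages)
        rules = {r.rule_id: r for r in default_rule_table()}
        assert [rules[e.rule_id].option for e in messages] == [2, 2, 3]

    def test_meeting_at_0930_gets_one_congratulation(
        self, bank, profile, steps_goal, good_weather
    ):
        crossing = dt.datetime.combine(DAY, dt.time(9, 30))
        source = FnActivitySource(steps_at=lambda t: 5000 if t >= crossing else 100)
        events = _run(bank, profile, steps_goal, source, good_weather)
        messages = [e for e in events if e.is_message_event]
        assert len(messages) == 1
        assert messages[0].rule_id == 1
        assert messages[0].timestamp == dt.datetime.combine(DAY, dt.time(10, 0))
        # the three scheduled slots are still evaluated but suppressed
        suppressed = [e for e in events if not e.is_message_event]
        assert [e.slot for e in suppressed] == [Slot.MIDDAY, Slot.EVENING, Slot.NIGHT]

    def test_no_goal_no_events(self, bank, profile, never_active_source, good_weather):
        assert _run(bank, profile, None, never_active_source, good_weather) == []

    def test_all_messages_fail_at_prob_one(
        self, bank, profile, steps_goal, never_active_source, good_weather
    ):
        events = _run(
            bank, profile, steps_goal, never_active_source, good_weather, failure_prob=1.0
        )
        messages = [e for e in events if e.is_message_event]
        assert messages and all(
            e.delivery_status is DeliveryStatus.FAILED for e in messages
        )

    def test_deterministic_under_seed(
        self, bank, profile, steps_goal, never_active_source, good_weather
    ):
        a = _run(bank, profile, steps_goal, never_active_source, good_weather, seed=9)
        b = _run(bank, profile, steps_goal, never_active_source, good_weather, seed=9)
        assert a == b

    def test_events_time_ordered(
        self, bank, profile, steps_goal, never_active_source, bad_weather
    ):
        events = _run(bank, profile, steps_goal, never_active_source, bad_weather)
        times = [e.timestamp for e in events]
        assert times == sorted(times)

    def test_bad_weather_selects_bad_weather_pools(
        self, bank, profile, steps_goal, never_active_source, bad_weather
    ):
        events = _run(bank, profile, steps_goal, never_active_source, bad_weather)
        pools = {r.rule_id: r.pool_id for r in default_rule_table()}
        assert [pools[e.rule_id] for e in events if e.is_message_event] == [
            "steps_midday_bad", "steps_evening_bad", "steps_night_bad",
        ]

    def test_night_slot_uses_tomorrows_daytime_weather(
        self, bank, profile, steps_goal, never_active_source
    ):
        class SplitWeather:
            # rainy today, dry tomorrow afternoon
            def forecast(self, location_key, when):
                blocks = []
                for d in range(3):
                    day = DAY + dt.timedelta(days=d)
                    for h in range(0, 24, 3):
                        p = 0.9 if d == 0 else 0.1
                        blocks.append(
                            ForecastBlock(dt.datetime.combine(day, dt.time(h, 0)), p)
                        )
                return WeatherForecast(tuple(blocks))

        events = _run(bank, profile, steps_goal, never_active_source, SplitWeather())
        pools = {r.rule_id: r.pool_id for r in default_rule_table()}
        night = [e for e in events if e.slot is Slot.NIGHT and e.is_message_event]
        assert pools[night[0].rule_id] == "steps_night_good"

    def test_stale_snapshot_flagged(
        self, bank, profile, steps_goal, good_weather
    ):
        source = FnActivitySource(steps_at=lambda t: 100, lag_minutes=6 * 60)
        goal = steps_goal
        events = _run(bank, profile, goal, source, good_weather)
        messages = [e for e in events if e.is_message_event]
        assert messages and all(e.stale for e in messages)

    def test_rendered_body_has_no_placeholder(
        self, bank, profile, steps_goal, never_active_source, good_weather
    ):
        crossing = dt.datetime.combine(DAY, dt.time(9, 30))
        source = FnActivitySource(steps_at=lambda t: 5000 if t >= crossing else 100)
        events = _run(bank, profile, steps_goal, source, good_weather)
        for e in events:
            if e.rendered_body:
                assert "[NAME]" not in e.rendered_body

    def test_daily_caps_over_many_seeds(
        self, bank, profile, steps_goal, good_weather
    ):
        # randomized crossing times never break the per-day caps
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cross_min = int(rng.integers(8 * 60, 22 * 60))
            crossing = dt.datetime.combine(DAY, dt.time(0, 0)) + dt.timedelta(minutes=cross_min)
            source = FnActivitySource(steps_at=lambda t, c=crossing: 9000 if t >= c else 0)
            events = _run(bank, profile, steps_goal, source, good_weather, seed=seed)
            messages = [e for e in events if e.is_message_event]
            assert sum(1 for e in messages if e.rule_id == 1) <= 1
            scheduled = [e for e in messages if e.slot is not Slot.HOURLY]
            assert len(scheduled) <= 3
            assert len(messages) <= 4
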
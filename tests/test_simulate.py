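"""Synthetic cohort, traces, weather and the end-to-end trial."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from pydantic import ValidationError

from jitaikit.scheduling import ParticipantProfile
from jitaikit.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_day_trace,
    simulate_trial,
    simulate_weather,
)
from jitaikit.decision_engine import classify_weather
from jitaikit.types import WeatherClass

from conftest import DAY


def _profile(baseline=3000.0):
    return ParticipantProfile(
        participant_id="p01", first_name="Ann", baseline_steps=baseline,
        baseline_active_minutes=25.0,
    )


class TestConfig:
    def test_invalid_probability_names_key(self):
        with pytest.raises(ValidationError, match="delivery_failure_prob"):
            SimulationConfig(delivery_failure_prob=1.5)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError, match="no_such_knob"):
            SimulationConfig(no_such_knob=1)

    def test_goal_probs_must_sum_to_one(self):
        probs = {"steps_500": 0.5, "steps_750": 0.2}
        with pytest.raises(ValidationError, match="sum"):
            SimulationConfig(goal_choice_probs=probs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_participants=7, seed=3, rain_block_prob=0.4)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestCohort:
    def test_empty_cohort(self):
        assert simulate_cohort(SimulationConfig(n_participants=0)) == []

    def test_deterministic(self):
        cfg = SimulationConfig(n_participants=12, seed=5)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_onboarding_failure_fraction(self):
        # binomial check at n=10,000: observed fraction within 3 SE of 0.13
        cfg = SimulationConfig(n_participants=10_000, seed=2, onboarding_failure_prob=0.13)
        cohort = simulate_cohort(cfg)
        frac = np.mean([p.goal is None for p in cohort])
        se = np.sqrt(0.13 * 0.87 / 10_000)
        assert abs(frac - 0.13) < 3 * se

    def test_baselines_nonnegative_and_goals_valid(self):
        cohort = simulate_cohort(SimulationConfig(n_participants=200, seed=1))
        for p in cohort:
            assert p.baseline_steps >= 0 and p.baseline_active_minutes >= 0
            if p.goal is not None:
                assert p.goal.target > p.goal.baseline


class TestDayTrace:
    def test_cumulative_non_decreasing(self):
        cfg = SimulationConfig()
        trace = simulate_day_trace(_profile(), DAY, [], cfg, np.random.default_rng(0))
        assert np.all(np.diff(trace.cumulative_steps) >= 0)
        assert np.all(np.diff(trace.cumulative_active_minutes) >= 0)

    def test_minutes_bounded_by_elapsed_time(self):
        cfg = SimulationConfig(cadence_threshold=1.0)  # every non-empty tick active
        trace = simulate_day_trace(_profile(), DAY, [], cfg, np.random.default_rng(0))
        ticks = np.arange(97)
        assert np.all(trace.cumulative_active_minutes <= ticks * 15)

    def test_mean_matches_baseline_without_receptivity(self):
        cfg = SimulationConfig(receptivity_effect=0.0)
        rng = np.random.default_rng(10)
        profile = _profile(baseline=3000.0)
        totals = [
            simulate_day_trace(profile, DAY, [], cfg, rng).daily_steps
            for _ in range(2_000)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 3000.0) < 3 * se

    def test_receptivity_adds_expected_steps(self):
        cfg = SimulationConfig(receptivity_effect=500.0, day_cv=0.0)
        rng = np.random.default_rng(11)
        profile = _profile(baseline=3000.0)
        prompt = [dt.datetime.combine(DAY, dt.time(12, 30))]
        totals = [
            simulate_day_trace(profile, DAY, prompt, cfg, rng).daily_steps
            for _ in range(2_000)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 3500.0) < 3 * se

    def test_snapshot_lags_by_sync_cadence(self):
        cfg = SimulationConfig()
        from jitaikit.simulate import ReceptiveTraceSource, _day_rates

        src = ReceptiveTraceSource(
            cadence_threshold=cfg.cadence_threshold,
            receptivity_effect=0.0,
            sync_lag_minutes=15,
            boost_rng=np.random.default_rng(1),
        )
        rng = np.random.default_rng(2)
        src.register_day("p01", DAY, rng.poisson(_day_rates(3000.0, cfg, rng)))
        snap = src.latest("p01", dt.datetime.combine(DAY, dt.time(10, 0)))
        trace = src.trace("p01", DAY)
        assert snap.steps_today == trace.steps_at(dt.datetime.combine(DAY, dt.time(9, 45)))
        assert snap.last_sync == dt.datetime.combine(DAY, dt.time(9, 45))


class TestWeather:
    def test_degenerate_dry_always_good(self):
        cfg = SimulationConfig(rain_block_prob=0.0)
        src = simulate_weather(DAY, 10, cfg, np.random.default_rng(0))
        for d in range(10):
            start = dt.datetime.combine(DAY + dt.timedelta(days=d), dt.time(12, 30))
            assert classify_weather(src.forecast("", start), start, 4) is WeatherClass.GOOD

    def test_degenerate_wet_always_bad(self):
        cfg = SimulationConfig(rain_block_prob=1.0)
        src = simulate_weather(DAY, 10, cfg, np.random.default_rng(0))
        for d in range(10):
            start = dt.datetime.combine(DAY + dt.timedelta(days=d), dt.time(12, 30))
            assert classify_weather(src.forecast("", start), start, 4) is WeatherClass.BAD

    def test_good_fraction_matches_analytic(self):
        # the 12:30+4h window touches two independent blocks:
        # P(good) = (1 - q)^2 for block-rain probability q
        q = 0.3
        cfg = SimulationConfig(rain_block_prob=q)
        n_days = 10_000
        src = simulate_weather(DAY, n_days, cfg, np.random.default_rng(123))
        good = 0
        for d in range(n_days):
            start = dt.datetime.combine(DAY + dt.timedelta(days=d), dt.time(12, 30))
            good += classify_weather(src.forecast("", start), start, 4) is WeatherClass.GOOD
        expected = (1 - q) ** 2
        se = np.sqrt(expected * (1 - expected) / n_days)
        assert abs(good / n_days - expected) < 3 * se

    def test_forecast_covers_28_hours(self):
        cfg = SimulationConfig()
        src = simulate_weather(DAY, 3, cfg, np.random.default_rng(0))
        when = dt.datetime.combine(DAY, dt.time(20, 30))
        fc = src.forecast("", when)
        assert fc.covers(when, when + dt.timedelta(hours=28))


@pytest.fixture(scope="module")
def small_logs():
    return simulate_trial(SimulationConfig(n_participants=6, seed=42))


class TestTrial:
    def test_no_failures_means_all_delivered(self):
        cfg = SimulationConfig(
            n_participants=3, seed=1, delivery_failure_prob=0.0,
            activity_call_failure_prob=0.0, weather_call_failure_prob=0.0,
        )
        logs = simulate_trial(cfg)
        msg = logs.events[logs.events.message_id != ""]
        assert set(msg.delivery_status) == {"delivered"}

    def test_deterministic_byte_identical(self, tmp_path):
        from jitaikit.io import write_bundle

        cfg = SimulationConfig(n_participants=3, seed=9)
        for run in ("a", "b"):
            write_bundle(simulate_trial(cfg), tmp_path / run)
        for name in ("events", "ema", "wear", "daily", "survey", "profiles"):
            a = (tmp_path / "a" / f"{name}.csv").read_bytes()
            b = (tmp_path / "b" / f"{name}.csv").read_bytes()
            assert a == b, name

    def test_scheduled_evaluation_count(self):
        # 27 onboarded participants who never meet their goal, 28 days:
        # 27 x 28 x 3 scheduled-slot evaluations, every one a message event
        probs = {"steps_500": 1.0}
        cfg = SimulationConfig(
            n_participants=27, seed=4, onboarding_failure_prob=0.0,
            goal_choice_probs=probs, day_cv=0.0, receptivity_effect=0.0,
            delivery_failure_prob=0.0, activity_call_failure_prob=0.0,
            weather_call_failure_prob=0.0,
        )
        logs = simulate_trial(cfg)
        scheduled = logs.events[logs.events.slot.isin(["midday", "evening", "night"])]
        assert len(scheduled) == 27 * 28 * 3 == 2268
        # a +500-step goal sits far above Poisson day noise: never met
        assert not logs.daily[logs.daily.period == "intervention"].goal_met.any()
        assert (scheduled.message_id != "").all()

    def test_no_message_events_for_unonboarded(self, small_logs):
        unonboarded = small_logs.profiles.loc[
            ~small_logs.profiles.onboarded, "participant_id"
        ]
        assert not small_logs.events.participant_id.isin(set(unonboarded)).any()

    def test_message_event_caps_per_day(self, small_logs):
        msg = small_logs.events[small_logs.events.message_id != ""].copy()
        msg["day"] = msg.timestamp.str[:10]
        per_day = msg.groupby(["participant_id", "day"])
        assert (per_day.size() <= 4).all()
        option1 = msg[msg.rule_id == 1].groupby(["participant_id", "day"]).size()
        assert (option1 <= 1).all()

    def test_periods_partition_timeline(self, small_logs):
        cfg = small_logs.config
        per = small_logs.daily.groupby("period").size() / cfg.n_participants
        assert per["baseline"] == cfg.baseline_days
        assert per["intervention"] == 28
        assert per["followup"] == cfg.followup_days
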
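"""Shared fixtures: the packaged bank, deterministic fake data sources,
and a fixture participant."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pytest

from jitaikit.decision_engine import (
    ActivityGoal,
    ActivitySnapshot,
    ForecastBlock,
    WeatherForecast,
)
from jitaikit.message_bank import MessageBank, load_default_bank
from jitaikit.scheduling import ParticipantProfile
from jitaikit.types import GoalKind

DAY = dt.date(2020, 9, 7)  # a Monday


@pytest.fixture(scope="session")
def bank() -> MessageBank:
    return load_default_bank()


@pytest.fixture
def profile() -> ParticipantProfile:
    return ParticipantProfile(
        participant_id="p01",
        first_name="Ann",
        postal_code="PC01",
        baseline_steps=4200.0,
        baseline_active_minutes=22.0,
    )


@pytest.fixture
def steps_goal() -> ActivityGoal:
    return ActivityGoal(kind=GoalKind.STEPS, increment=750, baseline=4200.0, set_date=DAY)


@dataclass
class FnActivitySource:
    """Activity repository driven by a steps-vs-time function; minutes
    scale with steps. ``last_sync`` trails the query by ``lag_minutes``."""

    steps_at: Callable[[dt.datetime], int]
    minutes_at: Callable[[dt.datetime], float] | None = None
    lag_minutes: int = 15

    def latest(self, participant_id: str, when: dt.datetime) -> ActivitySnapshot:
        sync = when - dt.timedelta(minutes=self.lag_minutes)
        floor = dt.datetime.combine(when.date(), dt.time(0, 0))
        sync = max(sync, floor)
        steps = int(self.steps_at(sync))
        minutes = float(self.minutes_at(sync)) if self.minutes_at else steps / 100.0
        return ActivitySnapshot(
            as_of=when, steps_today=steps, active_minutes_today=minutes, last_sync=sync
        )


@dataclass
class ConstantWeatherSource:
    """Forecast provider with one constant precipitation probability
    everywhere (covers any 28-hour horizon)."""

    precip_prob: float

    def forecast(self, location_key: str, when: dt.datetime) -> WeatherForecast:
        day0 = dt.datetime.combine(when.date(), dt.time(0, 0))
        blocks = [
            ForecastBlock(day0 + dt.timedelta(hours=h), self.precip_prob)
            for h in range(0, 72, 3)
        ]
        return WeatherForecast(tuple(blocks))


@pytest.fixture
def never_active_source() -> FnActivitySource:
    return FnActivitySource(steps_at=lambda t: 100, minutes_at=lambda t: 1.0)


@pytest.fixture
def good_weather() -> ConstantWeatherSource:
    return ConstantWeatherSource(0.1)


@pytest.fixture
def bad_weather() -> ConstantWeatherSource:
    return ConstantWeatherSource(0.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
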
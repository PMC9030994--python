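"""Synthetic-cohort simulator: participants, intraday step traces,
weather, delivery failures, EMA compliance and wear time.

The generator exists so the whole intervention stack is testable
end-to-end without any field data. Steps accrue as per-tick (15-minute)
Poisson increments shaped by a diurnal rate profile and scaled so the
unconditional daily mean equals the participant's baseline; a delivered
prompt adds an increment with configurable expectation spread over the
following two hours (receptivity). Active minutes are credited for ticks
whose step count reaches a brisk-cadence threshold. Weather is drawn per
3-hour block from a wet/dry mixture, so the probability that a block
classifies as rainy (probability >= 0.5) is exactly ``rain_block_prob``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy import stats

from .decision_engine import (
    ActivityGoal,
    ActivitySnapshot,
    ForecastBlock,
    JitaiEngine,
    WeatherForecast,
)
from .message_bank import SendHistory, load_default_bank
from .scheduling import (
    MOOD_ITEMS,
    MOOD_SCALE,
    WELLBEING_ITEMS,
    WELLBEING_SCALE,
    ParticipantProfile,
    review_goal,
    schedule_ema_intervention,
)
from .types import EMAKind, GoalKind, StageOfChange

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ActivityTrace",
    "WearSummary",
    "ReceptiveTraceSource",
    "SimWeatherSource",
    "TrialLogs",
    "simulate_cohort",
    "simulate_day_trace",
    "simulate_weather",
    "simulate_trial",
    "GOAL_OPTIONS",
]

TICKS_PER_DAY = 96
TICK_MINUTES = 15

#: the six goal options a participant chooses among at onboarding
GOAL_OPTIONS = (
    (GoalKind.STEPS, 500),
    (GoalKind.STEPS, 750),
    (GoalKind.STEPS, 1000),
    (GoalKind.ACTIVE_MINUTES, 10),
    (GoalKind.ACTIVE_MINUTES, 20),
    (GoalKind.ACTIVE_MINUTES, 30),
)

_FIRST_NAMES = (
    "Ann", "Brian", "Carol", "Derek", "Elsie", "Frank", "Grace", "Harold",
    "Irene", "Jim", "Kath", "Len", "Margaret", "Norman", "Olive", "Peter",
    "Rose", "Stan", "Thelma", "Victor",
)

#: relative step-rate weight per waking hour (6:00-21:59); zero overnight.
#: Shape: quiet early morning, late-morning and mid-afternoon peaks,
#: tapering evening — a typical ambulatory pattern for older adults.
DEFAULT_DIURNAL_WEIGHTS = {
    6: 0.2, 7: 0.5, 8: 0.8, 9: 1.0, 10: 1.2, 11: 1.2, 12: 0.9, 13: 0.9,
    14: 1.1, 15: 1.1, 16: 0.9, 17: 0.8, 18: 0.6, 19: 0.5, 20: 0.3, 21: 0.2,
}


class SimulationConfig(BaseModel):
    """All knobs of the synthetic trial.

    Defaults emulate the deployed study conditions: a 30-participant
    cohort, an 8-day baseline wear week, a 4-week intervention, an 8-day
    follow-up week, a 6% message delivery-failure rate, 1% activity-call
    failures, 45% EMA compliance and a 13% onboarding-failure rate.
    """

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=30, ge=0)
    seed: int = 0
    start_date: dt.date = dt.date(2020, 9, 7)
    baseline_days: int = Field(default=8, ge=0)
    intervention_weeks: int = Field(default=4, ge=1)
    followup_days: int = Field(default=8, ge=0)

    baseline_steps_mean: float = Field(default=5000.0, gt=0)
    baseline_steps_sd: float = Field(default=2000.0, ge=0)
    baseline_minutes_mean: float = Field(default=25.0, gt=0)
    baseline_minutes_sd: float = Field(default=12.0, ge=0)

    #: probability of each of the six goal options, keyed "<kind>_<increment>"
    goal_choice_probs: dict[str, float] = Field(
        default_factory=lambda: {
            f"{kind.value}_{inc}": 1.0 / 6.0 for kind, inc in GOAL_OPTIONS
        }
    )
    diurnal_weights: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_DIURNAL_WEIGHTS)
    )
    #: coefficient of variation of the day-level activity multiplier
    #: (gamma with mean 1): day-to-day variation beyond tick-level noise
    day_cv: float = Field(default=0.25, ge=0)
    #: expected extra steps following one delivered prompt (over 2 hours)
    receptivity_effect: float = Field(default=100.0, ge=0)
    #: steps per 15-minute tick at or above which the tick counts as active
    cadence_threshold: float = Field(default=100.0, gt=0)

    delivery_failure_prob: float = Field(default=0.06, ge=0, le=1)
    activity_call_failure_prob: float = Field(default=0.01, ge=0, le=1)
    weather_call_failure_prob: float = Field(default=0.0, ge=0, le=1)
    ema_compliance_prob: float = Field(default=0.45, ge=0, le=1)
    survey_response_prob: float = Field(default=0.97, ge=0, le=1)
    onboarding_failure_prob: float = Field(default=0.13, ge=0, le=1)
    goal_review_change_prob: float = Field(default=0.2, ge=0, le=1)

    #: probability a 3-hour forecast block is rainy (precip prob >= 0.5)
    rain_block_prob: float = Field(default=0.3, ge=0, le=1)

    wear_hours_mean: float = Field(default=18.0, ge=0, le=24)
    wear_hours_sd: float = Field(default=4.0, ge=0)
    #: snapshots lag the trace by the upload cadence
    sync_lag_minutes: int = Field(default=15, ge=0)

    @field_validator("goal_choice_probs")
    @classmethod
    def _probs_valid(cls, v: dict[str, float]) -> dict[str, float]:
        valid = {f"{kind.value}_{inc}" for kind, inc in GOAL_OPTIONS}
        unknown = set(v) - valid
        if unknown:
            raise ValueError(f"unknown goal options {sorted(unknown)}")
        if any(p < 0 for p in v.values()):
            raise ValueError("goal_choice_probs must be non-negative")
        total = sum(v.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"goal_choice_probs sum to {total}, expected 1")
        return v

    @field_validator("diurnal_weights")
    @classmethod
    def _weights_valid(cls, v: dict[int, float]) -> dict[int, float]:
        if not v or any(w < 0 for w in v.values()) or sum(v.values()) <= 0:
            raise ValueError("diurnal_weights must be non-negative with positive sum")
        if any(not 0 <= h <= 23 for h in v):
            raise ValueError("diurnal_weights keyed by hour of day (0-23)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(open(path)) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def intervention_days(self) -> int:
        return 7 * self.intervention_weeks

    def goal_option_array(self) -> tuple[list[tuple[GoalKind, int]], np.ndarray]:
        opts = list(GOAL_OPTIONS)
        probs = np.array(
            [self.goal_choice_probs.get(f"{k.value}_{i}", 0.0) for k, i in opts]
        )
        return opts, probs / probs.sum()


@dataclass(frozen=True)
class WearSummary:
    """Per-day accelerometer wear hours (the raw-signal pipeline's
    summary output; this artifact never touches raw accelerations)."""

    participant_id: str
    date: dt.date
    wear_hours: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.wear_hours <= 24.0:
            raise ValueError(f"wear_hours {self.wear_hours} outside [0, 24]")

    @property
    def is_weekend(self) -> bool:
        return self.date.weekday() >= 5


@dataclass(frozen=True)
class ActivityTrace:
    """Cumulative steps and active minutes at 15-minute ticks over one day
    (97 sample points, 00:00 through 24:00)."""

    participant_id: str
    date: dt.date
    cumulative_steps: np.ndarray
    cumulative_active_minutes: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.cumulative_steps, self.cumulative_active_minutes):
            if len(arr) != TICKS_PER_DAY + 1 or arr[0] != 0:
                raise ValueError("trace must have 97 points starting at 0")
            if np.any(np.diff(arr) < 0):
                raise ValueError("cumulative trace must be non-decreasing")

    @property
    def daily_steps(self) -> int:
        return int(self.cumulative_steps[-1])

    @property
    def daily_active_minutes(self) -> float:
        return float(self.cumulative_active_minutes[-1])

    def _tick_index(self, when: dt.datetime) -> int:
        if when.date() < self.date:
            return 0
        if when.date() > self.date:
            return TICKS_PER_DAY
        minutes = when.hour * 60 + when.minute
        return min(minutes // TICK_MINUTES, TICKS_PER_DAY)

    def steps_at(self, when: dt.datetime) -> int:
        return int(self.cumulative_steps[self._tick_index(when)])

    def active_minutes_at(self, when: dt.datetime) -> float:
        return float(self.cumulative_active_minutes[self._tick_index(when)])


def _tick_rates(baseline_steps: float, weights: Mapping[int, float]) -> np.ndarray:
    """Per-tick Poisson rates whose sum equals the baseline daily mean."""
    w = np.zeros(TICKS_PER_DAY)
    for hour, weight in weights.items():
        w[4 * hour : 4 * hour + 4] = weight
    return baseline_steps * w / w.sum()


def _day_rates(
    baseline_steps: float, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One day's tick rates: the diurnal profile times a gamma day factor
    with mean 1 and CV ``day_cv`` (a good/bad activity day), keeping the
    unconditional daily mean at the baseline."""
    rates = _tick_rates(baseline_steps, config.diurnal_weights)
    if config.day_cv > 0:
        shape = 1.0 / config.day_cv**2
        rates = rates * rng.gamma(shape, 1.0 / shape)
    return rates


def _boost_increments(
    effect: float, prompt_minutes: int, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Poisson extra steps over the 8 ticks following a delivered prompt."""
    n_ticks = (2 * 60) // TICK_MINUTES
    start = prompt_minutes // TICK_MINUTES
    draws = rng.poisson(effect / n_ticks, n_ticks)
    return start, draws


def _assemble_trace(
    pid: str,
    day: dt.date,
    increments: np.ndarray,
    cadence_threshold: float,
) -> ActivityTrace:
    cum_steps = np.concatenate([[0], np.cumsum(increments)])
    active = (increments >= cadence_threshold) * TICK_MINUTES
    cum_minutes = np.concatenate([[0], np.cumsum(active)]).astype(float)
    return ActivityTrace(pid, day, cum_steps, cum_minutes)


def simulate_day_trace(
    profile: ParticipantProfile,
    day: dt.date,
    delivered_prompts: Sequence[dt.datetime],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ActivityTrace:
    """One day's cumulative trace for a participant.

    ``delivered_prompts`` are the times of prompts already delivered that
    day; each adds an increment with expectation ``receptivity_effect``
    spread over the following two hours.
    """
    rates = _day_rates(profile.baseline_steps, config, rng)
    increments = rng.poisson(rates).astype(np.int64)
    for when in delivered_prompts:
        if when.date() != day:
            continue
        start, draws = _boost_increments(
            config.receptivity_effect, when.hour * 60 + when.minute, rng
        )
        end = min(start + len(draws), TICKS_PER_DAY)
        increments[start:end] += draws[: end - start]
    return _assemble_trace(
        profile.participant_id, day, increments, config.cadence_threshold
    )


@dataclass
class ReceptiveTraceSource:
    """Activity repository backed by simulated tick increments.

    Implements the activity-source contract (latest snapshot at or before
    a query time, lagged by the upload cadence) and a receptivity hook:
    ``notify_delivery`` injects the post-prompt step boost into the rest
    of the day, so later goal checks see the behavioural response.
    """

    cadence_threshold: float
    receptivity_effect: float
    sync_lag_minutes: int
    boost_rng: np.random.Generator
    _increments: dict[tuple[str, dt.date], np.ndarray] = field(default_factory=dict)

    def register_day(self, pid: str, day: dt.date, increments: np.ndarray) -> None:
        self._increments[(pid, day)] = increments.astype(np.int64).copy()

    def notify_delivery(self, pid: str, when: dt.datetime) -> None:
        incr = self._increments.get((pid, when.date()))
        if incr is None or self.receptivity_effect <= 0:
            return
        start, draws = _boost_increments(
            self.receptivity_effect, when.hour * 60 + when.minute, self.boost_rng
        )
        end = min(start + len(draws), TICKS_PER_DAY)
        incr[start:end] += draws[: end - start]

    def latest(self, pid: str, when: dt.datetime) -> ActivitySnapshot:
        incr = self._increments.get((pid, when.date()))
        if incr is None:
            raise KeyError(f"no trace registered for {pid} on {when.date()}")
        sync = when - dt.timedelta(minutes=self.sync_lag_minutes)
        if sync.date() < when.date():
            tick = 0
            sync = dt.datetime.combine(when.date(), dt.time(0, 0))
        else:
            tick = min((sync.hour * 60 + sync.minute) // TICK_MINUTES, TICKS_PER_DAY)
            sync = dt.datetime.combine(when.date(), dt.time(0, 0)) + dt.timedelta(
                minutes=tick * TICK_MINUTES
            )
        seen = incr[:tick]
        return ActivitySnapshot(
            as_of=when,
            steps_today=int(seen.sum()),
            active_minutes_today=float(
                (seen >= self.cadence_threshold).sum() * TICK_MINUTES
            ),
            last_sync=sync,
        )

    def trace(self, pid: str, day: dt.date) -> ActivityTrace:
        return _assemble_trace(
            pid, day, self._increments[(pid, day)], self.cadence_threshold
        )


def simulate_weather(
    start: dt.date, n_days: int, config: SimulationConfig, rng: np.random.Generator
) -> "SimWeatherSource":
    """Draw 3-hour-block precipitation probabilities for ``n_days`` days
    (plus two days of lookahead so end-of-range queries stay covered).

    Each block is rainy (probability uniform on [0.5, 1)) with probability
    ``rain_block_prob``, else dry (uniform on [0, 0.5))."""
    blocks = []
    for d in range(n_days + 2):
        day = start + dt.timedelta(days=d)
        for h in range(0, 24, 3):
            wet = rng.random() < config.rain_block_prob
            p = 0.5 + 0.5 * rng.random() if wet else 0.5 * rng.random()
            blocks.append(
                ForecastBlock(dt.datetime.combine(day, dt.time(h, 0)), float(p))
            )
    return SimWeatherSource(tuple(blocks))


@dataclass(frozen=True)
class SimWeatherSource:
    """Weather provider backed by a pre-drawn block series; ``forecast``
    returns the blocks covering the next 28 hours from the query time.
    Blocks are time-ordered, so lookup is a binary search."""

    blocks: tuple[ForecastBlock, ...]
    horizon_hours: float = 28.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "_starts", [b.start for b in self.blocks])

    def forecast(self, location_key: str, when: dt.datetime) -> WeatherForecast:
        import bisect

        end = when + dt.timedelta(hours=self.horizon_hours)
        starts = self._starts
        lo = bisect.bisect_right(starts, when)
        lo = max(lo - 1, 0)
        if self.blocks and self.blocks[lo].end <= when:
            lo += 1
        hi = bisect.bisect_left(starts, end)
        return WeatherForecast(self.blocks[lo:hi])


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[ParticipantProfile]:
    """Draw the synthetic cohort: baselines from truncated normals, goal
    choices from the configured probabilities, and an
    ``onboarding_failure_prob`` fraction left without a goal (the failure
    mode in which interrupted onboarding silences all messaging)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    steps = _truncated_normal(
        config.baseline_steps_mean, config.baseline_steps_sd, 0, np.inf, n, rng
    )
    minutes = _truncated_normal(
        config.baseline_minutes_mean, config.baseline_minutes_sd, 0, np.inf, n, rng
    )
    opts, probs = config.goal_option_array()
    choices = rng.choice(len(opts), size=n, p=probs)
    failed = rng.random(n) < config.onboarding_failure_prob
    stages = rng.integers(0, len(StageOfChange), size=n)
    efficacy = rng.integers(1, 11, size=n)
    profiles = []
    stage_list = list(StageOfChange)
    for i in range(n):
        pid = f"p{i + 1:04d}"
        profile = ParticipantProfile(
            participant_id=pid,
            first_name=_FIRST_NAMES[i % len(_FIRST_NAMES)],
            postal_code=f"PC{i % 50:02d}",
            baseline_steps=float(steps[i]),
            baseline_active_minutes=float(minutes[i]),
            stage_of_change=stage_list[int(stages[i])],
        )
        if not failed[i]:
            kind, inc = opts[int(choices[i])]
            profile.goal = ActivityGoal(
                kind=kind,
                increment=inc,
                baseline=profile.baseline_for(kind),
                set_date=config.start_date,
            )
            profile.self_efficacy = int(efficacy[i])
        profiles.append(profile)
    return profiles


@dataclass
class TrialLogs:
    """The full log bundle of one synthetic trial run."""

    events: pd.DataFrame
    ema: pd.DataFrame
    wear: pd.DataFrame
    daily: pd.DataFrame
    survey: pd.DataFrame
    profiles: pd.DataFrame
    config: SimulationConfig

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            "events": self.events,
            "ema": self.ema,
            "wear": self.wear,
            "daily": self.daily,
            "survey": self.survey,
            "profiles": self.profiles,
        }


_SURVEY_CATEGORIES = {
    "research": [f"research_q{i}" for i in range(1, 5)],
    "technology": [f"technology_q{i}" for i in range(1, 7)],
    "app": [f"app_q{i}" for i in range(1, 10)],
}
#: response distribution over the 1-5 agreement scale, skewed positive
_SURVEY_RESPONSE_P = np.array([0.04, 0.08, 0.18, 0.45, 0.25])


def simulate_trial(config: SimulationConfig) -> TrialLogs:
    """Run the whole synthetic trial.

    Timeline per participant: baseline wear week (traces only) →
    onboarding (goal + self-efficacy, unless the participant is an
    onboarding failure) → intervention weeks with the daily decision loop
    and the EMA calendar (biweekly goal reviews applied in sequence) →
    follow-up wear week. All randomness descends from ``config.seed``.
    """
    bank = load_default_bank()
    root = np.random.SeedSequence(config.seed)
    cohort_ss, weather_ss, parts_ss = root.spawn(3)
    profiles = simulate_cohort(config, np.random.default_rng(cohort_ss))

    first_day = config.start_date - dt.timedelta(days=config.baseline_days)
    total_days = config.baseline_days + config.intervention_days + config.followup_days
    weather = simulate_weather(
        first_day, total_days, config, np.random.default_rng(weather_ss)
    )

    engine = JitaiEngine(
        bank=bank,
        failure_prob=config.delivery_failure_prob,
        activity_call_failure_prob=config.activity_call_failure_prob,
        weather_call_failure_prob=config.weather_call_failure_prob,
    )

    event_rows: list[dict] = []
    ema_rows: list[dict] = []
    wear_rows: list[dict] = []
    daily_rows: list[dict] = []
    survey_rows: list[dict] = []

    for profile, part_ss in zip(profiles, parts_ss.spawn(len(profiles))):
        trace_ss, boost_ss, engine_ss, ema_ss, wear_ss, survey_ss = part_ss.spawn(6)
        trace_rng = np.random.default_rng(trace_ss)
        engine_rng = np.random.default_rng(engine_ss)
        ema_rng = np.random.default_rng(ema_ss)
        wear_rng = np.random.default_rng(wear_ss)
        survey_rng = np.random.default_rng(survey_ss)

        source = ReceptiveTraceSource(
            cadence_threshold=config.cadence_threshold,
            receptivity_effect=config.receptivity_effect,
            sync_lag_minutes=config.sync_lag_minutes,
            boost_rng=np.random.default_rng(boost_ss),
        )
        history = SendHistory(profile.participant_id)
        pid = profile.participant_id

        wear_hours = _truncated_normal(
            config.wear_hours_mean, config.wear_hours_sd, 0, 24, total_days, wear_rng
        )

        calendar = schedule_ema_intervention(
            config.start_date, ema_rng, weeks=config.intervention_weeks
        )
        part_ema_rows = [_ema_row(pid, prompt, config, ema_rng) for prompt in calendar]
        ema_rows.extend(part_ema_rows)
        review_responded = {
            dt.datetime.fromisoformat(r["scheduled_datetime"]).date(): r["responded"]
            for r in part_ema_rows
            if r["kind"] == EMAKind.GOAL_REVIEW.value
        }

        if profile.goal is None:
            logger.info(
                "participant %s never completed onboarding; the decision loop "
                "is skipped for the whole intervention", pid,
            )

        for offset in range(total_days):
            day = first_day + dt.timedelta(days=offset)
            period = (
                "baseline"
                if offset < config.baseline_days
                else "intervention"
                if offset < config.baseline_days + config.intervention_days
                else "followup"
            )
            rates = _day_rates(profile.baseline_steps, config, trace_rng)
            source.register_day(pid, day, trace_rng.poisson(rates))

            if review_responded.get(day) and profile.goal is not None:
                _maybe_review_goal(profile, day, config, ema_rng)
            if period == "intervention" and profile.goal is not None:
                day_events = engine.run_day(
                    profile, profile.goal, day, source, weather, history, engine_rng
                )
                event_rows.extend(_event_row(ev) for ev in day_events)

            trace = source.trace(pid, day)
            goal = profile.goal
            daily_rows.append(
                {
                    "participant_id": pid,
                    "date": day.isoformat(),
                    "period": period,
                    "steps": trace.daily_steps,
                    "active_minutes": trace.daily_active_minutes,
                    "goal_kind": goal.kind.value if goal else "",
                    "goal_target": goal.target if goal else np.nan,
                    "goal_met": bool(
                        goal
                        and period == "intervention"
                        and (
                            trace.daily_steps
                            if goal.kind is GoalKind.STEPS
                            else trace.daily_active_minutes
                        )
                        >= goal.target
                    ),
                }
            )
            wear_rows.append(
                {
                    "participant_id": pid,
                    "date": day.isoformat(),
                    "period": period,
                    "wear_hours": round(float(wear_hours[offset]), 3),
                    "is_weekend": day.weekday() >= 5,
                }
            )

        if survey_rng.random() < config.survey_response_prob:
            for category, questions in _SURVEY_CATEGORIES.items():
                responses = survey_rng.choice(
                    np.arange(1, 6), size=len(questions), p=_SURVEY_RESPONSE_P
                )
                for q, r in zip(questions, responses):
                    survey_rows.append(
                        {
                            "participant_id": pid,
                            "category": category,
                            "question_id": q,
                            "response": int(r),
                        }
                    )

    profile_rows = [
        {
            "participant_id": p.participant_id,
            "first_name": p.first_name,
            "postal_code": p.postal_code,
            "baseline_steps": round(p.baseline_steps, 2),
            "baseline_active_minutes": round(p.baseline_active_minutes, 2),
            "onboarded": p.onboarded,
            "goal_kind": p.goal.kind.value if p.goal else "",
            "goal_increment": p.goal.increment if p.goal else np.nan,
            "goal_target": round(p.goal.target, 2) if p.goal else np.nan,
            "self_efficacy": p.self_efficacy if p.self_efficacy else np.nan,
            "stage_of_change": p.stage_of_change.value if p.stage_of_change else "",
        }
        for p in profiles
    ]

    return TrialLogs(
        events=pd.DataFrame(event_rows, columns=EVENT_COLUMNS),
        ema=pd.DataFrame(ema_rows, columns=EMA_COLUMNS),
        wear=pd.DataFrame(wear_rows, columns=WEAR_COLUMNS),
        daily=pd.DataFrame(daily_rows, columns=DAILY_COLUMNS),
        survey=pd.DataFrame(survey_rows, columns=SURVEY_COLUMNS),
        profiles=pd.DataFrame(profile_rows, columns=PROFILE_COLUMNS),
        config=config,
    )


def _maybe_review_goal(
    profile: ParticipantProfile,
    day: dt.date,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Biweekly review: keep the goal, or (with the configured
    probability) switch to another increment of the same kind."""
    from .decision_engine import ALLOWED_INCREMENTS

    if rng.random() >= config.goal_review_change_prob:
        return
    options = [
        i for i in ALLOWED_INCREMENTS[profile.goal.kind] if i != profile.goal.increment
    ]
    review_goal(profile, day, new_increment=options[int(rng.integers(len(options)))])


def _event_row(ev) -> dict:
    return {
        "participant_id": ev.participant_id,
        "timestamp": ev.timestamp.isoformat(),
        "slot": ev.slot.value if ev.slot else "",
        "kind": ev.kind,
        "rule_id": ev.rule_id if ev.rule_id is not None else np.nan,
        "message_id": ev.message_id or "",
        "rendered_body": ev.rendered_body or "",
        "delivery_status": ev.delivery_status.value,
        "rating": ev.rating.value,
        "stale": ev.stale,
        "activity_call_ok": ev.activity_call_ok,
        "weather_call_ok": ev.weather_call_ok,
    }


def _ema_row(
    pid: str, prompt, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    responded = bool(rng.random() < config.ema_compliance_prob)
    row = {
        "participant_id": pid,
        "kind": prompt.kind.value,
        "scheduled_datetime": prompt.scheduled_datetime.isoformat(),
        "week_index": prompt.week_index,
        "responded": responded,
        "active_today": "",
        "audio_ref": "",
        "item_scores": "",
    }
    if not responded:
        return row
    if prompt.kind is EMAKind.SNIPPET:
        row["active_today"] = "yes" if rng.random() < 0.6 else "no"
        row["audio_ref"] = (
            f"synthetic-snippet-{pid}-{prompt.scheduled_datetime:%Y%m%dT%H%M}.ref"
        )
    elif prompt.kind is EMAKind.MOOD:
        scores = rng.integers(MOOD_SCALE[0], MOOD_SCALE[1] + 1, MOOD_ITEMS)
        row["item_scores"] = ";".join(map(str, scores))
    elif prompt.kind is EMAKind.WELLBEING:
        scores = rng.integers(WELLBEING_SCALE[0], WELLBEING_SCALE[1] + 1, WELLBEING_ITEMS)
        row["item_scores"] = ";".join(map(str, scores))
    return row


EVENT_COLUMNS = [
    "participant_id", "timestamp", "slot", "kind", "rule_id", "message_id",
    "rendered_body", "delivery_status", "rating", "stale",
    "activity_call_ok", "weather_call_ok",
]
EMA_COLUMNS = [
    "participant_id", "kind", "scheduled_datetime", "week_index", "responded",
    "active_today", "audio_ref", "item_scores",
]
WEAR_COLUMNS = ["participant_id", "date", "period", "wear_hours", "is_weekend"]
DAILY_COLUMNS = [
    "participant_id", "date", "period", "steps", "active_minutes",
    "goal_kind", "goal_target", "goal_met",
]
SURVEY_COLUMNS = ["participant_id", "category", "question_id", "response"]
PROFILE_COLUMNS = [
    "participant_id", "first_name", "postal_code", "baseline_steps",
    "baseline_active_minutes", "onboarded", "goal_kind", "goal_increment",
    "goal_target", "self_efficacy", "stage_of_change",
]
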
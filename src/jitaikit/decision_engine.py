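"""The 13-rule tailoring engine and the daily decision loop.

Three intervention options are encoded as a partition of decision
contexts:

* option 1 (1 rule): the participant has met their daily goal — a
  congratulation message, checked hourly on the hour from 9:00 to 20:00
  and sent at most once per day;
* option 2 (8 rules): goal not yet met at one of the two in-day scheduled
  slots (12:30 or 17:30), split by goal kind and by good/bad weather over
  the next four hours — an activity suggestion;
* option 3 (4 rules): goal not met at the 20:30 slot, split by goal kind
  and by tomorrow's daytime weather — a next-day planning prompt.

1 + 8 + 4 = 13 rules. "Good" weather means every forecast block touching
the window has a precipitation probability strictly below 50%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Protocol, Sequence

import numpy as np

from .message_bank import MessageBank, SendHistory, render_message, select_message
from .types import DeliveryStatus, GoalKind, Rating, Slot, WeatherClass

__all__ = [
    "ActivityGoal",
    "ActivitySnapshot",
    "ForecastBlock",
    "WeatherForecast",
    "DecisionContext",
    "DecisionRule",
    "PromptEvent",
    "RuleTableError",
    "ForecastCoverageError",
    "ALLOWED_INCREMENTS",
    "HOURLY_CHECK_HOURS",
    "SLOT_TIMES",
    "classify_weather",
    "goal_progress",
    "evaluate",
    "default_rule_table",
    "rule_table_from_records",
    "validate_rule_table",
    "enumerate_contexts",
    "JitaiEngine",
    "run_day",
]

logger = logging.getLogger(__name__)

#: allowed goal increments above baseline, per goal kind
ALLOWED_INCREMENTS = {
    GoalKind.STEPS: (500, 750, 1000),
    GoalKind.ACTIVE_MINUTES: (10, 20, 30),
}

#: top-of-hour goal checks, 9:00 through 20:00 inclusive (12 checks)
HOURLY_CHECK_HOURS = tuple(range(9, 21))

#: wall-clock times of the three scheduled tailored sends
SLOT_TIMES = {
    Slot.MIDDAY: time(12, 30),
    Slot.EVENING: time(17, 30),
    Slot.NIGHT: time(20, 30),
}

#: weather window length for the in-day slots ("next 4 hours")
INDAY_WEATHER_HOURS = 4.0
#: tomorrow's daytime window assessed at the NIGHT slot
NIGHT_WINDOW = (time(12, 0), time(16, 0))
#: a snapshot older than this at evaluation time is flagged stale
STALE_AFTER = timedelta(hours=4)


class RuleTableError(ValueError):
    """The rule table is not a partition of valid contexts."""


class ForecastCoverageError(ValueError):
    """The forecast does not cover the requested window."""


@dataclass(frozen=True)
class ActivityGoal:
    """A baseline-relative daily activity target.

    The target is ``baseline + increment``; increments are restricted to
    500/750/1000 steps or 10/20/30 active minutes per day.
    """

    kind: GoalKind
    increment: int
    baseline: float
    set_date: date

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GoalKind(self.kind))
        allowed = ALLOWED_INCREMENTS[self.kind]
        if self.increment not in allowed:
            raise ValueError(
                f"increment {self.increment} not in allowed set {allowed} "
                f"for {self.kind.value} goals"
            )
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")

    @property
    def target(self) -> float:
        return self.baseline + self.increment


@dataclass(frozen=True)
class ActivitySnapshot:
    """The tracker's view of today's activity at a moment in time."""

    as_of: datetime
    steps_today: int
    active_minutes_today: float
    last_sync: datetime

    def __post_init__(self) -> None:
        if self.steps_today < 0 or self.active_minutes_today < 0:
            raise ValueError("activity counts must be non-negative")
        if self.last_sync > self.as_of:
            raise ValueError("last_sync cannot be after as_of")

    def value(self, kind: GoalKind) -> float:
        if GoalKind(kind) is GoalKind.STEPS:
            return self.steps_today
        return self.active_minutes_today


@dataclass(frozen=True)
class ForecastBlock:
    start: datetime
    precip_prob: float
    duration_hours: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.precip_prob <= 1.0:
            raise ValueError(f"precipitation probability {self.precip_prob} not in [0, 1]")
        if self.duration_hours <= 0:
            raise ValueError("block duration must be positive")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(hours=self.duration_hours)


@dataclass(frozen=True)
class WeatherForecast:
    """Time-ordered, non-overlapping precipitation-probability blocks
    (3-hour blocks as published by the forecast provider)."""

    blocks: tuple[ForecastBlock, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.start < prev.end:
                raise ValueError("forecast blocks overlap or are out of order")

    def intersecting(self, start: datetime, end: datetime) -> list[ForecastBlock]:
        return [b for b in self.blocks if b.start < end and b.end > start]

    def covers(self, start: datetime, end: datetime) -> bool:
        cursor = start
        for b in self.intersecting(start, end):
            if b.start > cursor:
                return False
            cursor = max(cursor, b.end)
            if cursor >= end:
                return True
        return cursor >= end


def classify_weather(
    forecast: WeatherForecast, window_start: datetime, window_hours: float
) -> WeatherClass:
    """Good weather iff the maximum precipitation probability over all
    blocks intersecting the window is strictly below 0.5 ("<50% chance of
    rain"); a block at exactly 0.5 makes the window bad."""
    window_end = window_start + timedelta(hours=window_hours)
    if not forecast.covers(window_start, window_end):
        raise ForecastCoverageError(
            f"forecast does not cover [{window_start}, {window_end})"
        )
    worst = max(b.precip_prob for b in forecast.intersecting(window_start, window_end))
    return WeatherClass.GOOD if worst < 0.5 else WeatherClass.BAD


def goal_progress(snapshot: ActivitySnapshot, goal: ActivityGoal) -> bool:
    """True iff today's value for the goal's kind has reached the target
    (boundary inclusive: hitting the target exactly counts as met)."""
    return snapshot.value(goal.kind) >= goal.target


@dataclass(frozen=True)
class DecisionContext:
    """Snapshot of the tailoring variables at one decision point."""

    slot: Slot
    goal_kind: GoalKind
    goal_met: bool
    weather_class: WeatherClass | None
    congratulated_today: bool

    def __post_init__(self) -> None:
        if self.slot is not Slot.HOURLY and self.weather_class is None:
            raise ValueError(f"weather_class required for slot {self.slot.value}")


@dataclass(frozen=True)
class DecisionRule:
    """A declarative predicate over :class:`DecisionContext`.

    ``goal_kinds`` / ``weather`` of ``None`` mean the variable is ignored.
    Each rule owns one message pool.
    """

    rule_id: int
    option: int
    pool_id: str
    slots: frozenset[Slot]
    goal_met: bool
    goal_kinds: frozenset[GoalKind] | None = None
    weather: frozenset[WeatherClass] | None = None
    requires_not_congratulated: bool = False

    def matches(self, ctx: DecisionContext) -> bool:
        if ctx.slot not in self.slots:
            return False
        if ctx.goal_met != self.goal_met:
            return False
        if self.goal_kinds is not None and ctx.goal_kind not in self.goal_kinds:
            return False
        if self.weather is not None and ctx.weather_class not in self.weather:
            return False
        if self.requires_not_congratulated and ctx.congratulated_today:
            return False
        return True

    def to_record(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "option": self.option,
            "pool_id": self.pool_id,
            "slots": sorted(s.value for s in self.slots),
            "goal_met": self.goal_met,
            "goal_kinds": None
            if self.goal_kinds is None
            else sorted(k.value for k in self.goal_kinds),
            "weather": None
            if self.weather is None
            else sorted(w.value for w in self.weather),
            "requires_not_congratulated": self.requires_not_congratulated,
        }


def rule_table_from_records(records: Iterable[dict]) -> tuple[DecisionRule, ...]:
    """Build a rule table from plain dicts (e.g. parsed YAML/JSON), so
    tests and configuration can inject alternative tables. The table is
    validated as a partition before use."""
    rules = []
    for rec in records:
        rules.append(
            DecisionRule(
                rule_id=int(rec["rule_id"]),
                option=int(rec["option"]),
                pool_id=str(rec["pool_id"]),
                slots=frozenset(Slot(s) for s in rec["slots"]),
                goal_met=bool(rec["goal_met"]),
                goal_kinds=None
                if rec.get("goal_kinds") is None
                else frozenset(GoalKind(k) for k in rec["goal_kinds"]),
                weather=None
                if rec.get("weather") is None
                else frozenset(WeatherClass(w) for w in rec["weather"]),
                requires_not_congratulated=bool(
                    rec.get("requires_not_congratulated", False)
                ),
            )
        )
    table = tuple(rules)
    validate_rule_table(table)
    return table


def default_rule_table() -> tuple[DecisionRule, ...]:
    """The deployed 13-rule table: 1 option-1 rule, 8 option-2 rules and
    4 option-3 rules, keyed to the fixture bank's pools."""
    rules: list[DecisionRule] = [
        DecisionRule(
            rule_id=1,
            option=1,
            pool_id="goal_met",
            slots=frozenset({Slot.HOURLY}),
            goal_met=True,
            requires_not_congratulated=True,
        )
    ]
    rid = 2
    for kind, prefix in ((GoalKind.STEPS, "steps"), (GoalKind.ACTIVE_MINUTES, "minutes")):
        for slot in (Slot.MIDDAY, Slot.EVENING):
            for wx in (WeatherClass.GOOD, WeatherClass.BAD):
                rules.append(
                    DecisionRule(
                        rule_id=rid,
                        option=2,
                        pool_id=f"{prefix}_{slot.value}_{wx.value}",
                        slots=frozenset({slot}),
                        goal_met=False,
                        goal_kinds=frozenset({kind}),
                        weather=frozenset({wx}),
                    )
                )
                rid += 1
    for kind, prefix in ((GoalKind.STEPS, "steps"), (GoalKind.ACTIVE_MINUTES, "minutes")):
        for wx in (WeatherClass.GOOD, WeatherClass.BAD):
            rules.append(
                DecisionRule(
                    rule_id=rid,
                    option=3,
                    pool_id=f"{prefix}_night_{wx.value}",
                    slots=frozenset({Slot.NIGHT}),
                    goal_met=False,
                    goal_kinds=frozenset({kind}),
                    weather=frozenset({wx}),
                )
            )
            rid += 1
    return tuple(rules)


def enumerate_contexts() -> list[DecisionContext]:
    """All valid decision contexts (weather is undefined at hourly checks)."""
    contexts = []
    for slot, kind, met, congr in itertools.product(
        Slot, GoalKind, (False, True), (False, True)
    ):
        weathers = (None,) if slot is Slot.HOURLY else tuple(WeatherClass)
        for wx in weathers:
            contexts.append(DecisionContext(slot, kind, met, wx, congr))
    return contexts


def validate_rule_table(rules: Sequence[DecisionRule]) -> None:
    """Check the partition property: at most one rule fires for every
    valid context. Raised at load time so a bad table never runs."""
    ids = [r.rule_id for r in rules]
    if len(set(ids)) != len(ids):
        raise RuleTableError("duplicate rule_id in rule table")
    for ctx in enumerate_contexts():
        firing = [r.rule_id for r in rules if r.matches(ctx)]
        if len(firing) > 1:
            raise RuleTableError(
                f"rules {firing} all fire for context {ctx} — table is not a partition"
            )


def evaluate(
    ctx: DecisionContext, rules: Sequence[DecisionRule]
) -> DecisionRule | None:
    """Return the unique firing rule for the context, or ``None``."""
    for rule in rules:
        if rule.matches(ctx):
            return rule
    return None


@dataclass(frozen=True)
class PromptEvent:
    """One row of the prompt log.

    A *message event* carries a ``rule_id`` and ``message_id``; a scheduled
    slot where no rule fired (or a data call failed) is recorded with
    status ``suppressed`` and neither id. A reminder row carries a
    description in ``rendered_body`` and no rule.
    """

    participant_id: str
    timestamp: datetime
    slot: Slot | None
    rule_id: int | None = None
    message_id: str | None = None
    rendered_body: str | None = None
    delivery_status: DeliveryStatus = DeliveryStatus.SUPPRESSED
    rating: Rating = Rating.NONE
    stale: bool = False
    activity_call_ok: bool = True
    weather_call_ok: bool = True
    kind: str = "message"  # message | reminder | marker

    def __post_init__(self) -> None:
        if (self.rule_id is None) != (self.message_id is None):
            raise ValueError("message_id must be present iff rule_id is present")
        if self.rating is not Rating.NONE and self.delivery_status is not DeliveryStatus.DELIVERED:
            raise ValueError("rating only allowed on delivered events")

    @property
    def is_message_event(self) -> bool:
        return self.message_id is not None


class ActivitySource(Protocol):
    """Contract for the activity repository: the latest snapshot at or
    before a query time, with ``last_sync <= query time``; repeated
    queries at the same time return the same snapshot."""

    def latest(self, participant_id: str, when: datetime) -> ActivitySnapshot: ...


class WeatherSource(Protocol):
    """Contract for the forecast provider: a forecast covering at least
    the next 28 hours from the query time at the given location."""

    def forecast(self, location_key: str, when: datetime) -> WeatherForecast: ...


def _weather_window(slot: Slot, at: datetime) -> tuple[datetime, float]:
    """Window the weather is classified over for a scheduled slot: the
    next 4 hours in-day; tomorrow 12:00-16:00 at the night slot (its
    messages talk about tomorrow's plans)."""
    if slot in (Slot.MIDDAY, Slot.EVENING):
        return at, INDAY_WEATHER_HOURS
    tomorrow = at.date() + timedelta(days=1)
    start = datetime.combine(tomorrow, NIGHT_WINDOW[0])
    hours = (NIGHT_WINDOW[1].hour - NIGHT_WINDOW[0].hour) + (
        NIGHT_WINDOW[1].minute - NIGHT_WINDOW[0].minute
    ) / 60.0
    return start, hours


@dataclass
class JitaiEngine:
    """Runs the daily decision loop for one participant-day at a time.

    ``failure_prob`` is the per-message Bernoulli delivery-failure
    probability; the optional data-call failure probabilities emulate
    unreachable activity/weather services, which suppress the slot (a
    message cannot be compiled without its tailoring inputs).
    """

    bank: MessageBank
    rules: tuple[DecisionRule, ...] = field(default_factory=default_rule_table)
    failure_prob: float = 0.0
    activity_call_failure_prob: float = 0.0
    weather_call_failure_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("failure_prob", "activity_call_failure_prob", "weather_call_failure_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} not in [0, 1]")
        validate_rule_table(self.rules)

    def _decision_times(self, day: date) -> list[tuple[datetime, Slot]]:
        times = [
            (datetime.combine(day, time(h, 0)), Slot.HOURLY) for h in HOURLY_CHECK_HOURS
        ]
        times += [(datetime.combine(day, t), s) for s, t in SLOT_TIMES.items()]
        times.sort(key=lambda ts: ts[0])
        return times

    def run_day(
        self,
        profile,
        goal: ActivityGoal | None,
        day: date,
        activity_source: ActivitySource,
        weather_source: WeatherSource,
        history: SendHistory,
        rng: np.random.Generator,
    ) -> list[PromptEvent]:
        """Evaluate the 12 hourly checks and 3 scheduled slots of one day.

        Returns the day's prompt log, time-ordered: at most one option-1
        (congratulation) message event, at most one message event per
        scheduled slot, and a ``suppressed`` row for every scheduled slot
        where no message could be sent. A participant without a goal
        (onboarding never completed) receives no events at all.
        """
        pid = profile.participant_id
        if goal is None:
            logger.warning(
                "participant %s has no activity goal (onboarding incomplete); "
                "no messages will be sent on %s", pid, day,
            )
            return []
        location = getattr(profile, "postal_code", "")
        events: list[PromptEvent] = []
        congratulated = False
        for at, slot in self._decision_times(day):
            activity_ok = rng.random() >= self.activity_call_failure_prob
            if slot is Slot.HOURLY:
                if not activity_ok:
                    continue  # check silently skipped; nothing to suppress
                snapshot = activity_source.latest(pid, at)
                ctx = DecisionContext(slot, goal.kind, goal_progress(snapshot, goal), None, congratulated)
                rule = evaluate(ctx, self.rules)
                if rule is None:
                    continue
                stale = (at - snapshot.last_sync) > STALE_AFTER
                ev = self._send(profile, at, slot, rule, history, rng, stale)
                events.append(ev)
                self._notify(activity_source, ev)
                if rule.option == 1:
                    congratulated = True
                continue
            weather_ok = rng.random() >= self.weather_call_failure_prob
            if not (activity_ok and weather_ok):
                events.append(
                    PromptEvent(
                        pid, at, slot,
                        activity_call_ok=activity_ok, weather_call_ok=weather_ok,
                    )
                )
                continue
            snapshot = activity_source.latest(pid, at)
            win_start, win_hours = _weather_window(slot, at)
            wx = classify_weather(weather_source.forecast(location, at), win_start, win_hours)
            ctx = DecisionContext(slot, goal.kind, goal_progress(snapshot, goal), wx, congratulated)
            rule = evaluate(ctx, self.rules)
            if rule is None:
                events.append(PromptEvent(pid, at, slot))
                continue
            stale = (at - snapshot.last_sync) > STALE_AFTER
            ev = self._send(profile, at, slot, rule, history, rng, stale)
            events.append(ev)
            self._notify(activity_source, ev)
            if rule.option == 1:  # pragma: no cover — option 1 fires hourly only
                congratulated = True
        return events

    @staticmethod
    def _notify(activity_source: ActivitySource, ev: PromptEvent) -> None:
        """Receptivity hook: a source may react to a delivered prompt
        (the simulator injects the behavioural step response here)."""
        if ev.delivery_status is DeliveryStatus.DELIVERED:
            notify = getattr(activity_source, "notify_delivery", None)
            if notify is not None:
                notify(ev.participant_id, ev.timestamp)

    def _send(
        self,
        profile,
        at: datetime,
        slot: Slot,
        rule: DecisionRule,
        history: SendHistory,
        rng: np.random.Generator,
        stale: bool,
    ) -> PromptEvent:
        template = select_message(self.bank, rule.pool_id, history, rng)
        body = render_message(template, profile)
        delivered = rng.random() >= self.failure_prob
        return PromptEvent(
            participant_id=profile.participant_id,
            timestamp=at,
            slot=slot,
            rule_id=rule.rule_id,
            message_id=template.message_id,
            rendered_body=body,
            delivery_status=DeliveryStatus.DELIVERED if delivered else DeliveryStatus.FAILED,
            stale=stale,
        )


def run_day(
    profile,
    goal: ActivityGoal | None,
    day: date,
    activity_source: ActivitySource,
    weather_source: WeatherSource,
    history: SendHistory,
    rng: np.random.Generator,
    failure_prob: float = 0.0,
    *,
    bank: MessageBank,
    rules: tuple[DecisionRule, ...] | None = None,
) -> list[PromptEvent]:
    """Functional wrapper around :meth:`JitaiEngine.run_day`."""
    engine = JitaiEngine(
        bank=bank,
        rules=rules if rules is not None else default_rule_table(),
        failure_prob=failure_prob,
    )
    return engine.run_day(profile, goal, day, activity_source, weather_source, history, rng)
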
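"""Onboarding, goal setting, biweekly goal review, activity-reminder
planning, and the EMA prompt calendar.

The EMA calendar per intervention week: two randomly chosen days (one
weekday Mon-Fri, one weekend day Sat/Sun) carry voice-snippet prompts at
12:30 and 17:30 and a mood questionnaire at 20:30; a well-being
questionnaire is prompted at 20:30 on exactly one of the two days. Over
the 4-week intervention this yields 16 snippet, 8 mood and 4 well-being
prompts per participant, plus goal-review prompts after weeks 2 and 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
import numpy as np

from .decision_engine import ActivityGoal
from .types import EMAKind, GoalKind, StageOfChange

__all__ = [
    "ParticipantProfile",
    "PlannedActivity",
    "ActivityPlanner",
    "EMAPrompt",
    "EMAResponse",
    "set_goal",
    "record_self_efficacy",
    "review_goal",
    "goal_review_schedule",
    "schedule_ema_week",
    "schedule_ema_intervention",
    "SNIPPET_TIMES",
    "QUESTIONNAIRE_TIME",
    "GOAL_REVIEW_DAYS",
    "MOOD_ITEMS",
    "MOOD_SCALE",
    "WELLBEING_ITEMS",
    "WELLBEING_SCALE",
]

SNIPPET_TIMES = (time(12, 30), time(17, 30))
QUESTIONNAIRE_TIME = time(20, 30)
GOAL_REVIEW_TIME = time(9, 0)
#: goal review after 2 and after 4 weeks of intervention
GOAL_REVIEW_DAYS = (14, 28)
INTERVENTION_WEEKS = 4

#: mood questionnaire: short-form bipolar items on a 6-point scale
MOOD_ITEMS = 6
MOOD_SCALE = (1, 6)
#: short mental well-being scale: 7 items on a 7-point scale
WELLBEING_ITEMS = 7
WELLBEING_SCALE = (1, 7)


@dataclass
class ParticipantProfile:
    """Identity plus the tailoring substrate gathered at onboarding.

    ``baseline_steps`` / ``baseline_active_minutes`` are mean daily values
    over the baseline wear week. A participant counts as onboarded once
    both a goal and a self-efficacy rating are recorded; without a goal
    the decision engine sends nothing.
    """

    participant_id: str
    first_name: str
    postal_code: str = ""
    baseline_steps: float | None = None
    baseline_active_minutes: float | None = None
    goal: ActivityGoal | None = None
    self_efficacy: int | None = None
    stage_of_change: StageOfChange | None = None

    def __post_init__(self) -> None:
        if self.self_efficacy is not None and not 1 <= self.self_efficacy <= 10:
            raise ValueError("self_efficacy must be on the 1-10 scale")

    @property
    def onboarded(self) -> bool:
        return self.goal is not None and self.self_efficacy is not None

    def baseline_for(self, kind: GoalKind) -> float | None:
        if GoalKind(kind) is GoalKind.STEPS:
            return self.baseline_steps
        return self.baseline_active_minutes


def set_goal(
    profile: ParticipantProfile,
    kind: GoalKind | str,
    increment: int,
    set_date: date,
) -> ActivityGoal:
    """Choose a baseline-relative goal: +500/750/1000 steps or +10/20/30
    active minutes over the baseline-week daily mean."""
    kind = GoalKind(kind)
    baseline = profile.baseline_for(kind)
    if baseline is None:
        raise ValueError(
            f"participant {profile.participant_id}: no baseline recorded for "
            f"{kind.value} — complete the baseline week first"
        )
    goal = ActivityGoal(kind=kind, increment=increment, baseline=baseline, set_date=set_date)
    profile.goal = goal
    return goal


def record_self_efficacy(profile: ParticipantProfile, rating: int) -> None:
    """Record confidence in achieving the goal on the 1-10 scale."""
    if not 1 <= int(rating) <= 10:
        raise ValueError("self-efficacy rating must be between 1 and 10")
    profile.self_efficacy = int(rating)


def review_goal(
    profile: ParticipantProfile,
    review_date: date,
    new_increment: int | None = None,
    new_kind: GoalKind | str | None = None,
) -> ActivityGoal:
    """Apply a biweekly goal review: keep the goal (``new_increment`` is
    None) or re-set it; a changed goal keeps the original baseline."""
    if profile.goal is None:
        raise ValueError("cannot review a goal that was never set")
    if new_increment is None:
        return profile.goal
    kind = GoalKind(new_kind) if new_kind is not None else profile.goal.kind
    baseline = (
        profile.goal.baseline if kind is profile.goal.kind else profile.baseline_for(kind)
    )
    if baseline is None:
        raise ValueError(f"no baseline recorded for {kind.value}")
    goal = ActivityGoal(kind=kind, increment=new_increment, baseline=baseline, set_date=review_date)
    profile.goal = goal
    return goal


@dataclass(frozen=True)
class EMAPrompt:
    kind: EMAKind
    scheduled_datetime: datetime
    week_index: int

    def __post_init__(self) -> None:
        t = self.scheduled_datetime.time()
        if self.kind is EMAKind.SNIPPET and t not in SNIPPET_TIMES:
            raise ValueError(f"snippet prompts run at 12:30 or 17:30, not {t}")
        if self.kind in (EMAKind.MOOD, EMAKind.WELLBEING) and t != QUESTIONNAIRE_TIME:
            raise ValueError(f"questionnaire prompts run at 20:30, not {t}")


@dataclass(frozen=True)
class EMAResponse:
    """A completed EMA prompt.

    Snippets carry a yes/no "were you active today?" flag and an opaque
    reference to the recorded audio; questionnaires carry raw item scores
    within their scale bounds (no psychometric scoring is applied).
    """

    prompt: EMAPrompt
    active_today: bool | None = None
    audio_ref: str | None = None
    item_scores: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bounds = {EMAKind.MOOD: MOOD_SCALE, EMAKind.WELLBEING: WELLBEING_SCALE}.get(
            self.prompt.kind
        )
        if bounds is not None:
            lo, hi = bounds
            bad = [s for s in self.item_scores if not lo <= s <= hi]
            if bad:
                raise ValueError(
                    f"{self.prompt.kind.value} item scores {bad} outside [{lo}, {hi}]"
                )


def goal_review_schedule(intervention_start: date) -> list[EMAPrompt]:
    """Two goal-review prompts, 14 and 28 days after intervention start."""
    return [
        EMAPrompt(
            kind=EMAKind.GOAL_REVIEW,
            scheduled_datetime=datetime.combine(
                intervention_start + timedelta(days=d), GOAL_REVIEW_TIME
            ),
            week_index=d // 7,
        )
        for d in GOAL_REVIEW_DAYS
    ]


def schedule_ema_week(
    week_index: int, week_start: date, rng: np.random.Generator
) -> list[EMAPrompt]:
    """One week of EMA prompts: 4 snippet + 2 mood + 1 well-being.

    Picks one weekday and one weekend day uniformly from the 7-day window
    starting at ``week_start``; the well-being questionnaire lands on one
    of the two picked days, chosen uniformly. Deterministic given the
    generator state.
    """
    days = [week_start + timedelta(days=i) for i in range(7)]
    weekdays = [d for d in days if d.weekday() < 5]
    weekend = [d for d in days if d.weekday() >= 5]
    if not weekdays or not weekend:
        raise ValueError("week window must contain a weekday and a weekend day")
    picked = [
        weekdays[int(rng.integers(len(weekdays)))],
        weekend[int(rng.integers(len(weekend)))],
    ]
    wellbeing_day = picked[int(rng.integers(2))]
    prompts: list[EMAPrompt] = []
    for d in picked:
        for t in SNIPPET_TIMES:
            prompts.append(EMAPrompt(EMAKind.SNIPPET, datetime.combine(d, t), week_index))
        prompts.append(
            EMAPrompt(EMAKind.MOOD, datetime.combine(d, QUESTIONNAIRE_TIME), week_index)
        )
        if d == wellbeing_day:
            prompts.append(
                EMAPrompt(EMAKind.WELLBEING, datetime.combine(d, QUESTIONNAIRE_TIME), week_index)
            )
    prompts.sort(key=lambda p: (p.scheduled_datetime, p.kind.value))
    return prompts


def schedule_ema_intervention(
    start: date, rng: np.random.Generator, weeks: int = INTERVENTION_WEEKS
) -> list[EMAPrompt]:
    """The full EMA calendar: weekly schedules (week boundaries at the
    start weekday) plus the two goal-review prompts. Default 4 weeks gives
    16 snippet, 8 mood and 4 well-being prompts for any seed."""
    prompts: list[EMAPrompt] = []
    for w in range(weeks):
        prompts.extend(schedule_ema_week(w + 1, start + timedelta(days=7 * w), rng))
    prompts.extend(goal_review_schedule(start))
    prompts.sort(key=lambda p: (p.scheduled_datetime, p.kind.value))
    return prompts


@dataclass
class PlannedActivity:
    """A participant-logged plan; the app reminds at the planned time."""

    participant_id: str
    description: str
    planned_datetime: datetime
    reminder_sent: bool = False


@dataclass
class ActivityPlanner:
    """Holds planned activities and emits each reminder exactly once."""

    plans: list[PlannedActivity] = field(default_factory=list)

    def plan_activity(
        self,
        profile: ParticipantProfile,
        description: str,
        planned_datetime: datetime,
        now: datetime,
    ) -> PlannedActivity:
        if planned_datetime <= now:
            raise ValueError(
                f"planned time {planned_datetime} is not in the future (now {now})"
            )
        plan = PlannedActivity(profile.participant_id, description, planned_datetime)
        self.plans.append(plan)
        return plan

    def due_reminders(self, now: datetime) -> list[PlannedActivity]:
        """Plans whose time has arrived and whose reminder has not yet
        fired; calling again at a later time never re-emits them."""
        due = [
            p for p in self.plans if not p.reminder_sent and p.planned_datetime <= now
        ]
        for p in due:
            p.reminder_sent = True
        return due
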
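"""Shared vocabulary types for the intervention engine.

The enums here are the tailoring variables every other module speaks:
which kind of activity goal a participant chose, which decision slot the
clock is in, how the weather window was classified, and what happened to
a prompt once a rule fired.
"""

from __future__ import annotations

import enum


class GoalKind(str, enum.Enum):
    """The two activity-goal families a participant can choose between."""

    STEPS = "steps"
    ACTIVE_MINUTES = "active_minutes"


class GoalScope(str, enum.Enum):
    """Which goal kind(s) a message pool serves; ``SHARED`` pools serve both."""

    STEPS = "steps"
    ACTIVE_MINUTES = "active_minutes"
    SHARED = "shared"

    def reaches(self, kind: GoalKind) -> bool:
        return self is GoalScope.SHARED or self.value == kind.value


class Slot(str, enum.Enum):
    """Decision slots of the daily loop.

    HOURLY checks run on the hour from 9:00 to 20:00; the three scheduled
    tailored sends happen at 12:30 (MIDDAY), 17:30 (EVENING) and 20:30
    (NIGHT), participant-local wall clock.
    """

    HOURLY = "hourly"
    MIDDAY = "midday"
    EVENING = "evening"
    NIGHT = "night"


SCHEDULED_SLOTS = (Slot.MIDDAY, Slot.EVENING, Slot.NIGHT)


class WeatherClass(str, enum.Enum):
    GOOD = "good"
    BAD = "bad"


class DeliveryStatus(str, enum.Enum):
    """Outcome of a prompt slot: a message delivered, a delivery failure,
    or a slot evaluated without any rule firing (suppressed)."""

    DELIVERED = "delivered"
    FAILED = "failed"
    SUPPRESSED = "suppressed"


class Rating(str, enum.Enum):
    """Thumbs up / thumbs down response to "Was this useful?" (exclusive)."""

    UP = "up"
    DOWN = "down"
    NONE = "none"


class StageOfChange(str, enum.Enum):
    """Transtheoretical-model stage reported at onboarding."""

    PRECONTEMPLATION = "precontemplation"
    CONTEMPLATION = "contemplation"
    PREPARATION = "preparation"
    ACTION = "action"
    MAINTENANCE = "maintenance"


class EMAKind(str, enum.Enum):
    """Prompt kinds on the EMA calendar.

    ``SNIPPET`` is a voice-memo prompt at 12:30 or 17:30; ``MOOD`` and
    ``WELLBEING`` are evening questionnaires at 20:30; ``GOAL_REVIEW`` is the
    biweekly goal revision prompt.
    """

    SNIPPET = "snippet"
    MOOD = "mood"
    WELLBEING = "wellbeing"
    GOAL_REVIEW = "goal_review"
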
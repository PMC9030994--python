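"""Independent oracles used by several test modules.

The rule-table oracle is a literal truth table written from the
intervention design, independent of the engine's predicate machinery:
option 1 fires only at hourly checks when the goal is met and no
congratulation has gone out yet; options 2 and 3 fire at the scheduled
slots when the goal is not met, split by goal kind and weather.
"""

from __future__ import annotations

from jitaikit.types import GoalKind, Slot, WeatherClass

_SCHEDULED = {
    (GoalKind.STEPS, Slot.MIDDAY, WeatherClass.GOOD): 2,
    (GoalKind.STEPS, Slot.MIDDAY, WeatherClass.BAD): 3,
    (GoalKind.STEPS, Slot.EVENING, WeatherClass.GOOD): 4,
    (GoalKind.STEPS, Slot.EVENING, WeatherClass.BAD): 5,
    (GoalKind.ACTIVE_MINUTES, Slot.MIDDAY, WeatherClass.GOOD): 6,
    (GoalKind.ACTIVE_MINUTES, Slot.MIDDAY, WeatherClass.BAD): 7,
    (GoalKind.ACTIVE_MINUTES, Slot.EVENING, WeatherClass.GOOD): 8,
    (GoalKind.ACTIVE_MINUTES, Slot.EVENING, WeatherClass.BAD): 9,
    (GoalKind.STEPS, Slot.NIGHT, WeatherClass.GOOD): 10,
    (GoalKind.STEPS, Slot.NIGHT, WeatherClass.BAD): 11,
    (GoalKind.ACTIVE_MINUTES, Slot.NIGHT, WeatherClass.GOOD): 12,
    (GoalKind.ACTIVE_MINUTES, Slot.NIGHT, WeatherClass.BAD): 13,
}


def expected_rule_id(
    slot: Slot,
    goal_kind: GoalKind,
    goal_met: bool,
    weather: WeatherClass | None,
    congratulated: bool,
) -> int | None:
    """The rule that should fire for a context, or None."""
    if goal_met:
        if slot is Slot.HOURLY and not congratulated:
            return 1
        return None
    if slot is Slot.HOURLY:
        return None
    return _SCHEDULED[(goal_kind, slot, weather)]


def wear_valid_bruteforce(days) -> bool:
    """Subset-enumeration oracle for the wear criterion: some subset of
    >=4 days exists in which every day has >=16 h wear and at least one
    day is a weekend day."""
    import itertools

    days = list(days)
    for r in range(4, len(days) + 1):
        for combo in itertools.combinations(days, r):
            if all(d.wear_hours >= 16.0 for d in combo) and any(
                d.is_weekend for d in combo
            ):
                return True
    return False
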
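"""Feasibility and acceptability measures computed from log bundles.

Definitions mirror a feasibility-trial report: message delivery rate
(delivered / attempted), data-call success rates, onboarding rate, EMA
compliance as the mean over participants of completed/scheduled (with the
calendar totals 16 snippet / 8 mood / 4 well-being as denominators),
daily goal achievement, the accelerometer wear-validity criterion
(>=4 days of >=16 h wear including at least one weekend day), and Likert
acceptability scores on the 1-5 agreement scale.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decision_engine import ActivityGoal
from .simulate import TrialLogs, WearSummary
from .types import Slot

__all__ = [
    "FeasibilityReport",
    "AcceptabilityScores",
    "compute_feasibility",
    "wear_validity",
    "score_acceptability",
    "goal_achievement_days",
    "WEAR_MIN_VALID_DAYS",
    "WEAR_MIN_HOURS",
]

#: wear-validity criterion: at least this many valid days ...
WEAR_MIN_VALID_DAYS = 4
#: ... each with at least this many hours of wear, including >=1 weekend day
WEAR_MIN_HOURS = 16.0

#: Likert responses counting as agreement ("agreed or strongly agreed")
AGREE_RESPONSES = (4, 5)
LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class FeasibilityReport:
    """Aggregate feasibility measures of one trial (real or simulated).

    Rates are proportions in [0, 1]; a rate whose denominator is empty is
    ``None`` (undefined), never 0. ``ema_compliance`` maps prompt kind to
    (mean, sd, scheduled-per-participant); the SD is the sample SD over
    participants of each participant's completed/scheduled fraction.
    """

    message_delivery_rate: float | None
    activity_call_success: float | None
    weather_call_success: float | None
    onboarding_rate: float | None
    option1_share: float | None
    ema_compliance: dict[str, tuple[float, float, float]]
    goal_achievement_days: dict[str, int]
    wear_valid: dict[tuple[str, str], bool]
    n_messages_attempted: int = 0
    n_messages_delivered: int = 0

    def to_dict(self) -> dict:
        return {
            "message_delivery_rate": self.message_delivery_rate,
            "activity_call_success": self.activity_call_success,
            "weather_call_success": self.weather_call_success,
            "onboarding_rate": self.onboarding_rate,
            "option1_share": self.option1_share,
            "n_messages_attempted": self.n_messages_attempted,
            "n_messages_delivered": self.n_messages_delivered,
            "ema_compliance": {
                kind: {"mean": m, "sd": s, "scheduled_per_participant": n}
                for kind, (m, s, n) in self.ema_compliance.items()
            },
            "goal_achievement_days": dict(self.goal_achievement_days),
            "wear_valid": {
                f"{pid}:{period}": ok for (pid, period), ok in self.wear_valid.items()
            },
        }

    def summary(self) -> str:
        def pct(x):
            return "undefined" if x is None else f"{100 * x:.1f}%"

        lines = [
            "Feasibility report",
            "==================",
            f"messages attempted        {self.n_messages_attempted}",
            f"messages delivered        {self.n_messages_delivered} ({pct(self.message_delivery_rate)})",
            f"option-1 share            {pct(self.option1_share)}",
            f"activity-call success     {pct(self.activity_call_success)}",
            f"weather-call success      {pct(self.weather_call_success)}",
            f"onboarding rate           {pct(self.onboarding_rate)}",
        ]
        for kind, (m, s, n) in self.ema_compliance.items():
            lines.append(
                f"EMA {kind:<10} compliance mean {m:.2f} (SD {s:.2f}) of {n:g} scheduled"
            )
        if self.wear_valid:
            for period in sorted({p for _, p in self.wear_valid}):
                vals = [ok for (pid, pp), ok in self.wear_valid.items() if pp == period]
                lines.append(
                    f"wear valid ({period:<12}) {sum(vals)}/{len(vals)} participants"
                )
        if self.goal_achievement_days:
            days = list(self.goal_achievement_days.values())
            lines.append(
                f"goal-achievement days     mean {np.mean(days):.1f} per participant"
            )
        return "\n".join(lines)


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_feasibility(logs: TrialLogs | Mapping[str, pd.DataFrame]) -> FeasibilityReport:
    """Compute the feasibility measures from a trial log bundle."""
    frames = logs.frames() if isinstance(logs, TrialLogs) else dict(logs)
    events = frames.get("events", pd.DataFrame())
    ema = frames.get("ema", pd.DataFrame())
    wear = frames.get("wear", pd.DataFrame())
    daily = frames.get("daily", pd.DataFrame())
    profiles = frames.get("profiles", pd.DataFrame())

    # --- message delivery ---------------------------------------------------
    attempted = delivered = option1_delivered = 0
    act_ok = act_n = wx_ok = wx_n = 0
    if len(events):
        ids = events["message_id"]
        msg = events[ids.notna() & (ids.astype(str) != "")]
        attempted = len(msg)
        delivered_mask = msg["delivery_status"] == "delivered"
        delivered = int(delivered_mask.sum())
        option1_delivered = int(
            (delivered_mask & (msg["rule_id"].astype(float) == 1)).sum()
        )
        scheduled_rows = events[
            events["slot"].isin([s.value for s in (Slot.MIDDAY, Slot.EVENING, Slot.NIGHT)])
        ]
        act_n = len(scheduled_rows)
        act_ok = int(scheduled_rows["activity_call_ok"].astype(bool).sum())
        wx_n = len(scheduled_rows)
        wx_ok = int(scheduled_rows["weather_call_ok"].astype(bool).sum())

    # --- onboarding ---------------------------------------------------------
    onboarding_rate = None
    if len(profiles):
        onboarding_rate = _rate(int(profiles["onboarded"].astype(bool).sum()), len(profiles))

    # --- EMA compliance -----------------------------------------------------
    compliance: dict[str, tuple[float, float, float]] = {}
    if len(ema):
        for kind, grp in ema.groupby("kind", sort=True):
            per_part = grp.groupby("participant_id")["responded"].agg(
                lambda s: s.astype(bool).mean()
            )
            scheduled = grp.groupby("participant_id").size()
            compliance[str(kind)] = (
                float(per_part.mean()),
                float(per_part.std(ddof=1)) if len(per_part) > 1 else 0.0,
                float(scheduled.mean()),
            )

    # --- goal achievement ---------------------------------------------------
    achievement: dict[str, int] = {}
    if len(daily):
        inter = daily[daily["period"] == "intervention"]
        achievement = (
            inter.groupby("participant_id")["goal_met"]
            .agg(lambda s: int(s.astype(bool).sum()))
            .to_dict()
        )

    # --- wear validity ------------------------------------------------------
    valid: dict[tuple[str, str], bool] = {}
    if len(wear):
        for (pid, period), grp in wear.groupby(["participant_id", "period"], sort=True):
            days = [
                WearSummary(str(pid), dt.date.fromisoformat(str(r.date)), float(r.wear_hours))
                for r in grp.itertuples()
            ]
            valid[(str(pid), str(period))] = wear_validity(days)

    return FeasibilityReport(
        message_delivery_rate=_rate(delivered, attempted),
        activity_call_success=_rate(act_ok, act_n),
        weather_call_success=_rate(wx_ok, wx_n),
        onboarding_rate=onboarding_rate,
        option1_share=_rate(option1_delivered, delivered),
        ema_compliance=compliance,
        goal_achievement_days=achievement,
        wear_valid=valid,
        n_messages_attempted=attempted,
        n_messages_delivered=delivered,
    )


def wear_validity(days: Iterable[WearSummary]) -> bool:
    """True iff at least 4 days reach 16 hours of wear and at least one of
    those valid days falls on a weekend (Saturday/Sunday)."""
    valid = [d for d in days if d.wear_hours >= WEAR_MIN_HOURS]
    return len(valid) >= WEAR_MIN_VALID_DAYS and any(d.is_weekend for d in valid)


@dataclass(frozen=True)
class AcceptabilityScores:
    """Likert acceptability summary.

    ``question_means`` are per-question means over respondents on the 1-5
    scale; a category score is the mean of its question means, also
    reported as a percentage (score / 5). ``agreement`` gives, per
    question, (n agreeing i.e. responding 4 or 5, n responses,
    proportion). Questions with zero responses are excluded and flagged.
    """

    question_means: dict[str, float]
    category_scores: dict[str, float]
    category_percent: dict[str, float]
    agreement: dict[str, tuple[int, int, float]]
    excluded_questions: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "question_means": dict(self.question_means),
            "category_scores": dict(self.category_scores),
            "category_percent": dict(self.category_percent),
            "agreement": {
                q: {"n_agree": a, "n": n, "proportion": p}
                for q, (a, n, p) in self.agreement.items()
            },
            "excluded_questions": list(self.excluded_questions),
        }


def score_acceptability(survey: pd.DataFrame) -> AcceptabilityScores:
    """Score a long-format survey table (participant_id, category,
    question_id, response) with responses coded 1-5."""
    if len(survey):
        coded = survey["response"].astype(float)
        bad = survey[coded.notna() & ~coded.between(LIKERT_MIN, LIKERT_MAX)]
        if len(bad):
            idx = bad.index[0]
            raise ValueError(
                f"row {idx}, column response: {bad.loc[idx, 'response']!r} "
                f"outside the {LIKERT_MIN}-{LIKERT_MAX} Likert scale"
            )
    question_means: dict[str, float] = {}
    agreement: dict[str, tuple[int, int, float]] = {}
    excluded: list[str] = []
    categories: dict[str, list[str]] = {}
    if len(survey):
        for (category, qid), grp in survey.groupby(["category", "question_id"], sort=True):
            responses = grp["response"].astype(float).dropna()
            if responses.empty:
                excluded.append(str(qid))
                continue
            question_means[str(qid)] = float(responses.mean())
            n_agree = int(responses.isin(AGREE_RESPONSES).sum())
            agreement[str(qid)] = (n_agree, len(responses), n_agree / len(responses))
            categories.setdefault(str(category), []).append(str(qid))
    category_scores = {
        cat: float(np.mean([question_means[q] for q in qs]))
        for cat, qs in categories.items()
    }
    category_percent = {cat: s / LIKERT_MAX for cat, s in category_scores.items()}
    return AcceptabilityScores(
        question_means=question_means,
        category_scores=category_scores,
        category_percent=category_percent,
        agreement=agreement,
        excluded_questions=tuple(excluded),
    )


def goal_achievement_days(
    end_of_day_values: Sequence[tuple[dt.date, float]],
    goals: Sequence[ActivityGoal],
) -> int:
    """Days on which the end-of-day value reached the target of the goal
    active that day (the goal with the latest ``set_date`` not after the
    day; goal revisions are respected piecewise)."""
    if not goals:
        return 0
    ordered = sorted(goals, key=lambda g: g.set_date)
    count = 0
    for day, value in end_of_day_values:
        active = None
        for g in ordered:
            if g.set_date <= day:
                active = g
        if active is not None and value >= active.target:
            count += 1
    return count
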
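"""Tailored message bank: loading, validation, rendering, and
anti-repetition selection.

The bank is a JSON file of message records, one pool per decision rule.
The packaged fixture bank has 13 pools holding 136 unique messages
(pool sizes between 10 and 14); a participant on either goal kind can
reach the shared goal-achievement pool plus the six pools specific to
their goal, 75 unique messages in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .types import GoalKind, GoalScope

__all__ = [
    "MessageTemplate",
    "MessageBank",
    "SendHistory",
    "BankParseError",
    "BankValidationError",
    "load_bank",
    "default_bank_path",
    "load_default_bank",
    "select_message",
    "render_message",
    "reachable_message_count",
]

#: pool sizes allowed for a complete bank
POOL_SIZE_RANGE = (10, 14)
#: number of decision rules, hence pools, in a complete bank
N_POOLS = 13

NAME_TOKEN = "[NAME]"


class BankParseError(ValueError):
    """The bank file could not be parsed into message records."""


class BankValidationError(ValueError):
    """A structural invariant of the bank is violated; the message names
    the offending pool or message id."""


@dataclass(frozen=True)
class MessageTemplate:
    """One message in the bank.

    ``body`` may contain the placeholder token ``[NAME]`` which
    :func:`render_message` substitutes with the participant's first name.
    ``figure_ref`` and ``link_ref`` are opaque annotations (an image or
    hyperlink shown alongside the text); they are carried, never fetched.
    """

    message_id: str
    pool_id: str
    goal_scope: GoalScope
    body: str
    figure_ref: str | None = None
    link_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.body:
            raise BankValidationError(f"message {self.message_id!r}: empty body")

    def to_record(self) -> dict:
        rec = {
            "message_id": self.message_id,
            "pool_id": self.pool_id,
            "goal_scope": self.goal_scope.value,
            "body": self.body,
        }
        if self.figure_ref is not None:
            rec["figure_ref"] = self.figure_ref
        if self.link_ref is not None:
            rec["link_ref"] = self.link_ref
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "MessageTemplate":
        try:
            return cls(
                message_id=str(rec["message_id"]),
                pool_id=str(rec["pool_id"]),
                goal_scope=GoalScope(rec["goal_scope"]),
                body=str(rec["body"]),
                figure_ref=rec.get("figure_ref"),
                link_ref=rec.get("link_ref"),
            )
        except KeyError as exc:
            raise BankParseError(f"message record missing field {exc}") from None
        except ValueError as exc:
            if isinstance(exc, BankValidationError):
                raise
            raise BankParseError(f"bad message record {dict(rec)!r}: {exc}") from None


@dataclass(frozen=True)
class MessageBank:
    """Rule-keyed pools of message templates.

    ``pools`` maps pool id to an ordered tuple of templates. A *complete*
    bank (the deployable fixture) has exactly 13 pools of 10-14 messages
    each; partial banks are allowed for testing via ``complete=False``.
    """

    pools: Mapping[str, tuple[MessageTemplate, ...]]
    complete: bool = True

    def __post_init__(self) -> None:
        validate_bank(self, complete=self.complete)

    @classmethod
    def from_templates(
        cls, templates: Iterable[MessageTemplate], complete: bool = True
    ) -> "MessageBank":
        pools: dict[str, list[MessageTemplate]] = {}
        for t in templates:
            pools.setdefault(t.pool_id, []).append(t)
        return cls({k: tuple(v) for k, v in pools.items()}, complete=complete)

    @property
    def pool_ids(self) -> tuple[str, ...]:
        return tuple(self.pools)

    def pool(self, pool_id: str) -> tuple[MessageTemplate, ...]:
        try:
            return self.pools[pool_id]
        except KeyError:
            raise KeyError(f"unknown pool {pool_id!r}") from None

    def templates(self) -> list[MessageTemplate]:
        return [t for pool in self.pools.values() for t in pool]

    def __len__(self) -> int:
        return sum(len(p) for p in self.pools.values())

    def subset(self, pool_ids: Iterable[str]) -> "MessageBank":
        """A partial bank restricted to the given pools (for tests)."""
        keep = set(pool_ids)
        return MessageBank(
            {k: v for k, v in self.pools.items() if k in keep}, complete=False
        )

    def save(self, path: str | Path) -> Path:
        """Write the bank as JSON; ``load_bank`` round-trips it exactly."""
        path = Path(path)
        records = [t.to_record() for t in self.templates()]
        path.write_text(json.dumps(records, indent=1, ensure_ascii=False) + "\n")
        return path


def validate_bank(bank: MessageBank, complete: bool = True) -> None:
    """Raise :class:`BankValidationError` on the first violated invariant."""
    seen: dict[str, str] = {}
    for pool_id, pool in bank.pools.items():
        for t in pool:
            if t.pool_id != pool_id:
                raise BankValidationError(
                    f"message {t.message_id!r} filed under pool {pool_id!r} "
                    f"but declares pool {t.pool_id!r}"
                )
            if t.message_id in seen:
                raise BankValidationError(
                    f"duplicate message_id {t.message_id!r} "
                    f"(pools {seen[t.message_id]!r} and {pool_id!r})"
                )
            seen[t.message_id] = pool_id
        scopes = {t.goal_scope for t in pool}
        if len(scopes) > 1:
            raise BankValidationError(
                f"pool {pool_id!r} mixes goal scopes {sorted(s.value for s in scopes)}"
            )
        if not pool:
            raise BankValidationError(f"pool {pool_id!r} is empty")
    if complete:
        lo, hi = POOL_SIZE_RANGE
        if len(bank.pools) != N_POOLS:
            raise BankValidationError(
                f"bank has {len(bank.pools)} pools, expected {N_POOLS}"
            )
        for pool_id, pool in bank.pools.items():
            if not lo <= len(pool) <= hi:
                raise BankValidationError(
                    f"pool {pool_id!r} has {len(pool)} messages, "
                    f"expected between {lo} and {hi}"
                )


def load_bank(path: str | Path, complete: bool = True) -> MessageBank:
    """Load and validate a JSON message bank.

    Parameters
    ----------
    path
        JSON file holding a list of message records.
    complete
        Enforce the full structural invariants (13 pools of 10-14
        messages). Set to ``False`` to load partial banks in tests.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise BankParseError(f"{path}: empty bank file")
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BankParseError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(records, list):
        raise BankParseError(f"{path}: expected a JSON list of message records")
    templates = [MessageTemplate.from_record(r) for r in records]
    return MessageBank.from_templates(templates, complete=complete)


def default_bank_path() -> Path:
    """Location of the packaged fixture bank (136 messages, 13 pools)."""
    return Path(resources.files("jitaikit").joinpath("data/message_bank.json"))


def load_default_bank() -> MessageBank:
    return load_bank(default_bank_path())


@dataclass
class SendHistory:
    """Per-participant record of which messages have been used, per pool.

    Selection is without replacement within a pool: once every message in
    a pool has been used for a participant, the pool's history resets and
    selection restarts over the full pool.
    """

    participant_id: str
    sent: dict[str, set[str]] = field(default_factory=dict)

    def sent_in_pool(self, pool_id: str) -> set[str]:
        return self.sent.setdefault(pool_id, set())

    def record(self, pool_id: str, message_id: str) -> None:
        self.sent_in_pool(pool_id).add(message_id)

    def reset_pool(self, pool_id: str) -> None:
        self.sent[pool_id] = set()


def select_message(
    bank: MessageBank,
    pool_id: str,
    history: SendHistory,
    rng: np.random.Generator,
) -> MessageTemplate:
    """Draw uniformly from the pool's not-yet-used messages.

    The draw is recorded in ``history``; when the pool is exhausted the
    history for that pool is reset first and selection restarts over the
    full pool. Deterministic for a given generator state.
    """
    pool = bank.pool(pool_id)
    used = history.sent_in_pool(pool_id)
    remaining = [t for t in pool if t.message_id not in used]
    if not remaining:
        history.reset_pool(pool_id)
        remaining = list(pool)
    choice = remaining[int(rng.integers(len(remaining)))]
    history.record(pool_id, choice.message_id)
    return choice


def render_message(template: MessageTemplate, profile) -> str:
    """Substitute every ``[NAME]`` token with the participant's first name.

    All other text is returned byte-identical. ``profile`` needs only a
    non-empty ``first_name`` attribute.
    """
    first_name = getattr(profile, "first_name", profile)
    if not isinstance(first_name, str) or not first_name:
        raise ValueError("participant first name must be a non-empty string")
    return template.body.replace(NAME_TOKEN, first_name)


def reachable_message_count(bank: MessageBank, goal_kind: GoalKind | str) -> int:
    """Number of unique messages a participant with this goal kind can
    ever receive: the union of pools whose scope is the goal kind or
    shared (shared pools count once)."""
    goal_kind = GoalKind(goal_kind)
    ids = {
        t.message_id
        for pool in bank.pools.values()
        for t in pool
        if t.goal_scope.reaches(goal_kind)
    }
    return len(ids)


def _unused(bank: MessageBank, pool_id: str, history: SendHistory) -> list[str]:
    """Message ids still unsent in a pool (diagnostics/tests)."""
    used = history.sent.get(pool_id, set())
    return [t.message_id for t in bank.pool(pool_id) if t.message_id not in used]
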
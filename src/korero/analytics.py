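"""Privacy-safe event logging and open-trial cohort summaries.

Only the *series of activities and intents* is ever logged: event payloads
carry module ids, intent ids, phases and scores, never raw user text.
Cohort summaries reproduce the arithmetic of a pre/post single-item open
trial: registration/login/target-age funnel counts, demographic
percentages over target-age users, pre-post completion, and the mean (SD)
of the 0-10 worry item before and after.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "Event",
    "EventLog",
    "PrivacyViolation",
    "UserRecord",
    "CohortSummary",
    "PrePostSummary",
    "append_event",
    "summarize_cohort",
    "prepost_summary",
    "round_half_up",
    "users_to_csv",
    "users_from_csv",
]

EventType = Literal[
    "registration",
    "session_start",
    "module_start",
    "module_complete",
    "intent_detected",
    "priority_digression",
    "assessment",
    "risk_escalation",
    "session_end",
]

#: Payload keys that would carry raw user text; appending such an event is
#: a privacy violation.
FREE_TEXT_KEYS = frozenset(
    {"text", "utterance", "message", "input", "free_text", "raw"}
)


class PrivacyViolation(ValueError):
    """Raised when an event payload would log raw user text."""


class Event(BaseModel):
    model_config = ConfigDict(extra="forbid")

    timestamp: str  # ISO-8601
    user_id: str
    type: EventType
    payload: dict[str, object] = Field(default_factory=dict)

    @field_validator("payload")
    @classmethod
    def _no_free_text(cls, payload: dict) -> dict:
        bad = FREE_TEXT_KEYS & set(payload)
        if bad:
            raise PrivacyViolation(
                f"payload keys {sorted(bad)} would log raw user text"
            )
        return payload


@dataclass
class EventLog:
    """Append-only usage log; serializable as JSON-lines."""

    events: list[Event] = field(default_factory=list)

    def append(self, event: Event) -> "EventLog":
        bad = FREE_TEXT_KEYS & set(event.payload)
        if bad:  # construction normally rejects this; guard bypasses too
            raise PrivacyViolation(
                f"payload keys {sorted(bad)} would log raw user text"
            )
        self.events.append(event)
        return self

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_type(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(e.model_dump(mode="json"), sort_keys=True) + "\n"
            for e in self.events
        )

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        log = cls()
        for line in text.splitlines():
            if line.strip():
                log.append(Event.model_validate(json.loads(line)))
        return log


def append_event(log: EventLog, event: Event) -> EventLog:
    """Append one well-formed event (payloads with free-text keys raise)."""
    return log.append(event)


class UserRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    user_id: str
    age: int = Field(ge=0)
    gender: str
    ethnicity: str
    registered_at: str = ""


def users_to_csv(users: Iterable[UserRecord]) -> str:
    df = pd.DataFrame([u.model_dump() for u in users])
    return df.to_csv(index=False)


def users_from_csv(text: str) -> list[UserRecord]:
    import io

    df = pd.read_csv(io.StringIO(text), dtype={"user_id": str}, keep_default_na=False)
    return [UserRecord.model_validate(rec) for rec in df.to_dict("records")]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (matches how trial reports print percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class PrePostSummary(BaseModel):
    mean_pre: Optional[float] = None
    sd_pre: Optional[float] = None
    mean_post: Optional[float] = None
    sd_post: Optional[float] = None
    n: int = 0


class CohortSummary(BaseModel):
    n_registered: int
    n_logged_in: int
    n_target_age: int
    pct_by_gender: dict[str, float]
    pct_by_ethnicity: dict[str, float]
    n_prepost_completers: int
    prepost_denominator: int
    pct_prepost: Optional[float] = None
    mean_pre: Optional[float] = None
    sd_pre: Optional[float] = None
    mean_post: Optional[float] = None
    sd_post: Optional[float] = None
    n_returned: int = 0

    def to_table(self) -> str:
        rows = [
            ("registrations", self.n_registered),
            ("logged in", self.n_logged_in),
            ("target age (13-24)", self.n_target_age),
            ("returned (>=2 sessions)", self.n_returned),
            ("pre-post completers", self.n_prepost_completers),
            ("pre-post denominator", self.prepost_denominator),
            ("pre-post completion %", self.pct_prepost),
            ("mean pre (SD)", f"{self.mean_pre} ({self.sd_pre})"),
            ("mean post (SD)", f"{self.mean_post} ({self.sd_post})"),
        ]
        for cat, pct in sorted(self.pct_by_gender.items()):
            rows.append((f"gender {cat} %", pct))
        for cat, pct in sorted(self.pct_by_ethnicity.items()):
            rows.append((f"ethnicity {cat} %", pct))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _pct_breakdown(series: pd.Series) -> dict[str, float]:
    n = len(series)
    if n == 0:
        return {}
    counts = series.value_counts()
    return {
        str(cat): round_half_up(100.0 * k / n, 1) for cat, k in counts.items()
    }


def _session_scores(log: EventLog, user_ids: set[str]):
    """Per (user, session_index): first pre-phase score and any outro score."""
    pre: dict[tuple[str, int], int] = {}
    post: dict[tuple[str, int], int] = {}
    for e in log.of_type("assessment"):
        if e.user_id not in user_ids:
            continue
        phase = e.payload.get("phase")
        sidx = int(e.payload.get("session_index", 1))  # type: ignore[arg-type]
        score = int(e.payload.get("score"))  # type: ignore[arg-type]
        key = (e.user_id, sidx)
        if phase in ("onboarding", "intro"):
            pre.setdefault(key, score)
        elif phase == "outro":
            post.setdefault(key, score)
    return pre, post


def _completer_pairs(log: EventLog, user_ids: set[str]):
    """One (pre, post) pair per completer: both scores in the same session;
    pre is the first intro/onboarding score of that session. A user's first
    completed session is used if they complete more than one."""
    pre, post = _session_scores(log, user_ids)
    pairs: dict[str, tuple[int, int]] = {}
    for key in sorted(post):
        uid, _ = key
        if key in pre and uid not in pairs:
            pairs[uid] = (pre[key], post[key])
    return pairs


def prepost_summary(log: EventLog, target_age_users: set[str]) -> PrePostSummary:
    """Mean/SD of the worry item pre and post, over completers only.

    A completer recorded both the session-start score and the outro recheck
    within the same session. SD is the sample standard deviation (n-1);
    values are rounded to 1 decimal place. n<1 yields absent means, n<2
    absent SDs.
    """
    pairs = _completer_pairs(log, target_age_users)
    if not pairs:
        return PrePostSummary(n=0)
    pre = pd.Series([p[0] for p in pairs.values()], dtype=float)
    post = pd.Series([p[1] for p in pairs.values()], dtype=float)
    out = PrePostSummary(
        n=len(pairs),
        mean_pre=round_half_up(pre.mean(), 1),
        mean_post=round_half_up(post.mean(), 1),
    )
    if len(pairs) >= 2:
        out.sd_pre = round_half_up(pre.std(ddof=1), 1)
        out.sd_post = round_half_up(post.std(ddof=1), 1)
    return out


def summarize_cohort(
    log: EventLog,
    users: list[UserRecord],
    target_age: tuple[int, int] = (13, 24),
) -> CohortSummary:
    """Derive the uptake/outcome summary table from users and events.

    Demographic percentages are computed over target-age users (bounds
    inclusive), percentage = 100*k/n rounded half-up to 1 decimal place
    (0 dp for the pre-post completion rate). The pre-post denominator is
    the target-age users who recorded a session-start score and reached
    the outro offer; completers additionally recorded the outro score.
    """
    if not users:
        return CohortSummary(
            n_registered=0,
            n_logged_in=0,
            n_target_age=0,
            pct_by_gender={},
            pct_by_ethnicity={},
            n_prepost_completers=0,
            prepost_denominator=0,
        )
    known = {u.user_id for u in users}
    for e in log:
        if e.user_id not in known:
            raise ValueError(f"event for unregistered user {e.user_id!r}")

    df = pd.DataFrame([u.model_dump() for u in users])
    logged_in = {e.user_id for e in log.of_type("session_start")}
    lo, hi = target_age
    target = df[(df.age >= lo) & (df.age <= hi) & df.user_id.isin(logged_in)]
    target_ids = set(target.user_id)

    sessions_per_user: dict[str, set[int]] = {}
    for e in log.of_type("session_start"):
        if e.user_id in target_ids:
            sessions_per_user.setdefault(e.user_id, set()).add(
                int(e.payload.get("session_index", 1))  # type: ignore[arg-type]
            )
    n_returned = sum(1 for s in sessions_per_user.values() if len(s) >= 2)

    # denominator: pre score recorded and outro module reached
    pre, post = _session_scores(log, target_ids)
    reached_outro: set[str] = set()
    for e in log.of_type("module_start"):
        if e.user_id in target_ids and e.payload.get("outro"):
            reached_outro.add(e.user_id)
    denom_users = {uid for uid, _ in pre} & reached_outro
    pairs = _completer_pairs(log, target_ids)
    completers = set(pairs) & denom_users

    pp = prepost_summary(log, target_ids)
    summary = CohortSummary(
        n_registered=len(users),
        n_logged_in=len(logged_in & known),
        n_target_age=len(target_ids),
        pct_by_gender=_pct_breakdown(target.gender),
        pct_by_ethnicity=_pct_breakdown(target.ethnicity),
        n_prepost_completers=len(completers),
        prepost_denominator=len(denom_users),
        n_returned=n_returned,
        mean_pre=pp.mean_pre,
        sd_pre=pp.sd_pre,
        mean_post=pp.mean_post,
        sd_post=pp.sd_post,
    )
    if denom_users:
        summary.pct_prepost = round_half_up(
            100.0 * len(completers) / len(denom_users), 0
        )
    return summary
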
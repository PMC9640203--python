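"""Delivery channels: deterministic scripted replay and an interactive console.

The engine is channel-agnostic; a channel takes :class:`TurnResult`
messages, annotates pacing (a typing indicator plus a short delay before
each bubble gives the conversation a human rhythm), and feeds user input
back in. The scripted channel replays a fixed input sequence and records
a transcript that is byte-identical across runs for a fixed (graph,
script, seed) — the backbone of the test suite.
"""

from __future__ import annotations

import json
import sys
import time
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import engine as _engine
from .analytics import EventLog
from .messages import OutboundMessage, TurnResult, UserInput
from .model import DialogGraph
from .nlu import IntentRegistry, RiskLexicon

__all__ = [
    "PacingConfig",
    "Script",
    "Transcript",
    "TranscriptEntry",
    "apply_pacing",
    "pacing_delay",
    "replay_script",
    "run_console",
]


class PacingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    base_ms: int = 300
    rate_ms_per_char: int = 10
    cap_ms: int = 2000
    test_mode: bool = False


def pacing_delay(message: OutboundMessage, config: PacingConfig) -> int:
    """Delay in ms before a message: ``min(cap, base + rate * chars)``;
    always 0 in test mode and for typing indicators themselves."""
    if config.test_mode or message.kind == "typing_on":
        return 0
    chars = len(message.text or "")
    return min(config.cap_ms, config.base_ms + config.rate_ms_per_char * chars)


def apply_pacing(
    messages: list[OutboundMessage], config: PacingConfig
) -> list[OutboundMessage]:
    """Annotate delays, inserting a typing indicator before each delayed
    text bubble. Never reorders or alters content."""
    out: list[OutboundMessage] = []
    for msg in messages:
        delay = pacing_delay(msg, config)
        if delay > 0 and msg.kind == "text":
            out.append(OutboundMessage(kind="typing_on", pacing_ms=delay))
        out.append(msg.model_copy(update={"pacing_ms": delay}))
    return out


class Script(BaseModel):
    """Ordered scripted user inputs (YAML: a list of one-key mappings
    ``text:``/``option:``/``score:``/``decline:``)."""

    model_config = ConfigDict(extra="forbid")

    steps: list[UserInput] = Field(min_length=1)

    @classmethod
    def from_yaml(cls, text: str) -> "Script":
        raw = yaml.safe_load(text)
        steps = []
        for item in raw if isinstance(raw, list) else raw.get("steps", []):
            if isinstance(item, dict):
                (key, value), = item.items()
                if key == "decline":
                    steps.append(UserInput.decline())
                elif key == "score":
                    steps.append(UserInput.score(int(value)))
                elif key in ("text", "option"):
                    steps.append(UserInput(kind=key, value=str(value)))
                else:
                    raise ValueError(f"unknown script step {key!r}")
            else:
                steps.append(UserInput.text(str(item)))
        return cls(steps=steps)


class TranscriptEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    turn: int
    direction: str  # "out" | "in" | "rejected"
    message: Optional[OutboundMessage] = None
    input: Optional[UserInput] = None


class Transcript(BaseModel):
    model_config = ConfigDict(extra="forbid")

    entries: list[TranscriptEntry] = Field(default_factory=list)
    ended: bool = False

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(e.model_dump(mode="json", exclude_none=True), sort_keys=True)
            + "\n"
            for e in self.entries
        )

    def outbound_texts(self) -> list[str]:
        return [
            e.message.text
            for e in self.entries
            if e.message is not None and e.message.kind == "text"
        ]


def _record_turn(
    transcript: Transcript, turn: int, result: TurnResult, config: PacingConfig
) -> None:
    for msg in apply_pacing(result.outbound, config):
        transcript.entries.append(
            TranscriptEntry(turn=turn, direction="out", message=msg)
        )


def replay_script(
    graph: DialogGraph,
    script: Script,
    seed: int = 0,
    *,
    user_id: str = "scripted-user",
    prior: Optional[Union[str, "_engine.Session"]] = None,
    registry: Optional[IntentRegistry] = None,
    lexicon: Optional[RiskLexicon] = None,
    log: Optional[EventLog] = None,
    pacing: Optional[PacingConfig] = None,
) -> tuple[Transcript, "_engine.Session"]:
    """Drive a full session from a script; deterministic for fixed inputs.

    Mismatched input (e.g. text where a score is awaited) is recorded as a
    rejected input followed by the engine's re-prompt; the script then
    continues with the next step.
    """
    config = pacing or PacingConfig(test_mode=True)
    transcript = Transcript()
    session, result = _engine.start_session(
        graph, user_id, prior=prior, seed=seed, log=log
    )
    turn = 0
    _record_turn(transcript, turn, result, config)
    for step in script.steps:
        if result.ended:
            break
        turn += 1
        expected = result.awaiting.kind if result.awaiting else None
        ok = (
            expected == "assessment"
            and step.kind in ("score", "decline")
            or expected == "quick_reply"
            and step.kind in ("option", "text")
            or expected == "free_text"
            and step.kind in ("text", "option")
        )
        transcript.entries.append(
            TranscriptEntry(
                turn=turn, direction="in" if ok else "rejected", input=step
            )
        )
        result = _engine.advance_turn(
            session, graph, step, registry=registry, lexicon=lexicon, log=log
        )
        _record_turn(transcript, turn, result, config)
    transcript.ended = result.ended
    return transcript, session


def run_console(
    graph: DialogGraph,
    *,
    user_id: str = "console-user",
    prior: Optional[str] = None,
    seed: int = 0,
    registry: Optional[IntentRegistry] = None,
    lexicon: Optional[RiskLexicon] = None,
    log: Optional[EventLog] = None,
    pacing: Optional[PacingConfig] = None,
    stdin=None,
    stdout=None,
) -> "_engine.Session":
    """Interactive console session (used by the ``korero run`` command)."""
    config = pacing or PacingConfig()
    stdin = stdin or sys.stdin
    stdout = stdout or sys.stdout
    session, result = _engine.start_session(
        graph, user_id, prior=prior, seed=seed, log=log
    )
    while True:
        for msg in apply_pacing(result.outbound, config):
            if msg.pacing_ms and not config.test_mode:
                time.sleep(msg.pacing_ms / 1000.0)
            if msg.kind == "text":
                print(msg.text, file=stdout)
            elif msg.kind == "attachment":
                ref = msg.attachment
                print(f"[{ref.kind}: {ref.uri_or_path}]", file=stdout)
        if result.ended:
            break
        if result.awaiting.kind == "quick_reply" and result.awaiting.options:
            print(f"  options: {' | '.join(result.awaiting.options)}", file=stdout)
        line = stdin.readline()
        if not line:
            break
        line = line.strip()
        if result.awaiting.kind == "assessment":
            if line.lower() in ("skip", ""):
                step = UserInput.decline()
            else:
                try:
                    step = UserInput.score(int(line))
                except ValueError:
                    step = UserInput.text(line)
        elif result.awaiting.kind == "quick_reply":
            step = (
                UserInput.option(line)
                if result.awaiting.options and line in result.awaiting.options
                else UserInput.text(line)
            )
        else:
            step = UserInput.text(line)
        result = _engine.advance_turn(
            session, graph, step, registry=registry, lexicon=lexicon, log=log
        )
    return session
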
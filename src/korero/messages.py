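"""Turn-level value types shared by the engine, safety protocol and channels."""

from __future__ import annotations

from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .model import AttachmentRef

__all__ = ["OutboundMessage", "AwaitState", "TurnResult", "UserInput"]


class OutboundMessage(BaseModel):
    """One bubble dispatched to the user.

    ``typing_on`` messages model the channel's typing indicator: they carry
    no payload, only a pacing delay.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["text", "attachment", "typing_on"]
    text: Optional[str] = None
    attachment: Optional[AttachmentRef] = None
    pacing_ms: int = 0

    @model_validator(mode="after")
    def _payload_consistent(self) -> "OutboundMessage":
        if self.kind == "typing_on" and (self.text or self.attachment):
            raise ValueError("typing_on messages carry no payload")
        if self.kind == "text" and self.text is None:
            raise ValueError("text message requires text")
        if self.kind == "attachment" and self.attachment is None:
            raise ValueError("attachment message requires an attachment")
        if self.pacing_ms < 0:
            raise ValueError("pacing_ms must be non-negative")
        return self


class AwaitState(BaseModel):
    """What the session is waiting for at the end of a turn."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["free_text", "quick_reply", "assessment"]
    node_id: Optional[str] = None  # None for engine-synthesised prompts (menu)
    options: Optional[list[str]] = None  # quick_reply only
    scale: Optional[tuple[int, int]] = None  # assessment only


class TurnResult(BaseModel):
    """Everything produced by one dialog turn.

    Invariant: ``awaiting is None`` exactly when the session has ended.
    """

    model_config = ConfigDict(extra="forbid")

    outbound: list[OutboundMessage]
    awaiting: Optional[AwaitState] = None
    ended: bool = False

    @model_validator(mode="after")
    def _awaiting_xor_ended(self) -> "TurnResult":
        if (self.awaiting is None) != self.ended:
            raise ValueError("awaiting is None iff session ended")
        return self


class UserInput(BaseModel):
    """One inbound user action: typed text, a tapped option, a scale score,
    or an explicit decline of an optional prompt."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["text", "option", "score", "decline"]
    value: Union[str, int, None] = None

    @classmethod
    def text(cls, value: str) -> "UserInput":
        return cls(kind="text", value=value)

    @classmethod
    def option(cls, value: str) -> "UserInput":
        return cls(kind="option", value=value)

    @classmethod
    def score(cls, value: int) -> "UserInput":
        return cls(kind="score", value=value)

    @classmethod
    def decline(cls) -> "UserInput":
        return cls(kind="decline")
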
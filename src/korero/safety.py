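"""Risk-escalation protocol: confirm, empathise, signpost a helpline, shut down.

A self-harm match in user input — at any point in the dialog — preempts
all other routing. The protocol is a fixed two-phase sequence:

1. *Confirmation*: ask the user to confirm the reading of their message.
2. On **yes**: an expression of empathy, direction to a help hotline, and
   shutdown of the automated dialog (the session ends; no further turns
   are accepted). On **no**: a brief acknowledgement and a gentle resume
   at the interrupted node.

The denial path is this package's choice (the protocol requires a
confirmation step, so a denial branch must exist); resuming where the
user left off is the least disruptive option. All texts live in
:class:`korero.model.EscalationConfig` — configuration, not code — and the
shipped fixture uses a placeholder helpline, never a real number.
"""

from __future__ import annotations

from typing import Optional

from .analytics import EventLog
from .messages import AwaitState, OutboundMessage, TurnResult
from .model import EscalationConfig

__all__ = ["begin_escalation", "run_escalation"]

CONFIRM_OPTIONS = ["yes", "no"]


def begin_escalation(
    session,
    config: EscalationConfig,
    origin: Optional[str] = None,
    outbound: Optional[list[OutboundMessage]] = None,
) -> TurnResult:
    """Phase 1: emit the confirmation prompt and await yes/no.

    ``origin`` is the node the user was at when risk was detected; a
    denial resumes there.
    """
    out = list(outbound or [])
    out.append(OutboundMessage(kind="text", text=config.confirm_prompt))
    session.mode = "escalation"
    session.escalation_origin = origin
    session.awaiting = AwaitState(
        kind="quick_reply", node_id=None, options=list(CONFIRM_OPTIONS)
    )
    return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)


def run_escalation(
    session,
    config: EscalationConfig,
    confirm_input: Optional[bool] = None,
    *,
    graph=None,
    log: Optional[EventLog] = None,
) -> TurnResult:
    """Drive the escalation state machine.

    With no ``confirm_input`` this is phase 1 (delegates to
    :func:`begin_escalation`). ``True`` ends the session after empathy and
    hotline messages and logs exactly one ``risk_escalation`` event;
    ``False`` resumes at the interrupted node with a re-prompt.
    """
    from . import engine as _engine  # deferred: engine imports this module

    if confirm_input is None and session.mode != "escalation":
        return begin_escalation(session, config, origin=session.position or None)

    out: list[OutboundMessage] = []
    if confirm_input is True:
        out.append(OutboundMessage(kind="text", text=config.empathy_text))
        out.append(OutboundMessage(kind="text", text=config.hotline_text))
        _engine._log(session, log, "risk_escalation", confirmed=True)
        return _engine._end_session(session, out, log)
    if confirm_input is False:
        out.append(OutboundMessage(kind="text", text=config.decline_return_text))
        session.mode = "node"
        origin_id = session.escalation_origin
        session.escalation_origin = None
        if origin_id is not None and graph is not None:
            session.position = origin_id
            node = graph.node(origin_id)
            out.extend(_engine._prompt_for(node))
            session.awaiting = _engine._await_for(node)
            return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)
        if graph is not None:
            return _engine._menu_turn(session, graph, out)
        return _engine._end_session(session, out, log)
    # unintelligible answer to a safety question: ask again verbatim
    out.append(OutboundMessage(kind="text", text=config.confirm_prompt))
    session.awaiting = AwaitState(
        kind="quick_reply", node_id=None, options=list(CONFIRM_OPTIONS)
    )
    return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)
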
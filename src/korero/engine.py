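"""Deterministic dialog-turn execution over a validated graph.

A *dialog turn* traverses the graph from the user's current vertex,
emitting message bubbles and applying invisible branch/update nodes, until
a vertex that requires user input (or session end) is reached. The engine
is purely functional over session state plus an append-only event log: it
never sleeps (pacing is annotated by :mod:`korero.channels`) and, given the
same graph, seed and input sequence, reproduces byte-identical transcripts.

Sessions persist across visits through a JSON archive; a re-entry session
(``session_index > 1``) sets the ``returning`` variable so content can
abbreviate onboarding to a greeting plus the brief assessment, as the
demo pack does.
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime, timedelta, timezone
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from . import safety
from .analytics import Event, EventLog
from .messages import AwaitState, OutboundMessage, TurnResult, UserInput
from .model import (
    AssessmentNode,
    AttachmentRef,
    BranchNode,
    Condition,
    DialogGraph,
    DialogModule,
    ExitModuleNode,
    FreeTextNode,
    MessageNode,
    QuickRepliesNode,
    RichMediaNode,
    UpdateValueNode,
)
from .nlu import IntentRegistry, RiskLexicon, resolve_routing

__all__ = [
    "AssessmentRecord",
    "EngineError",
    "Session",
    "advance_turn",
    "apply_update",
    "evaluate_branch",
    "offer_module_menu",
    "record_assessment",
    "save_item",
    "start_session",
]

DEFAULT_MAX_STEPS = 200
MENU_PROMPT = "What would you like to try?"
FINISH_OPTION = "Finish up"
REPROMPT_PREFIX = "Sorry, I didn't quite catch that."
_EPOCH = datetime(2020, 4, 1, tzinfo=timezone.utc)

SCHEMA_VERSION = 1


class EngineError(RuntimeError):
    """Protocol misuse or a content bug surfaced at run time."""


class AssessmentRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    item_id: str
    phase: Literal["onboarding", "intro", "outro"]
    score: int
    session_index: int


class Session(BaseModel):
    """Live per-user state; archives to JSON between visits."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    user_id: str
    graph_id: str
    position: str = ""
    variables: dict[str, object] = Field(default_factory=dict)
    modules_started: list[str] = Field(default_factory=list)
    modules_completed: list[str] = Field(default_factory=list)
    digression_origin: Optional[str] = None
    saved_items: list[AttachmentRef] = Field(default_factory=list)
    assessments: list[AssessmentRecord] = Field(default_factory=list)
    session_index: int = 1
    ended: bool = False
    rng_seed: int = 0
    # engine bookkeeping
    mode: Literal["node", "menu", "escalation"] = "node"
    awaiting: Optional[AwaitState] = None
    escalation_origin: Optional[str] = None
    current_module: Optional[str] = None
    event_seq: int = 0
    trace: list[str] = Field(default_factory=list)

    def to_archive(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_archive(cls, text: str) -> "Session":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise EngineError(f"corrupt session archive: {exc}") from exc
        return cls.model_validate(data)


def _stamp(session: Session) -> str:
    """Deterministic logical timestamp (one tick per event)."""
    session.event_seq += 1
    return (_EPOCH + timedelta(seconds=session.event_seq)).isoformat()


def _log(session: Session, log: Optional[EventLog], type_: str, **payload) -> None:
    if log is None:
        return
    log.append(
        Event(
            timestamp=_stamp(session),
            user_id=session.user_id,
            type=type_,
            payload=payload,
        )
    )


def _text(s: str) -> OutboundMessage:
    return OutboundMessage(kind="text", text=s)


def _default_registry() -> IntentRegistry:
    from .fixtures import default_intents

    return default_intents()


def _default_lexicon() -> RiskLexicon:
    from .fixtures import default_risk_lexicon

    return default_risk_lexicon()


# ---------------------------------------------------------------------------
# condition / update primitives


def _compare(value: object, op: str, operand: object) -> Optional[bool]:
    """Three-valued comparison; None means not evaluable (-> default edge)."""
    if op == "is_set":
        return value is not None
    if value is None:
        return None
    if op in ("eq", "ne"):
        same = value == operand or str(value) == str(operand)
        return same if op == "eq" else not same
    try:
        a, b = float(value), float(operand)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        if isinstance(value, str) and isinstance(operand, str):
            a, b = value, operand  # lexicographic on short strings
        else:
            return None
    return {"lt": a < b, "le": a <= b, "gt": a > b, "ge": a >= b}[op]


def evaluate_branch(session: Session, node: BranchNode) -> str:
    """Deterministically pick the outgoing edge label for a branch node.

    An unset variable under any operator except ``is_set`` routes to
    ``default``; so does a type-incompatible comparison.
    """
    value = session.variables.get(node.condition.variable)
    outcome = _compare(value, node.condition.op, node.condition.value)
    if outcome is None:
        label = "default"
    else:
        label = "true" if outcome else "false"
    if label not in node.branches:
        if "default" in node.branches:
            return "default"
        raise EngineError(
            f"branch {node.id!r} has no edge for {label!r} and no default"
        )
    return label


def condition_holds(session: Session, cond: Condition) -> bool:
    """Strict check used for module serve conditions (unset -> False)."""
    return _compare(session.variables.get(cond.variable), cond.op, cond.value) is True


def apply_update(session: Session, node: UpdateValueNode) -> Session:
    """Set/overwrite a session variable; emits nothing to the user."""
    if node.expr is not None:
        parts = node.expr.split()
        if len(parts) != 3 or parts[1] not in ("+", "-"):
            raise EngineError(f"unparseable expression {node.expr!r} at {node.id!r}")
        name, op, lit = parts
        base = session.variables.get(name)
        if base is None:
            warnings.warn(
                f"update {node.id!r}: variable {name!r} unset, using 0",
                stacklevel=2,
            )
            base = 0
        try:
            base_i = int(base)  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise EngineError(f"non-integer base in {node.expr!r}") from exc
        delta = int(lit)
        session.variables[node.variable] = (
            base_i + delta if op == "+" else base_i - delta
        )
    else:
        session.variables[node.variable] = node.value
    return session


# ---------------------------------------------------------------------------
# menu / assessments / saved items


def offer_module_menu(session: Session, graph: DialogGraph) -> list[str]:
    """Ordered module ids to offer: serveable activity modules, with
    never-tried modules first (users are nudged toward new skills), pack
    order preserved within each band; completed non-repeatable modules drop
    out."""
    tried = set(session.modules_started)
    completed = set(session.modules_completed)
    fresh: list[str] = []
    again: list[str] = []
    for m in graph.modules:
        if "onboarding" in m.tags or "outro" in m.tags:
            continue
        if m.serve_condition is not None and not condition_holds(
            session, m.serve_condition
        ):
            continue
        if not m.repeatable and m.id in completed:
            continue
        (again if m.id in tried else fresh).append(m.id)
    return fresh + again


def record_assessment(
    session: Session,
    node: AssessmentNode,
    score: int,
    log: Optional[EventLog] = None,
) -> Session:
    """Append one assessment record; phase is derived from context:
    the first administration of a session is ``onboarding`` (first-ever
    session) or ``intro``, any later one is the outro recheck."""
    if not (node.scale_min <= score <= node.scale_max):
        raise EngineError(
            f"score {score} outside [{node.scale_min}, {node.scale_max}]"
        )
    already = any(
        a.session_index == session.session_index for a in session.assessments
    )
    if already:
        phase = "outro"
    elif session.session_index == 1:
        phase = "onboarding"
    else:
        phase = "intro"
    session.assessments.append(
        AssessmentRecord(
            item_id=node.item_id,
            phase=phase,
            score=score,
            session_index=session.session_index,
        )
    )
    _log(
        session,
        log,
        "assessment",
        item=node.item_id,
        phase=phase,
        score=score,
        session_index=session.session_index,
    )
    return session


def save_item(session: Session, attachment: AttachmentRef) -> Session:
    """Save a poster/attachment for later; refuses non-saveable media and
    de-duplicates by path."""
    if not attachment.saveable:
        raise EngineError(f"attachment {attachment.uri_or_path!r} is not saveable")
    if all(a.uri_or_path != attachment.uri_or_path for a in session.saved_items):
        session.saved_items.append(attachment)
    return session


# ---------------------------------------------------------------------------
# traversal core


def _enter_module(
    session: Session, graph: DialogGraph, module: DialogModule, log: Optional[EventLog]
) -> None:
    if session.current_module != module.id:
        session.current_module = module.id
        if module.id not in session.modules_started:
            session.modules_started.append(module.id)
        _log(
            session,
            log,
            "module_start",
            module=module.id,
            outro="outro" in module.tags,
        )


def _prompt_for(node, clarify: bool = False) -> list[OutboundMessage]:
    """(Re-)emit the input prompt of an input-requiring node."""
    out: list[OutboundMessage] = []
    if clarify:
        out.append(_text(REPROMPT_PREFIX))
    if isinstance(node, (QuickRepliesNode, FreeTextNode)):
        out.append(_text(node.prompt))
    elif isinstance(node, AssessmentNode):
        prompt = node.prompt or (
            f"On a scale of {node.scale_min} to {node.scale_max}, where "
            f"{node.scale_min} is “{node.anchors[0]}” and "
            f"{node.scale_max} is “{node.anchors[1]}”, "
            "how worried are you right now?"
        )
        out.append(_text(prompt))
        if not node.required:
            out.append(_text("(You can also say “skip”.)"))
    return out


def _await_for(node) -> AwaitState:
    if isinstance(node, QuickRepliesNode):
        return AwaitState(kind="quick_reply", node_id=node.id, options=list(node.options))
    if isinstance(node, FreeTextNode):
        return AwaitState(kind="free_text", node_id=node.id)
    if isinstance(node, AssessmentNode):
        return AwaitState(
            kind="assessment", node_id=node.id, scale=(node.scale_min, node.scale_max)
        )
    raise EngineError(f"node {node.id!r} does not await input")


def _menu_turn(
    session: Session, graph: DialogGraph, out: list[OutboundMessage]
) -> TurnResult:
    ids = offer_module_menu(session, graph)
    titles = [graph.module_map()[i].title for i in ids]
    options = titles + [FINISH_OPTION]
    session.mode = "menu"
    session.position = ""
    session.awaiting = AwaitState(kind="quick_reply", node_id=None, options=options)
    out.append(_text(MENU_PROMPT))
    return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)


def _end_session(
    session: Session, out: list[OutboundMessage], log: Optional[EventLog]
) -> TurnResult:
    session.ended = True
    session.awaiting = None
    session.mode = "node"
    session.digression_origin = None
    _log(session, log, "session_end", session_index=session.session_index)
    return TurnResult(outbound=out, awaiting=None, ended=True)


def _outro_module(graph: DialogGraph) -> Optional[DialogModule]:
    for m in graph.modules:
        if "outro" in m.tags:
            return m
    return None


def _walk(
    session: Session,
    graph: DialogGraph,
    out: list[OutboundMessage],
    log: Optional[EventLog],
    max_steps: int,
) -> TurnResult:
    """Traverse from ``session.position`` until input is required or the
    session ends; caps at ``max_steps`` to surface content bugs."""
    nodes = graph.node_map()
    modules = graph.module_map()
    for _ in range(max_steps):
        node = nodes.get(session.position)
        if node is None:
            raise EngineError(f"position {session.position!r} does not resolve")
        session.trace.append(node.id)
        _enter_module(session, graph, modules[node.module_id], log)

        if isinstance(node, MessageNode):
            out.extend(_text(t) for t in node.texts)
            session.position = node.next
        elif isinstance(node, RichMediaNode):
            out.append(OutboundMessage(kind="attachment", attachment=node.attachment))
            session.position = node.next
        elif isinstance(node, UpdateValueNode):
            apply_update(session, node)
            session.position = node.next
        elif isinstance(node, BranchNode):
            label = evaluate_branch(session, node)
            session.position = node.branches[label]
        elif isinstance(node, ExitModuleNode):
            mod = modules[node.module_id]
            if mod.id not in session.modules_completed:
                session.modules_completed.append(mod.id)
            _log(session, log, "module_complete", module=mod.id)
            if node.next == "end":
                return _end_session(session, out, log)
            if node.next not in (None, "menu"):
                session.position = modules[node.next].entry
                continue
            if session.digression_origin is not None:
                session.position = session.digression_origin
                session.digression_origin = None
                origin = nodes[session.position]
                out.extend(_prompt_for(origin))
                session.awaiting = _await_for(origin)
                session.mode = "node"
                return TurnResult(
                    outbound=out, awaiting=session.awaiting, ended=False
                )
            return _menu_turn(session, graph, out)
        else:  # input-requiring node
            out.extend(_prompt_for(node))
            session.awaiting = _await_for(node)
            session.mode = "node"
            return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)
    raise EngineError(f"max_steps={max_steps} exceeded: input-free content loop")


def _reprompt(session: Session, graph: DialogGraph, out: list[OutboundMessage]) -> TurnResult:
    """Repeat the pending prompt once, with a brief clarification line."""
    assert session.awaiting is not None
    if session.awaiting.node_id is not None:
        node = graph.node(session.awaiting.node_id)
        out.extend(_prompt_for(node, clarify=True))
    else:
        out.append(_text(REPROMPT_PREFIX))
        out.append(_text(MENU_PROMPT))
    return TurnResult(outbound=out, awaiting=session.awaiting, ended=False)


# ---------------------------------------------------------------------------
# public turn API


def start_session(
    graph: DialogGraph,
    user_id: str,
    prior: Optional[object] = None,
    seed: int = 0,
    *,
    log: Optional[EventLog] = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[Session, TurnResult]:
    """Open a session and run the first turn up to the first input request.

    ``prior`` is a previous :class:`Session` or its JSON archive; saved
    items, assessment history and module progress carry over, and
    ``session_index`` increments so content can route re-entry through the
    abbreviated greeting + brief-assessment path.
    """
    if isinstance(prior, str):
        prior = Session.from_archive(prior)
    index = 1 if prior is None else prior.session_index + 1
    session = Session(
        user_id=user_id,
        graph_id=graph.graph_id,
        session_index=index,
        rng_seed=seed,
        variables={"session_index": index, "returning": index > 1},
    )
    if prior is not None:
        if prior.graph_id != graph.graph_id:
            raise EngineError("prior archive is for a different graph")
        session.saved_items = list(prior.saved_items)
        session.assessments = list(prior.assessments)
        session.modules_started = list(prior.modules_started)
        session.modules_completed = list(prior.modules_completed)
        session.event_seq = prior.event_seq
    entry_mod = graph.module_map().get(graph.entry_module)
    if entry_mod is None:
        raise EngineError(f"entry module {graph.entry_module!r} missing")
    _log(session, log, "session_start", session_index=index)
    session.position = entry_mod.entry
    result = _walk(session, graph, [], log, max_steps)
    return session, result


def advance_turn(
    session: Session,
    graph: DialogGraph,
    input: Optional[UserInput] = None,
    *,
    registry: Optional[IntentRegistry] = None,
    lexicon: Optional[RiskLexicon] = None,
    log: Optional[EventLog] = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> TurnResult:
    """Consume one user input and traverse to the next input request.

    Routing: option labels match quick replies; free text goes through
    :func:`korero.nlu.resolve_routing` (risk > local > priority >
    fallback); scores are bounds-checked. Invalid input re-prompts, it
    never crashes the session.
    """
    if session.ended:
        raise EngineError("session has ended; no further turns accepted")
    if session.awaiting is None:
        raise EngineError("session is not awaiting input")
    if input is None:
        raise EngineError("input required: previous turn was awaiting")
    registry = registry or _default_registry()
    lexicon = lexicon or _default_lexicon()
    out: list[OutboundMessage] = []

    if session.mode == "escalation":
        return safety.run_escalation(
            session,
            graph.escalation,
            _as_confirmation(input),
            graph=graph,
            log=log,
        )

    kind = session.awaiting.kind
    if kind == "quick_reply":
        return _consume_quick_reply(
            session, graph, input, registry, lexicon, out, log, max_steps
        )
    if kind == "free_text":
        return _consume_free_text(
            session, graph, input, registry, lexicon, out, log, max_steps
        )
    if kind == "assessment":
        return _consume_assessment(
            session, graph, input, registry, lexicon, out, log, max_steps
        )
    raise EngineError(f"unknown awaiting kind {kind!r}")  # pragma: no cover


def _as_confirmation(input: UserInput) -> Optional[bool]:
    if input.kind in ("option", "text") and isinstance(input.value, str):
        v = input.value.strip().lower()
        if v in ("yes", "y", "yeah", "yep"):
            return True
        if v in ("no", "n", "nope"):
            return False
    return None


def _route_decision(
    session: Session,
    graph: DialogGraph,
    node,
    text: str,
    registry: IntentRegistry,
    lexicon: RiskLexicon,
    out: list[OutboundMessage],
    log: Optional[EventLog],
    max_steps: int,
) -> Optional[TurnResult]:
    """Apply a routing decision for typed text; None means caller should
    re-prompt (no applicable route)."""
    decision = resolve_routing(
        session, node, text, registry, lexicon, graph.priority_bindings
    )
    if decision.kind == "risk_escalation":
        origin = node.id if node is not None else None
        return safety.begin_escalation(
            session, graph.escalation, origin=origin, outbound=out
        )
    if decision.kind == "local_edge":
        _log(session, log, "intent_detected", intent=decision.intent_id)
        session.position = decision.edge.target
        return _walk(session, graph, out, log, max_steps)
    if decision.kind == "priority_digression":
        _log(session, log, "intent_detected", intent=decision.intent_id)
        _log(
            session,
            log,
            "priority_digression",
            intent=decision.intent_id,
            target=decision.target,
        )
        if node is not None:
            session.digression_origin = node.id
        session.position = decision.target
        return _walk(session, graph, out, log, max_steps)
    # fallback
    _log(session, log, "intent_detected", intent=decision.intent_id)
    if decision.edge is not None:
        session.position = decision.edge.target
        return _walk(session, graph, out, log, max_steps)
    return None


def _consume_quick_reply(
    session, graph, input, registry, lexicon, out, log, max_steps
) -> TurnResult:
    options = session.awaiting.options or []
    value = str(input.value) if input.value is not None else ""

    if session.awaiting.node_id is None:  # engine-synthesised module menu
        if input.kind in ("option", "text"):
            if value == FINISH_OPTION or value.strip().lower() == "finish up":
                outro = _outro_module(graph)
                if outro is None:
                    return _end_session(session, out, log)
                session.mode = "node"
                session.position = outro.entry
                return _walk(session, graph, out, log, max_steps)
            by_title = {
                graph.module_map()[i].title: i
                for i in offer_module_menu(session, graph)
            }
            target = by_title.get(value)
            if target is None and value in by_title.values():
                target = value  # module id typed directly
            if target is not None:
                session.mode = "node"
                session.position = graph.module_map()[target].entry
                return _walk(session, graph, out, log, max_steps)
            if input.kind == "text":
                result = _route_decision(
                    session, graph, None, value, registry, lexicon, out, log, max_steps
                )
                if result is not None:
                    return result
        return _reprompt(session, graph, out)

    node = graph.node(session.awaiting.node_id)
    if input.kind in ("option", "text") and isinstance(node, QuickRepliesNode):
        for edge in node.edges:
            if edge.label == value:
                session.position = edge.target
                return _walk(session, graph, out, log, max_steps)
        if input.kind == "text":
            # typed text at a quick-replies node still gets risk/priority
            result = _route_decision(
                session, graph, node, value, registry, lexicon, out, log, max_steps
            )
            if result is not None:
                return result
    return _reprompt(session, graph, out)


def _consume_free_text(
    session, graph, input, registry, lexicon, out, log, max_steps
) -> TurnResult:
    node = graph.node(session.awaiting.node_id)
    if input.kind not in ("text", "option") or not isinstance(input.value, str):
        return _reprompt(session, graph, out)
    result = _route_decision(
        session, graph, node, input.value, registry, lexicon, out, log, max_steps
    )
    if result is not None:
        return result
    return _reprompt(session, graph, out)


def _consume_assessment(
    session, graph, input, registry, lexicon, out, log, max_steps
) -> TurnResult:
    node = graph.node(session.awaiting.node_id)
    assert isinstance(node, AssessmentNode)
    if input.kind == "text" and isinstance(input.value, str):
        # risk phrases are detected at any point in the dialog, even where
        # a score is expected
        result = _route_decision(
            session, graph, node, input.value, registry, lexicon, out, log, max_steps
        )
        if result is not None:
            return result
        out.clear()
    if input.kind == "decline" or (
        isinstance(input.value, str) and input.value.strip().lower() == "skip"
    ):
        if node.required:
            return _reprompt(session, graph, out)
        session.position = node.next  # invited, not required: no record
        return _walk(session, graph, out, log, max_steps)
    try:
        score = int(input.value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return _reprompt(session, graph, out)
    if not (node.scale_min <= score <= node.scale_max):
        return _reprompt(session, graph, out)
    record_assessment(session, node, score, log=log)
    session.position = node.next
    return _walk(session, graph, out, log, max_steps)
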
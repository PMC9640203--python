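"""Typed dialog-graph content model, YAML serialization, validation, DOT export.

A content pack is a directed graph of typed nodes organised into modules.
Each module has one entry node and at least one reachable exit; the graph
has one global entry module. Free-text questions route on classified
intents with a mandatory fallback edge; quick-reply questions route on
option labels; branch and update-value nodes are invisible to the user and
steer the flow through session variables. Priority bindings map intents to
digression targets anywhere in the graph.

Node identifiers are case-sensitive slugs, unique graph-wide, so an edge
target is simply a node id (cross-module edges are legal but linted).
"""

from __future__ import annotations

import re
from collections import deque
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "AttachmentRef",
    "Condition",
    "Edge",
    "DialogGraph",
    "DialogModule",
    "GraphParseError",
    "MessageNode",
    "QuickRepliesNode",
    "FreeTextNode",
    "BranchNode",
    "UpdateValueNode",
    "RichMediaNode",
    "AssessmentNode",
    "ExitModuleNode",
    "Node",
    "ValidationIssue",
    "VALIDATION_CODES",
    "parse_graph",
    "serialize_graph",
    "validate_graph",
    "to_dot",
]

FALLBACK_LABEL = "fallback"

_SLUG_RE = re.compile(r"^[A-Za-z0-9_\-]+$")


class GraphParseError(ValueError):
    """Raised when a content-pack document cannot be resolved into a graph."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Condition(_Model):
    """Simple comparison over one session variable.

    Variables hold integers, booleans, or short strings; ``is_set`` ignores
    the operand. An unset variable under any other operator routes the
    owning branch to its ``default`` edge.
    """

    variable: str
    op: Literal["eq", "ne", "lt", "le", "gt", "ge", "is_set"]
    value: Union[int, bool, str, None] = None


class AttachmentRef(_Model):
    """Opaque reference to rich media (image, poster, webview, ...)."""

    kind: Literal["image", "gif", "audio", "video", "webview", "poster"]
    uri_or_path: str
    caption: Optional[str] = None
    saveable: bool = False


class Edge(_Model):
    """Labelled transition to another node (id resolved graph-wide)."""

    target: str
    label: str = "default"
    source: Optional[str] = None  # filled during parsing


class _NodeBase(_Model):
    id: str
    module_id: Optional[str] = None  # filled during parsing

    @field_validator("id")
    @classmethod
    def _slug(cls, v: str) -> str:
        if not _SLUG_RE.match(v):
            raise ValueError(f"node id {v!r} is not a slug")
        return v

    @property
    def out_edges(self) -> list[Edge]:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def requires_input(self) -> bool:
        return False


class MessageNode(_NodeBase):
    """Sends 1..n consecutive text bubbles, then follows its single edge."""

    type: Literal["message"] = "message"
    texts: list[str] = Field(min_length=1)
    next: str

    @property
    def out_edges(self) -> list[Edge]:
        return [Edge(target=self.next, label="default", source=self.id)]


class QuickRepliesNode(_NodeBase):
    """Prompt with a closed set of tappable options, one edge per label."""

    type: Literal["quick_replies"] = "quick_replies"
    prompt: str
    options: list[str] = Field(min_length=1)
    edges: list[Edge] = Field(default_factory=list)

    @property
    def out_edges(self) -> list[Edge]:
        return self.edges

    @property
    def requires_input(self) -> bool:
        return True


class FreeTextNode(_NodeBase):
    """Free-text question; routes on classified intent with one fallback."""

    type: Literal["free_text"] = "free_text"
    prompt: str
    intents: dict[str, str] = Field(default_factory=dict)  # intent id -> target
    fallback: Optional[str] = None  # target; validator flags absence

    @property
    def intent_edges(self) -> dict[str, Edge]:
        return {
            i: Edge(target=t, label=i, source=self.id)
            for i, t in self.intents.items()
        }

    @property
    def fallback_edge(self) -> Optional[Edge]:
        if self.fallback is None:
            return None
        return Edge(target=self.fallback, label=FALLBACK_LABEL, source=self.id)

    @property
    def out_edges(self) -> list[Edge]:
        edges = list(self.intent_edges.values())
        if self.fallback_edge is not None:
            edges.append(self.fallback_edge)
        return edges

    @property
    def requires_input(self) -> bool:
        return True


class BranchNode(_NodeBase):
    """Invisible condition check; selects the edge labelled by the outcome."""

    type: Literal["branch"] = "branch"
    condition: Condition
    branches: dict[str, str] = Field(min_length=1)  # outcome label -> target

    @property
    def out_edges(self) -> list[Edge]:
        return [
            Edge(target=t, label=lab, source=self.id)
            for lab, t in self.branches.items()
        ]


class UpdateValueNode(_NodeBase):
    """Invisible assignment to a session variable.

    ``value`` is a literal; ``expr`` alternatively names a tiny arithmetic
    expression ``<variable> (+|-) <int>`` evaluated over session variables.
    """

    type: Literal["update_value"] = "update_value"
    variable: str
    value: Union[int, bool, str, None] = None
    expr: Optional[str] = None
    next: str

    @property
    def out_edges(self) -> list[Edge]:
        return [Edge(target=self.next, label="default", source=self.id)]


class RichMediaNode(_NodeBase):
    """Sends one attachment (image/poster/webview/...), then continues."""

    type: Literal["rich_media"] = "rich_media"
    attachment: AttachmentRef
    next: str

    @property
    def out_edges(self) -> list[Edge]:
        return [Edge(target=self.next, label="default", source=self.id)]


class AssessmentNode(_NodeBase):
    """Single-item self-report scale (0-10 worry item in the demo pack)."""

    type: Literal["assessment"] = "assessment"
    item_id: str
    scale_min: int = 0
    scale_max: int = 10
    anchors: tuple[str, str] = ("no worries", "totally freaking out")
    required: bool = True
    prompt: str = ""
    next: str

    @property
    def out_edges(self) -> list[Edge]:
        return [Edge(target=self.next, label="default", source=self.id)]

    @property
    def requires_input(self) -> bool:
        return True


class ExitModuleNode(_NodeBase):
    """Terminal node of a module.

    ``next`` hints where control goes: ``"menu"``/``None`` return to the
    module menu (or to a pending digression origin), ``"end"`` finishes the
    session, and any other value is the id of the module to chain into.
    """

    type: Literal["exit_module"] = "exit_module"
    next: Optional[str] = None

    @property
    def out_edges(self) -> list[Edge]:
        return []


Node = Annotated[
    Union[
        MessageNode,
        QuickRepliesNode,
        FreeTextNode,
        BranchNode,
        UpdateValueNode,
        RichMediaNode,
        AssessmentNode,
        ExitModuleNode,
    ],
    Field(discriminator="type"),
]

NODE_TYPES = {
    "message",
    "quick_replies",
    "free_text",
    "branch",
    "update_value",
    "rich_media",
    "assessment",
    "exit_module",
}


class DialogModule(_Model):
    """Self-contained dialog sub-graph: one entry, >=1 reachable exits."""

    id: str
    title: str
    entry: str
    nodes: list[Node] = Field(min_length=1)
    serve_condition: Optional[Condition] = None
    repeatable: bool = True
    tags: list[str] = Field(default_factory=list)

    def node_map(self) -> dict[str, Node]:
        return {n.id: n for n in self.nodes}


class EscalationConfig(_Model):
    """Fixed texts of the risk-escalation protocol (see :mod:`korero.safety`)."""

    confirm_prompt: str = (
        "That sounded serious. Are you telling me you might hurt yourself?"
    )
    empathy_text: str = (
        "I'm really sorry you're going through this. You deserve support "
        "from a real person."
    )
    hotline_text: str = (
        "Please reach out right now: free call or text 1737 "
        "(placeholder helpline) to talk with a trained counsellor."
    )
    decline_return_text: str = (
        "Okay, thanks for letting me know. Let's carry on."
    )


class DialogGraph(_Model):
    """A complete authored content pack."""

    graph_id: str
    entry_module: str
    modules: list[DialogModule] = Field(min_length=1)
    priority_bindings: dict[str, str] = Field(default_factory=dict)
    escalation: EscalationConfig = Field(default_factory=EscalationConfig)
    metadata: dict[str, str] = Field(default_factory=dict)

    def module_map(self) -> dict[str, DialogModule]:
        return {m.id: m for m in self.modules}

    def node_map(self) -> dict[str, Node]:
        out: dict[str, Node] = {}
        for m in self.modules:
            out.update(m.node_map())
        return out

    def node(self, node_id: str) -> Node:
        n = self.node_map().get(node_id)
        if n is None:
            raise KeyError(f"unknown node {node_id!r}")
        return n


class ValidationIssue(_Model):
    severity: Literal["error", "warning"]
    code: str
    node_or_module: str
    message: str


#: Closed set of validator codes (documented contract).
VALIDATION_CODES = {
    "E_ENTRY_MODULE_MISSING": "graph entry_module names no module",
    "E_MODULE_ENTRY_MISSING": "module entry names no node in the module",
    "E_NO_REACHABLE_EXIT": "no exit_module node reachable from module entry",
    "E_TARGET_UNRESOLVED": "edge target names no node in the graph",
    "E_OPTION_UNROUTED": "quick-reply option label has no matching out-edge",
    "E_DUPLICATE_OPTION": "duplicate quick-reply option label",
    "E_FREETEXT_NO_FALLBACK": "free-text node lacks a fallback edge",
    "E_INPUT_FREE_CYCLE": "cycle with no user-input node (turn would not end)",
    "E_PRIORITY_TARGET_MISSING": "priority binding targets no node",
    "E_DUPLICATE_ID": "duplicate module or node identifier",
    "W_ORPHAN_NODE": "node unreachable from every entry point",
    "W_CROSS_MODULE_EDGE": "edge crosses module boundary",
    "W_BRANCH_NO_DEFAULT": "branch node has no default edge",
}


# ---------------------------------------------------------------------------
# parsing / serialization


def parse_graph(document: Union[str, dict]) -> DialogGraph:
    """Parse a YAML document (or pre-loaded mapping) into a resolved graph.

    All references (module entry, edge targets, priority bindings) must
    resolve; otherwise :class:`GraphParseError` is raised — never a partial
    graph. Duplicate identifiers and unknown node types are also errors.
    """
    if isinstance(document, str):
        try:
            data = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            loc = f" (line {mark.line + 1})" if mark is not None else ""
            raise GraphParseError(f"YAML syntax error{loc}: {exc}") from exc
    else:
        data = document
    if not isinstance(data, dict):
        raise GraphParseError("document is not a mapping")

    for mod in data.get("modules", []):
        for node in mod.get("nodes", []) if isinstance(mod, dict) else []:
            ntype = node.get("type") if isinstance(node, dict) else None
            if ntype is not None and ntype not in NODE_TYPES:
                raise GraphParseError(
                    f"unknown node type {ntype!r} at node "
                    f"{node.get('id', '?')!r}"
                )

    try:
        graph = DialogGraph.model_validate(data)
    except Exception as exc:
        raise GraphParseError(f"invalid content pack: {exc}") from exc

    # identifier uniqueness
    seen: set[str] = set()
    for m in graph.modules:
        if m.id in seen:
            raise GraphParseError(f"duplicate module id {m.id!r}")
        seen.add(m.id)
    node_ids: set[str] = set()
    for m in graph.modules:
        for n in m.nodes:
            if n.id in node_ids:
                raise GraphParseError(f"duplicate node id {n.id!r}")
            node_ids.add(n.id)
            n.module_id = m.id
            # stamp edge sources on the stored edges of quick-reply nodes
            if isinstance(n, QuickRepliesNode):
                for e in n.edges:
                    e.source = n.id

    # reference resolution
    module_ids = {m.id for m in graph.modules}
    if graph.entry_module not in module_ids:
        raise GraphParseError(
            f"entry_module {graph.entry_module!r} names no module"
        )
    for m in graph.modules:
        if m.entry not in {n.id for n in m.nodes}:
            raise GraphParseError(
                f"module {m.id!r} entry {m.entry!r} names no node in it"
            )
        for n in m.nodes:
            if isinstance(n, ExitModuleNode):
                if n.next not in (None, "menu", "end") and n.next not in module_ids:
                    raise GraphParseError(
                        f"exit node {n.id!r} next hint {n.next!r} "
                        "names no module"
                    )
                continue
            for e in n.out_edges:
                if e.target not in node_ids:
                    raise GraphParseError(
                        f"unresolved edge target {e.target!r} "
                        f"(edge {n.id!r} --{e.label}-->)"
                    )
    for intent_id, target in graph.priority_bindings.items():
        if target not in node_ids:
            raise GraphParseError(
                f"priority binding {intent_id!r} -> {target!r} "
                "targets no node"
            )
    return graph


def serialize_graph(graph: DialogGraph) -> str:
    """Serialize to canonical (key-sorted) YAML.

    Round-trip safe: ``parse_graph(serialize_graph(g))`` is structurally
    identical to ``g``, and serializing twice is byte-identical.
    """
    data = graph.model_dump(mode="json", exclude_none=True)
    # drop parse-time bookkeeping so output is canonical authored form
    for mod in data["modules"]:
        for node in mod["nodes"]:
            node.pop("module_id", None)
            for e in node.get("edges", []):
                e.pop("source", None)
    return yaml.safe_dump(data, sort_keys=True, allow_unicode=True, width=88)


# ---------------------------------------------------------------------------
# validation


def _issue(severity: str, code: str, where: str, message: str) -> ValidationIssue:
    assert code in VALIDATION_CODES
    return ValidationIssue(
        severity=severity, code=code, node_or_module=where, message=message
    )


def _reachable(start: str, adjacency: dict[str, list[str]]) -> set[str]:
    seen = {start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in adjacency.get(cur, []):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen


def validate_graph(graph: DialogGraph) -> list[ValidationIssue]:
    """Check every structural invariant; an empty list means a clean pack.

    Detects: missing module entry, no reachable exit, unrouted or duplicate
    quick-reply options, free-text nodes without fallback, unresolved edge
    targets, dangling priority bindings, input-free cycles (errors), and
    orphan nodes, cross-module edges, default-less branches (warnings).
    """
    issues: list[ValidationIssue] = []
    nodes = graph.node_map()
    module_ids = {m.id for m in graph.modules}

    if graph.entry_module not in module_ids:
        issues.append(
            _issue(
                "error",
                "E_ENTRY_MODULE_MISSING",
                graph.graph_id,
                f"entry_module {graph.entry_module!r} names no module",
            )
        )

    # duplicate ids (programmatic graphs can bypass parse_graph)
    seen_ids: set[str] = set()
    for m in graph.modules:
        for n in m.nodes:
            if n.id in seen_ids:
                issues.append(
                    _issue("error", "E_DUPLICATE_ID", n.id, "duplicate node id")
                )
            seen_ids.add(n.id)

    adjacency: dict[str, list[str]] = {}
    for m in graph.modules:
        local = m.node_map()
        if m.entry not in local:
            issues.append(
                _issue(
                    "error",
                    "E_MODULE_ENTRY_MISSING",
                    m.id,
                    f"entry {m.entry!r} names no node in module {m.id!r}",
                )
            )
        for n in m.nodes:
            targets = []
            for e in n.out_edges:
                if e.target not in nodes:
                    issues.append(
                        _issue(
                            "error",
                            "E_TARGET_UNRESOLVED",
                            n.id,
                            f"edge --{e.label}--> {e.target!r} unresolved",
                        )
                    )
                    continue
                targets.append(e.target)
                if nodes[e.target].module_id not in (None, m.id):
                    issues.append(
                        _issue(
                            "warning",
                            "W_CROSS_MODULE_EDGE",
                            n.id,
                            f"edge --{e.label}--> {e.target!r} leaves "
                            f"module {m.id!r}",
                        )
                    )
            adjacency[n.id] = targets

            if isinstance(n, QuickRepliesNode):
                labels = [e.label for e in n.edges]
                if len(set(n.options)) != len(n.options):
                    issues.append(
                        _issue(
                            "error",
                            "E_DUPLICATE_OPTION",
                            n.id,
                            "duplicate option label",
                        )
                    )
                for opt in n.options:
                    if opt not in labels:
                        issues.append(
                            _issue(
                                "error",
                                "E_OPTION_UNROUTED",
                                n.id,
                                f"option {opt!r} has no out-edge",
                            )
                        )
                for lab in labels:
                    if lab not in n.options:
                        issues.append(
                            _issue(
                                "error",
                                "E_OPTION_UNROUTED",
                                n.id,
                                f"edge label {lab!r} is not an option",
                            )
                        )
            elif isinstance(n, FreeTextNode):
                if n.fallback is None:
                    issues.append(
                        _issue(
                            "error",
                            "E_FREETEXT_NO_FALLBACK",
                            n.id,
                            "free-text node lacks a fallback edge",
                        )
                    )
            elif isinstance(n, BranchNode):
                if "default" not in n.branches:
                    issues.append(
                        _issue(
                            "warning",
                            "W_BRANCH_NO_DEFAULT",
                            n.id,
                            "branch has no default edge",
                        )
                    )

    # per-module exit reachability
    for m in graph.modules:
        if m.entry not in m.node_map():
            continue
        reach = _reachable(m.entry, adjacency)
        exits = {n.id for n in m.nodes if isinstance(n, ExitModuleNode)}
        if not exits & reach:
            issues.append(
                _issue(
                    "error",
                    "E_NO_REACHABLE_EXIT",
                    m.id,
                    "no exit_module node reachable from module entry",
                )
            )

    # orphans: roots are the global entry, every module entry (menu-served)
    # and every priority-binding target
    roots: set[str] = set()
    mm = graph.module_map()
    if graph.entry_module in mm:
        roots.add(mm[graph.entry_module].entry)
    for m in graph.modules:
        if m.entry in nodes:
            roots.add(m.entry)
    for target in graph.priority_bindings.values():
        if target in nodes:
            roots.add(target)
        else:
            issues.append(
                _issue(
                    "error",
                    "E_PRIORITY_TARGET_MISSING",
                    target,
                    "priority binding targets no node",
                )
            )
    reachable_all: set[str] = set()
    for r in roots:
        reachable_all |= _reachable(r, adjacency)
    for nid in nodes:
        if nid not in reachable_all:
            issues.append(
                _issue("warning", "W_ORPHAN_NODE", nid, "node is unreachable")
            )

    # input-free cycles: cycle detection on the subgraph of nodes that do
    # not pause the turn (a cycle through any input node is a legal menu loop)
    passive = {
        nid for nid, n in nodes.items() if not n.requires_input
    }
    color: dict[str, int] = {}

    def has_cycle(start: str) -> Optional[str]:
        stack = [(start, iter(adjacency.get(start, [])))]
        color[start] = 1
        while stack:
            nid, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in passive:
                    continue
                c = color.get(nxt, 0)
                if c == 1:
                    return nxt
                if c == 0:
                    color[nxt] = 1
                    stack.append((nxt, iter(adjacency.get(nxt, []))))
                    advanced = True
                    break
            if not advanced:
                color[nid] = 2
                stack.pop()
        return None

    for nid in sorted(passive):
        if color.get(nid, 0) == 0:
            witness = has_cycle(nid)
            if witness is not None:
                issues.append(
                    _issue(
                        "error",
                        "E_INPUT_FREE_CYCLE",
                        witness,
                        "cycle with no user-input node",
                    )
                )
                break  # one witness suffices; authors fix and re-run
    return issues


# ---------------------------------------------------------------------------
# DOT export

_DOT_SHAPE = {
    "message": "box",
    "quick_replies": "hexagon",
    "free_text": "house",
    "branch": "diamond",
    "update_value": "note",
    "rich_media": "component",
    "assessment": "ellipse",
    "exit_module": "doublecircle",
}


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(graph: DialogGraph) -> str:
    """Render the graph as a Graphviz DOT digraph (one DOT node per dialog
    node, shape keyed by node type, edge labels preserved)."""
    lines = [f'digraph "{_dot_escape(graph.graph_id)}" {{', "  rankdir=TB;"]
    for m in graph.modules:
        lines.append(f'  subgraph "cluster_{_dot_escape(m.id)}" {{')
        lines.append(f'    label="{_dot_escape(m.title)}";')
        for n in m.nodes:
            shape = _DOT_SHAPE[n.type]
            lines.append(
                f'    "{_dot_escape(n.id)}" [shape={shape}, '
                f'label="{_dot_escape(n.id)}\\n({n.type})"];'
            )
        lines.append("  }")
    for m in graph.modules:
        for n in m.nodes:
            for e in n.out_edges:
                lines.append(
                    f'  "{_dot_escape(n.id)}" -> "{_dot_escape(e.target)}" '
                    f'[label="{_dot_escape(e.label)}"];'
                )
    lines.append("}")
    return "\n".join(lines) + "\n"
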
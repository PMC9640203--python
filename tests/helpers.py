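"""Independent oracles and generators shared across the test suite.

Everything here deliberately re-derives behaviour by a different route
than the package (naive recursion, brute-force passes, direct formula
evaluation) so tests compare two independent implementations.
"""

from __future__ import annotations

import random
from collections import deque

from korero.analytics import EventLog, UserRecord, round_half_up
from korero.model import DialogGraph, parse_graph

SENTINEL_TEXT = "xyzzy sentinel utterance plugh"


# ---------------------------------------------------------------------------
# random valid content packs


def make_minimal_doc() -> dict:
    """Smallest legal graph: one module, entry message -> exit."""
    return {
        "graph_id": "minimal",
        "entry_module": "m",
        "modules": [
            {
                "id": "m",
                "title": "Minimal",
                "entry": "hello",
                "nodes": [
                    {"id": "hello", "type": "message", "texts": ["hi"], "next": "bye"},
                    {"id": "bye", "type": "exit_module", "next": "end"},
                ],
            }
        ],
    }


def make_random_graph_doc(seed: int, input_nodes: bool = True) -> dict:
    """Random single-module DAG content pack (always parseable).

    Node i only targets nodes j > i (plus the final exit), so traversal
    always terminates and the exit is reachable from the entry; nodes that
    happen to be untargeted become genuine orphans, which exercises the
    reachability checks.
    """
    rng = random.Random(seed)
    k = rng.randint(3, 9)
    ids = [f"n{i}" for i in range(k)] + ["fin"]

    def later(i: int) -> str:
        return rng.choice(ids[i + 1 :])

    types = ["message", "branch", "update_value"]
    if input_nodes:
        types += ["quick_replies", "assessment"]
    nodes = []
    for i in range(k):
        t = rng.choice(types)
        nid = ids[i]
        if t == "message":
            nodes.append(
                {"id": nid, "type": "message", "texts": [f"text {i}"], "next": later(i)}
            )
        elif t == "branch":
            nodes.append(
                {
                    "id": nid,
                    "type": "branch",
                    "condition": {
                        "variable": rng.choice(["x", "y"]),
                        "op": rng.choice(["eq", "ne", "lt", "le", "gt", "ge", "is_set"]),
                        "value": rng.choice([0, 1, 2, "a"]),
                    },
                    "branches": {
                        "true": later(i),
                        "false": later(i),
                        "default": later(i),
                    },
                }
            )
        elif t == "update_value":
            nodes.append(
                {
                    "id": nid,
                    "type": "update_value",
                    "variable": rng.choice(["x", "y"]),
                    "value": rng.randint(0, 3),
                    "next": later(i),
                }
            )
        elif t == "quick_replies":
            n_opt = rng.randint(2, 3)
            opts = [f"opt{i}_{j}" for j in range(n_opt)]
            nodes.append(
                {
                    "id": nid,
                    "type": "quick_replies",
                    "prompt": f"choose {i}",
                    "options": opts,
                    "edges": [{"label": o, "target": later(i)} for o in opts],
                }
            )
        else:
            nodes.append(
                {
                    "id": nid,
                    "type": "assessment",
                    "item_id": "item",
                    "scale_min": 0,
                    "scale_max": 10,
                    "required": True,
                    "next": later(i),
                }
            )
    nodes.append({"id": "fin", "type": "exit_module", "next": "end"})
    return {
        "graph_id": f"random{seed}",
        "entry_module": "m",
        "modules": [
            {"id": "m", "title": "Random", "entry": "n0", "nodes": nodes}
        ],
    }


def make_random_graph(seed: int, input_nodes: bool = True) -> DialogGraph:
    return parse_graph(make_random_graph_doc(seed, input_nodes))


# ---------------------------------------------------------------------------
# naive reference interpreter (engine oracle)


def naive_trace(graph: DialogGraph, raw_inputs: list) -> list[str]:
    """Visited-node sequence of a deliberately naive interpreter.

    Consumes raw inputs (str labels / int scores) at input-requiring
    nodes; invalid input is swallowed without leaving the node. Stops when
    an exit is reached or inputs run out at an input node.
    """
    nodes = {n.id: n for m in graph.modules for n in m.nodes}
    variables: dict = {"session_index": 1, "returning": False}
    inputs = deque(raw_inputs)
    trace: list[str] = []
    nid = graph.module_map()[graph.entry_module].entry
    while True:
        node = nodes[nid]
        trace.append(nid)
        t = node.type
        if t in ("message", "rich_media"):
            nid = node.next
        elif t == "update_value":
            if node.expr is not None:
                name, op, lit = node.expr.split()
                base = int(variables.get(name) or 0)
                variables[node.variable] = (
                    base + int(lit) if op == "+" else base - int(lit)
                )
            else:
                variables[node.variable] = node.value
            nid = node.next
        elif t == "branch":
            v = variables.get(node.condition.variable)
            op, operand = node.condition.op, node.condition.value
            if op == "is_set":
                ok = v is not None
            elif v is None:
                ok = None
            elif op in ("eq", "ne"):
                same = v == operand or str(v) == str(operand)
                ok = same if op == "eq" else not same
            else:
                try:
                    a, b = float(v), float(operand)
                except (TypeError, ValueError):
                    ok = None
                else:
                    ok = {
                        "lt": a < b,
                        "le": a <= b,
                        "gt": a > b,
                        "ge": a >= b,
                    }[op]
            label = "default" if ok is None else ("true" if ok else "false")
            if label not in node.branches:
                label = "default"
            nid = node.branches[label]
        elif t == "exit_module":
            return trace
        elif t == "quick_replies":
            while True:
                if not inputs:
                    return trace
                val = inputs.popleft()
                match = [e.target for e in node.edges if e.label == val]
                if match:
                    nid = match[0]
                    break
        elif t == "assessment":
            while True:
                if not inputs:
                    return trace
                val = inputs.popleft()
                if isinstance(val, int) and node.scale_min <= val <= node.scale_max:
                    nid = node.next
                    break
        else:  # pragma: no cover
            raise AssertionError(f"oracle does not handle {t}")


# ---------------------------------------------------------------------------
# brute-force cohort summary (analytics oracle)


def brute_force_summary(log: EventLog, users: list[UserRecord]) -> dict:
    """Straight-line recomputation of the cohort summary quantities."""
    logged_in = sorted({e.user_id for e in log if e.type == "session_start"})
    by_id = {u.user_id: u for u in users}
    target = [u for u in (by_id[x] for x in logged_in) if 13 <= u.age <= 24]
    tids = {u.user_id for u in target}

    def pct(k: int, n: int, dp: int) -> float:
        return round_half_up(100.0 * k / n, dp)

    gender: dict[str, float] = {}
    eth: dict[str, float] = {}
    if target:
        for cat in {u.gender for u in target}:
            gender[cat] = pct(sum(u.gender == cat for u in target), len(target), 1)
        for cat in {u.ethnicity for u in target}:
            eth[cat] = pct(sum(u.ethnicity == cat for u in target), len(target), 1)

    pre: dict = {}
    post: dict = {}
    for e in log:
        if e.type != "assessment" or e.user_id not in tids:
            continue
        key = (e.user_id, e.payload["session_index"])
        if e.payload["phase"] in ("onboarding", "intro"):
            pre.setdefault(key, e.payload["score"])
        else:
            post.setdefault(key, e.payload["score"])
    reached = {
        e.user_id
        for e in log
        if e.type == "module_start" and e.payload.get("outro") and e.user_id in tids
    }
    denom = {u for u, _ in pre} & reached
    completers = {u for (u, s) in post if (u, s) in pre} & denom

    sessions: dict[str, set] = {}
    for e in log:
        if e.type == "session_start" and e.user_id in tids:
            sessions.setdefault(e.user_id, set()).add(
                e.payload.get("session_index", 1)
            )
    return {
        "n_registered": len(users),
        "n_logged_in": len(logged_in),
        "n_target_age": len(target),
        "pct_by_gender": gender,
        "pct_by_ethnicity": eth,
        "prepost_denominator": len(denom),
        "n_prepost_completers": len(completers),
        "pct_prepost": pct(len(completers), len(denom), 0) if denom else None,
        "n_returned": sum(1 for s in sessions.values() if len(s) >= 2),
    }


# ---------------------------------------------------------------------------
# shared property checks (unit suites and the acceptance suite both run these)


def check_routing_precedence() -> int:
    """Exhaustive 2^4 matrix: risk > local edge > priority > fallback."""
    from korero.model import FreeTextNode
    from korero.nlu import (
        Intent,
        IntentRegistry,
        RiskLexicon,
        RiskPhrase,
        resolve_routing,
    )

    registry = IntentRegistry(
        intents=[
            Intent(intent_id="loc", patterns=["blue"]),
            Intent(
                intent_id="pri",
                patterns=["red"],
                is_priority=True,
                priority_target="tgt",
            ),
        ]
    )
    lexicon = RiskLexicon(
        phrases=[RiskPhrase(pattern="hurt myself", category="self_harm")]
    )
    n = 0
    for risk in (False, True):
        for local in (False, True):
            for priority in (False, True):
                for has_fallback in (False, True):
                    word = "red" if priority else "blue"
                    text = "i feel " + word
                    if risk:
                        text += " and i might hurt myself"
                    intents = {("pri" if priority else "loc"): "ln"} if local else {}
                    node = FreeTextNode(
                        id="ft",
                        prompt="?",
                        intents=intents,
                        fallback="fb" if has_fallback else None,
                    )
                    decision = resolve_routing(
                        None, node, text, registry, lexicon, {}
                    )
                    if risk:
                        expected = "risk_escalation"
                    elif local:
                        expected = "local_edge"
                    elif priority:
                        expected = "priority_digression"
                    else:
                        expected = "fallback"
                    assert decision.kind == expected, (
                        risk, local, priority, has_fallback, decision.kind,
                    )
                    n += 1
    return n


def make_session_at(graph, node):
    """A live session positioned and awaiting at an arbitrary input node."""
    from korero.engine import Session, _await_for

    return Session(
        user_id="u",
        graph_id=graph.graph_id,
        position=node.id,
        variables={"session_index": 1, "returning": False},
        awaiting=_await_for(node),
        mode="node",
        current_module=node.module_id,
        modules_started=[node.module_id],
    )


def check_escalation_everywhere(graph, registry, lexicon) -> int:
    """Injecting a self-harm phrase at every input-accepting node must run
    the full confirm -> empathy -> hotline -> shutdown sequence."""
    from korero.analytics import EventLog
    from korero.engine import EngineError, advance_turn
    from korero.messages import UserInput

    input_nodes = [
        n for m in graph.modules for n in m.nodes if n.requires_input
    ]
    assert input_nodes, "demo pack has no input nodes?"
    for node in input_nodes:
        log = EventLog()
        session = make_session_at(graph, node)
        r1 = advance_turn(
            session, graph, UserInput.text("I want to kill myself"),
            registry=registry, lexicon=lexicon, log=log,
        )
        assert session.mode == "escalation", node.id
        assert r1.awaiting is not None and r1.awaiting.options == ["yes", "no"]
        assert r1.outbound[-1].text == graph.escalation.confirm_prompt
        r2 = advance_turn(
            session, graph, UserInput.option("yes"),
            registry=registry, lexicon=lexicon, log=log,
        )
        texts = [m.text for m in r2.outbound]
        assert texts == [graph.escalation.empathy_text, graph.escalation.hotline_text]
        assert r2.ended and session.ended
        assert len(log.of_type("risk_escalation")) == 1
        try:
            advance_turn(session, graph, UserInput.option("yes"),
                         registry=registry, lexicon=lexicon)
        except EngineError:
            pass
        else:
            raise AssertionError("ended session accepted another turn")
    return len(input_nodes)


def check_replay_determinism(graph_factory, script, registry, lexicon):
    """Two independent replays must be byte-identical (transcript and log)."""
    from korero.analytics import EventLog
    from korero.channels import replay_script

    outputs = []
    for _ in range(2):
        log = EventLog()
        transcript, _session = replay_script(
            graph_factory(), script, seed=7,
            registry=registry, lexicon=lexicon, log=log,
        )
        outputs.append((transcript.to_jsonl(), log.to_jsonl()))
    assert outputs[0] == outputs[1]
    return outputs[0]


def seeded_defects():
    """(name, mutator, expected_code) triples for validator soundness."""
    return [
        (
            "unrouted_option",
            lambda g: setattr(
                g.node("gf_qr"),
                "edges",
                [e for e in g.node("gf_qr").edges if e.label != "😐"],
            ),
            "E_OPTION_UNROUTED",
        ),
        (
            "missing_fallback",
            lambda g: setattr(g.node("pg_share"), "fallback", None),
            "E_FREETEXT_NO_FALLBACK",
        ),
        (
            "missing_entry",
            lambda g: setattr(g.module_map()["outro"], "entry", "ghost"),
            "E_MODULE_ENTRY_MISSING",
        ),
        (
            "dangling_binding",
            lambda g: g.priority_bindings.update(boredom="ghost"),
            "E_PRIORITY_TARGET_MISSING",
        ),
        (
            "unreachable_exit",
            lambda g: setattr(g.node("ch_msg"), "next", "ch_msg"),
            "E_NO_REACHABLE_EXIT",
        ),
        (
            "input_free_cycle",
            lambda g: setattr(g.node("ch_msg"), "next", "ch_msg"),
            "E_INPUT_FREE_CYCLE",
        ),
        (
            "unresolved_target",
            lambda g: setattr(g.node("ch_msg"), "next", "ghost"),
            "E_TARGET_UNRESOLVED",
        ),
    ]


def check_privacy_sentinel(graph, registry, lexicon) -> None:
    """Raw free text fed to the chatbot must never reach the event log."""
    from korero.analytics import EventLog
    from korero.channels import Script, replay_script
    from korero.messages import UserInput

    log = EventLog()
    script = Script(
        steps=[
            UserInput.score(5),
            UserInput.option("Practice gratitude"),
            UserInput.text(SENTINEL_TEXT),
            UserInput.option("Finish up"),
            UserInput.score(4),
            UserInput.option("😊"),
        ]
    )
    transcript, _ = replay_script(
        graph, script, registry=registry, lexicon=lexicon, log=log
    )
    serialized = log.to_jsonl()
    assert SENTINEL_TEXT not in serialized
    assert SENTINEL_TEXT in transcript.to_jsonl()  # but the channel saw it


def make_printed_cohort():
    """Cohort table shaped like the published uptake funnel: 393
    registered, 238 logged in, 127 target-age (90 female, 60 NZ
    European), 81 in the pre-post denominator, 30 completers."""
    from korero.analytics import Event

    ts = "2020-04-01T00:00:00+00:00"
    users, log = [], EventLog()
    uid = 0

    def add(age, logged_in, gender="male", ethnicity="other"):
        nonlocal uid
        uid += 1
        u = f"u{uid:04d}"
        users.append(
            UserRecord(
                user_id=u, age=age, gender=gender, ethnicity=ethnicity,
                registered_at=ts,
            )
        )
        if logged_in:
            log.append(
                Event(timestamp=ts, user_id=u, type="session_start",
                      payload={"session_index": 1})
            )
        return u

    target = []
    for i in range(127):
        target.append(
            add(
                age=13 + i % 12,
                logged_in=True,
                gender="female" if i < 90 else "male",
                ethnicity="nz_european" if i < 60 else "other",
            )
        )
    for _ in range(238 - 127):
        add(age=30, logged_in=True)
    for _ in range(393 - 238):
        add(age=20, logged_in=False)

    for i, u in enumerate(target[:81]):
        log.append(
            Event(timestamp=ts, user_id=u, type="assessment",
                  payload={"item": "covid_worry", "phase": "onboarding",
                           "score": 5, "session_index": 1})
        )
        log.append(
            Event(timestamp=ts, user_id=u, type="module_start",
                  payload={"module": "recheck", "outro": True})
        )
        if i < 30:
            log.append(
                Event(timestamp=ts, user_id=u, type="assessment",
                      payload={"item": "covid_worry", "phase": "outro",
                               "score": 4, "session_index": 1})
            )
    return users, log
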
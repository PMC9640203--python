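"""Intent classification, risk-phrase detection, and routing resolution.

Free text typed by the user is classified to exactly one intent from a
predefined registry (the shipped default has 40). Routing then follows a
strict precedence:

1. risk-lexicon match   -> escalation (self-harm) or protective digression
2. locally configured intent edge at the current node
3. priority intent      -> digression to its bound target anywhere in graph
4. fallback edge        -> generic response

The default classifier is a deterministic keyword/phrase scorer so the
package is self-contained and replayable; any external classifier can be
substituted through the same ``classify_text`` signature.
"""

from __future__ import annotations

import re
import unicodedata
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import FALLBACK_LABEL, Edge, FreeTextNode, QuickRepliesNode

__all__ = [
    "Intent",
    "IntentRegistry",
    "IntentClassification",
    "RiskLexicon",
    "RiskPhrase",
    "RoutingDecision",
    "classify_text",
    "match_risk",
    "normalize",
    "resolve_routing",
]

FALLBACK_INTENT = FALLBACK_LABEL

RiskCategory = Literal["self_harm", "abuse"]

#: Lexicon abuse matches digress to this intent's priority binding.
ABUSE_INTENT = "risk_of_abuse"


class Intent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intent_id: str
    patterns: list[str] = Field(min_length=1)
    is_priority: bool = False
    priority_target: Optional[str] = None  # node id; required iff priority


class IntentRegistry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intents: list[Intent]
    fallback_id: str = FALLBACK_INTENT

    def model_post_init(self, __context) -> None:
        ids = [i.intent_id for i in self.intents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate intent ids in registry")
        if self.fallback_id in ids:
            raise ValueError("fallback_id must not be a registry intent")
        for i in self.intents:
            if i.is_priority and i.priority_target is None:
                raise ValueError(
                    f"priority intent {i.intent_id!r} has no target"
                )

    def get(self, intent_id: str) -> Optional[Intent]:
        for i in self.intents:
            if i.intent_id == intent_id:
                return i
        return None

    @classmethod
    def from_yaml(cls, text: str) -> "IntentRegistry":
        return cls.model_validate(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            self.model_dump(mode="json", exclude_none=True), sort_keys=True
        )


class IntentClassification(BaseModel):
    intent_id: str
    score: float = Field(ge=0.0, le=1.0)
    matched_pattern: Optional[str] = None

    @property
    def is_fallback(self) -> bool:
        return self.score == 0.0


class RiskPhrase(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pattern: str
    category: RiskCategory


class RiskLexicon(BaseModel):
    model_config = ConfigDict(extra="forbid")

    phrases: list[RiskPhrase] = Field(min_length=1)

    @classmethod
    def from_yaml(cls, text: str) -> "RiskLexicon":
        return cls.model_validate(yaml.safe_load(text))


class RoutingDecision(BaseModel):
    kind: Literal["risk_escalation", "local_edge", "priority_digression", "fallback"]
    intent_id: str
    target: Optional[str] = None  # node id (digression) — edges carry target
    edge: Optional[Edge] = None
    risk_category: Optional[RiskCategory] = None
    classification: Optional[IntentClassification] = None


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)


def normalize(text: str) -> str:
    """Lowercase, strip punctuation/accents, collapse whitespace."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = _PUNCT_RE.sub(" ", text.lower())
    return " ".join(text.split())


def _pattern_matches(pattern_tokens: list[str], text_tokens: list[str]) -> bool:
    """Contiguous token-subsequence match."""
    k = len(pattern_tokens)
    if k == 0 or k > len(text_tokens):
        return False
    for i in range(len(text_tokens) - k + 1):
        if text_tokens[i : i + k] == pattern_tokens:
            return True
    return False


def classify_text(text: str, registry: IntentRegistry) -> IntentClassification:
    """Classify free text to one registry intent.

    Score of a matching pattern = (pattern token count) / (input token
    count), i.e. how much of the utterance the pattern covers; an intent's
    score is its best pattern's. Highest score wins; ties break
    lexicographically on intent_id (deterministic). No match, or empty
    text, classifies to the fallback id with score 0.
    """
    tokens = normalize(text).split()
    if not tokens:
        return IntentClassification(intent_id=registry.fallback_id, score=0.0)
    best: Optional[tuple[float, str, str]] = None  # (score, intent_id, pattern)
    for intent in registry.intents:
        for pattern in intent.patterns:
            ptoks = normalize(pattern).split()
            if _pattern_matches(ptoks, tokens):
                score = min(1.0, len(ptoks) / len(tokens))
                key = (score, intent.intent_id, pattern)
                if (
                    best is None
                    or score > best[0]
                    or (score == best[0] and intent.intent_id < best[1])
                ):
                    best = key
    if best is None:
        return IntentClassification(intent_id=registry.fallback_id, score=0.0)
    score, intent_id, pattern = best
    return IntentClassification(
        intent_id=intent_id, score=score, matched_pattern=pattern
    )


def match_risk(text: str, lexicon: RiskLexicon) -> Optional[RiskCategory]:
    """Return the first matching risk category, or None.

    Matching is case- and punctuation-insensitive (both sides normalized)
    and runs before any intent routing.
    """
    norm = f" {normalize(text)} "
    for phrase in lexicon.phrases:
        if f" {normalize(phrase.pattern)} " in norm:
            return phrase.category
    return None


def resolve_routing(
    session,
    node: Union[FreeTextNode, QuickRepliesNode],
    text: str,
    registry: IntentRegistry,
    lexicon: RiskLexicon,
    priority_bindings: Optional[dict[str, str]] = None,
) -> RoutingDecision:
    """Resolve typed text at an input node to a routing decision.

    Total: every input string yields a decision. Precedence is strictly
    risk > local intent edge > priority digression > fallback. Self-harm
    lexicon matches escalate; abuse matches digress to the protective
    module bound to ``risk_of_abuse``. ``session`` is accepted for
    interface symmetry with the engine (the default resolver is stateless).
    """
    bindings = dict(priority_bindings or {})

    risk = match_risk(text, lexicon)
    if risk == "self_harm":
        return RoutingDecision(
            kind="risk_escalation", intent_id="self_harm", risk_category=risk
        )
    if risk == "abuse":
        target = bindings.get(ABUSE_INTENT)
        if target is None:
            intent = registry.get(ABUSE_INTENT)
            target = intent.priority_target if intent else None
        if target is not None:
            return RoutingDecision(
                kind="priority_digression",
                intent_id=ABUSE_INTENT,
                target=target,
                risk_category=risk,
            )
        return RoutingDecision(
            kind="risk_escalation", intent_id=ABUSE_INTENT, risk_category=risk
        )

    cls = classify_text(text, registry)

    if isinstance(node, FreeTextNode) and not cls.is_fallback:
        edge = node.intent_edges.get(cls.intent_id)
        if edge is not None:
            return RoutingDecision(
                kind="local_edge",
                intent_id=cls.intent_id,
                edge=edge,
                target=edge.target,
                classification=cls,
            )

    if not cls.is_fallback:
        intent = registry.get(cls.intent_id)
        if intent is not None and intent.is_priority:
            target = bindings.get(cls.intent_id, intent.priority_target)
            if target is not None:
                return RoutingDecision(
                    kind="priority_digression",
                    intent_id=cls.intent_id,
                    target=target,
                    classification=cls,
                )

    edge = node.fallback_edge if isinstance(node, FreeTextNode) else None
    return RoutingDecision(
        kind="fallback",
        intent_id=cls.intent_id if not cls.is_fallback else registry.fallback_id,
        edge=edge,
        target=edge.target if edge is not None else None,
        classification=cls,
    )
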
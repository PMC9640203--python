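"""Synthetic open-trial cohort simulator.

Generates a registration cohort, subsamples logins, and produces the
usage event log by *actually replaying* the demo content pack through the
engine with sampled menu choices and sampled worry scores — so simulator
output is consumable by :mod:`korero.analytics` with no schema glue, and
every logged event corresponds to a real traversal.

Score model: session-start scores are drawn from a normal(mu_pre, sd_pre)
truncated to [0, 10] and rounded to integers; the outro score of a
completer is ``clamp(round(pre - effect_delta + noise))`` with
``noise ~ N(0, sd_noise)``. Reaching the outro offer, completing the
recheck, and returning for a second session are independent Bernoulli
draws. Everything is reproducible from ``config.seed`` alone.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ..analytics import Event, EventLog, UserRecord
from ..engine import FINISH_OPTION, Session, advance_turn, start_session
from ..messages import UserInput
from ..model import DialogGraph
from ..nlu import IntentRegistry, RiskLexicon

__all__ = ["TrialSimConfig", "simulate_trial"]

_Prob = Field(ge=0.0, le=1.0)

#: Benign free-text replies used when a replayed session hits a free-text
#: node; none of them matches a risk phrase or a priority intent.
SAFE_UTTERANCES = [
    "feeling pretty grateful today",
    "a bit tired but doing ok",
    "hanging out with my mates online",
    "listening to music mostly",
]


class TrialSimConfig(BaseModel):
    """Generator parameters; the packaged defaults emulate the uptake
    funnel and score distribution of a two-week open trial (see
    ``data/trial_default.yaml``)."""

    model_config = ConfigDict(extra="forbid")

    n_registered: int = Field(ge=0, default=393)
    p_login: float = _Prob
    p_target_age: float = _Prob
    age_target_range: tuple[int, int] = (13, 24)
    age_nontarget_range: tuple[int, int] = (25, 49)
    gender_mix: dict[str, float]
    ethnicity_mix: dict[str, float]
    mu_pre: float = Field(ge=0.0, le=10.0)
    sd_pre: float = Field(gt=0.0)
    effect_delta: float
    sd_noise: float = Field(ge=0.0)
    p_reach_outro: float = _Prob
    p_complete_outro: float = _Prob
    p_return: float = _Prob
    seed: int = 0


def _draw_categorical(rng: np.random.Generator, mix: dict[str, float]) -> str:
    cats = sorted(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(cats, p=probs))


def _sample_pre(rng: np.random.Generator, cfg: TrialSimConfig) -> int:
    while True:  # truncation by rejection; acceptance ~0.95 at defaults
        x = rng.normal(cfg.mu_pre, cfg.sd_pre)
        if 0.0 <= x <= 10.0:
            return int(round(x))


def _sample_post(pre: int, rng: np.random.Generator, cfg: TrialSimConfig) -> int:
    v = pre - cfg.effect_delta + rng.normal(0.0, cfg.sd_noise)
    return int(min(10, max(0, round(v))))


def _drive_session(
    graph: DialogGraph,
    registry: IntentRegistry,
    lexicon: RiskLexicon,
    user_id: str,
    prior: Optional[Session],
    rng: np.random.Generator,
    cfg: TrialSimConfig,
    log: EventLog,
) -> Session:
    """Replay one session with sampled choices: check-in score, one
    activity module, then either the outro chain or abandonment."""
    reach_outro = rng.random() < cfg.p_reach_outro
    complete_outro = rng.random() < cfg.p_complete_outro
    session, result = start_session(graph, user_id, prior=prior, log=log)
    pre_score: Optional[int] = None
    did_activity = False
    for _ in range(50):  # generous cap; scripted sessions are short
        if result.ended:
            break
        aw = result.awaiting
        if aw.kind == "assessment":
            if pre_score is None:
                pre_score = _sample_pre(rng, cfg)
                step = UserInput.score(pre_score)
            elif complete_outro:
                step = UserInput.score(_sample_post(pre_score, rng, cfg))
            else:
                step = UserInput.decline()
        elif aw.kind == "quick_reply" and aw.node_id is None:  # module menu
            if not did_activity and len(aw.options) > 1:
                did_activity = True
                step = UserInput.option(str(rng.choice(aw.options[:-1])))
            elif reach_outro:
                step = UserInput.option(FINISH_OPTION)
            else:
                break  # session abandoned mid-menu
        elif aw.kind == "quick_reply":
            step = UserInput.option(str(rng.choice(aw.options)))
        else:
            step = UserInput.text(str(rng.choice(SAFE_UTTERANCES)))
        result = advance_turn(
            session, graph, step, registry=registry, lexicon=lexicon, log=log
        )
    return session


def simulate_trial(
    config: TrialSimConfig,
    graph: Optional[DialogGraph] = None,
) -> tuple[list[UserRecord], EventLog]:
    """Generate (users, event log) for one synthetic open trial.

    Deterministic for a fixed config (the seed lives in the config).
    """
    from . import build_demo_graph, default_intents, default_risk_lexicon

    rng = np.random.default_rng(config.seed)
    graph = graph or build_demo_graph()
    registry = default_intents()
    lexicon = default_risk_lexicon()
    log = EventLog()
    users: list[UserRecord] = []

    for i in range(config.n_registered):
        uid = f"u{i:05d}"
        if rng.random() < config.p_target_age:
            lo, hi = config.age_target_range
        else:
            lo, hi = config.age_nontarget_range
        users.append(
            UserRecord(
                user_id=uid,
                age=int(rng.integers(lo, hi + 1)),
                gender=_draw_categorical(rng, config.gender_mix),
                ethnicity=_draw_categorical(rng, config.ethnicity_mix),
                registered_at=f"2020-04-01T00:00:00+00:00",
            )
        )
        log.append(
            Event(
                timestamp="2020-04-01T00:00:00+00:00",
                user_id=uid,
                type="registration",
                payload={"index": i},
            )
        )
        if rng.random() >= config.p_login:
            continue
        session = _drive_session(
            graph, registry, lexicon, uid, None, rng, config, log
        )
        if rng.random() < config.p_return:
            _drive_session(graph, registry, lexicon, uid, session, rng, config, log)
    return users, log
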
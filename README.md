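# korero

A dialog-graph engine for scripted mental-health support chatbots, built
for researchers and clinician-authors who deliver structured,
CBT-informed wellbeing content through a messaging channel and need the
whole pipeline — content model, turn execution, safety protocol, usage
analytics, and trial simulation — to be deterministic and testable.

## What it models

**Content as a typed directed graph.** A content pack is a set of dialog
*modules* (one entry node, one or more exits) built from a small node
palette: message bubbles, quick replies, free-text questions, invisible
branch/update-value nodes, rich media (posters, video, webviews), a
single-item assessment, and module exits. Packs are plain YAML, linted by
a structural validator (unrouted options, missing fallbacks, unreachable
exits, input-free cycles, orphan nodes, dangling priority bindings) and
exportable to Graphviz DOT.

**Deterministic dialog turns.** A turn traverses the graph from the
user's current vertex — emitting 2–3 message bubbles with a typing
indicator and length-proportional pacing `min(cap, base + rate·chars)` —
until a vertex requires input again. Sessions persist as JSON archives;
re-entry routes through an abbreviated greeting plus the brief
assessment.

**Intent routing with priority digressions.** Free text is classified to
one of 40 registry intents by a deterministic keyword scorer (pluggable
for an external NLU service). Routing precedence is strict:

1. **risk phrase** → escalation: confirmation, expression of empathy,
   direction to a help hotline, and shutdown of the automated dialog;
2. **locally configured intent edge** at the current node;
3. **priority intent** (recognised anywhere: self-harm, risk of abuse,
   low mood, fear, boredom, quit/exit) → digression to its bound target,
   returning to the interrupted prompt afterwards;
4. **fallback edge** → a generally applicable response.

**Privacy-safe analytics.** Event logs record only the series of
activities and intents — payloads carrying raw user text are rejected.
Cohort summaries compute the uptake funnel (registered → logged in →
target age 13–24), demographic percentages, pre/post completion of the
0–10 worry item ("no worries" … "totally freaking out"), and the mean
(SD) change, with half-up rounding at presentation precision.

**Trial simulation.** `fixtures.simulate_trial` generates a synthetic
open-trial cohort by actually replaying the demo pack per user:
session-start scores are drawn from a normal(μ_pre, σ_pre) truncated to
[0, 10] and discretised; outro scores follow
`post = clamp(round(pre − δ + ε))`, `ε ~ N(0, σ_noise)`; login, outro
reach, recheck completion, and repeat sessions are Bernoulli. The
packaged defaults emulate a two-week open trial (393 registrations,
~61% login, worry 5.1 → 4.3).

## Worked example

```python
from korero import fixtures, replay_script

graph = fixtures.build_demo_graph()          # 25-module demo pack, lints clean
transcript, session = replay_script(graph, fixtures.coverage_script())
for line in transcript.outbound_texts()[:5]:
    print(">", line)
print("assessments:", [(a.phase, a.score) for a in session.assessments])
```

prints

```
> Kia ora! I'm Kora, your wellbeing guide.
> Just so you know — I'm a computer program, not a real person.
> Together we can explore simple skills to look after your hauora.
> First, one quick check-in question, then you pick an activity.
> On a scale of 0 to 10, where 0 is “no worries” and 10 is “totally freaking out”, how worried are you right now?
assessments: [('onboarding', 5), ('outro', 4)]
```

The scripted user scores 5 at onboarding, tries two activity modules,
and records 4 at the outro recheck — one pre/post completer. The same
flow is available from the shell:

```bash
korero validate                      # 0 errors
korero replay --seed 9 --out t.jsonl # byte-identical on re-run
korero simulate-trial --seed 3       # users.csv + events.jsonl
korero summarize --users users.csv --events events.jsonl
```

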
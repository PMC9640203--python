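# Methods

## Dialog model and turn procedure

A content pack is a directed graph partitioned into modules. Node
identifiers are slugs, unique graph-wide, so edges name bare node ids;
cross-module edges are representable (priority digressions require them
in effect) but the linter warns on explicit ones, steering authors
toward module exits and menu returns. Module chaining is expressed on
the exit node itself: `next: <module>` chains, `next: end` finishes the
session, and no hint returns control to the module menu (or to a pending
digression origin).

A *turn* starts when user input is consumed and traverses nodes —
emitting text/attachment bubbles, applying variable updates, evaluating
branches — until a node requiring input, or session end. Traversal is
capped at `max_steps = 200` nodes per turn; exceeding the cap raises an
engine fault rather than looping, because a validated pack cannot hit it
(input-free cycles are validation errors). The engine never sleeps:
pacing is an annotation (`min(cap_ms, base_ms + rate_ms_per_char·len)`,
defaults 2000/300/10, zero in test mode) applied by the channel layer,
which keeps replays instant and transcripts byte-identical for a fixed
(graph, script, seed).

Variables are typed integer/boolean/short-string; conditions use the
closed operator set {eq, ne, lt, le, gt, ge, is_set}. An unset variable
under any operator but `is_set` routes a branch to its `default` edge,
and a type-incompatible ordering comparison does the same — degenerate
inputs select the author-designated safe path instead of raising.
Update expressions are limited to `var ± int`; an unset operand is
treated as 0 with a warning.

Re-entry behaviour is content, not engine code: the engine seeds
`session_index` and `returning` variables at session start and the demo
pack's onboarding block branches on them (full intro and psychoeducation
the first time; greeting plus the brief assessment thereafter). Session
state is keyed on `session_index` only; whether a user finished prior
onboarding does not change the route.

## Intent classification and routing

The default classifier is a deterministic keyword/phrase scorer: a
pattern matches as a contiguous token subsequence after normalisation
(lowercase, accent folding, punctuation stripping); its score is the
fraction of input tokens it covers; the best-scoring intent wins and
ties break lexicographically on intent id. There is no confidence
threshold by default (the best match wins; fallback only when nothing
matches). This stands in for an external NLU service behind the same
function signature — the point is a self-contained, replayable default,
not a statistical model.

Routing precedence is strict and total: risk phrase > locally configured
intent edge > priority intent > fallback. Design choices on the points
the precedence rule leaves open:

- A *self-harm* lexicon match escalates (below). An *abuse* match is
  treated as a priority digression to the protective-support module
  rather than a shutdown: the user may be describing danger from others,
  where cutting the conversation off is the wrong default.
- After a priority digression, an exit with no explicit hint returns the
  user to the interrupted prompt (re-prompted verbatim). The
  alternative — dropping to the menu — silently discards the authored
  context the user was in; gentle resume is the least-disruptive option.
- The quit/exit priority intent routes into the outro chain (recheck,
  feedback, resources) rather than terminating outright, so a departing
  user still passes the resources screen.
- The registry ships exactly 40 intents, *including* the priority
  intents; beyond the named mood and priority intents the remainder are
  package-invented conversational topics, present so the registry size
  and many-to-one intent→edge convergence are exercised realistically.

## Risk escalation

Escalation is a fixed two-phase sequence: confirmation question
(yes/no), then on *yes* an empathy message, a helpline direction, and
session shutdown (exactly one `risk_escalation` event; no further turns
accepted). On *no* the session resumes at the interrupted node. The
denial branch is this package's design: the protocol's confirmation step
implies one, and resuming beats abandoning a user who typed something
ambiguous. All escalation texts are pack configuration; the shipped
fixture uses a placeholder helpline number deliberately, so a research
artifact never carries stale clinical guidance.

## Event logging and cohort summaries

Events carry module ids, intent ids, phases and integer scores — never
free text; payload keys that would carry raw text (`text`, `utterance`,
…) are rejected at construction and again at append. Timestamps are a
deterministic logical clock (one tick per event from a fixed epoch) so
logs replay byte-identically; a wall clock would be injected at
deployment.

Cohort summaries compute: the funnel (registered, logged in, target age
13–24 inclusive), demographic percentages over target-age users,
returners (≥ 2 sessions), and pre/post completion. The pre score of a
pair is the first onboarding/intro score of a session; the pair must
come from the *same* session (cross-session pairing is rejected — the
instrument is a state measure, and pairing across visits would conflate
change with between-visit drift). The denominator is target-age users
with a recorded session-start score who reached the outro offer; it is
surfaced explicitly rather than derived, since completion rates are only
interpretable against a stated denominator. Percentages and means use
half-up rounding at presentation precision (1 dp; completion rate 0 dp);
SD is the sample standard deviation (n−1), absent when n < 2.

## Trial simulator

`simulate_trial` draws a registration cohort and replays one or two
sessions per logged-in user through the real engine on the demo pack, so
its event log is structurally identical to live logs. Defaults (units in
parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_registered` | 393 | cohort size (users) |
| `p_login` | 0.6056 | P(registration → login) |
| `p_target_age` | 0.5336 | P(login is aged 13–24) |
| `gender_mix` / `ethnicity_mix` | 70.9% female / 47.2% NZ European, remainder spread with an other/unspecified category | demographic draw |
| `mu_pre`, `sd_pre` | 5.1, 2.6 (scale points) | worry-score model, truncated to [0, 10], discretised |
| `effect_delta` | 0.8 | mean pre→post improvement |
| `sd_noise` | 1.0 | SD of the additive post-score noise |
| `p_reach_outro` | 0.638 | P(target-age session reaches the outro offer) |
| `p_complete_outro` | 0.370 | P(recheck completed given offered) |
| `p_return` | 0.244 | P(repeat session) |

These defaults emulate a two-week open trial's uptake funnel and score
distribution and are fixed as the package's study conditions. Two
consequences of the simple score model are worth stating. Truncating
normal(5.1, 2.6) to [0, 10] shifts the realised mean only slightly
(≈ 5.08) but shrinks the realised SD to ≈ 2.2; and the additive-noise
post model necessarily *inflates* post-score variance relative to the
pre scores (realised post SD ≈ 2.6–2.8), where real pre/post data are
positively correlated and can show a smaller post SD. The generator is
therefore calibrated to recover the pre and post *means*, not the SDs.
The simulator also makes no attempt to model session duration,
time-of-day usage, message-level timing, or demographic-dependent
engagement; passing tests show the pipeline arithmetic is right under
these conditions, not that real cohorts behave this way.

## Verification strategy and problem sizes

Every behavioural contract is checked against an independent oracle:
traversal against a naive recursive interpreter on random small DAG
packs; validator reachability against a networkx BFS; cohort summaries
against a brute-force pass over raw events; classifier tie-breaking
against exhaustive scoring of a toy registry; routing precedence against
the full 2⁴ matrix; escalation by injection at every input-accepting
node of the demo pack. Round-trip identity of the YAML serialization is
property-tested over randomly generated packs (derandomised hypothesis).

The acceptance script reports the cohort percentages recomputed from a
table built with the published funnel counts, the registry size, and
score means recovered from a simulated trial scaled to ~24,000
registrations (~2,000 completers), a size chosen so the sampling error
of a 1-dp mean is small (SE ≈ 0.05) while the whole run stays under half
a minute.

## Known limitations

- The keyword classifier has no spell correction, negation handling, or
  embeddings; "I'm not sad" classifies as sadness. A production
  deployment would plug an external classifier into the same interface.
- Risk detection is lexicon-substring based: paraphrased or oblique
  self-harm expressions not in the lexicon are not caught. The lexicon
  is configuration and should be clinically curated per deployment.
- The engine is single-user, synchronous, and in-memory by design;
  multi-user serving, push notifications and scheduled follow-ups are
  out of scope.
- Webviews, carousels and media are opaque references; no rendering.
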
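# Risk-phrase lexicon. self_harm matches trigger the escalation protocol
# (confirm -> empathy -> helpline -> shutdown); abuse matches digress to
# the protective-support module. Matching is case- and
# punctuation-insensitive on both sides.
phrases:
  - {pattern: "kill myself", category: self_harm}
  - {pattern: "end my life", category: self_harm}
  - {pattern: "hurt myself", category: self_harm}
  - {pattern: "harm myself", category: self_harm}
  - {pattern: "self harm", category: self_harm}
  - {pattern: "want to die", category: self_harm}
  - {pattern: "suicide", category: self_harm}
  - {pattern: "end it all", category: self_harm}
  - {pattern: "better off without me", category: self_harm}
  - {pattern: "not safe at home", category: abuse}
  - {pattern: "hits me", category: abuse}
  - {pattern: "being abused", category: abuse}
  - {pattern: "hurting me at home", category: abuse}
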
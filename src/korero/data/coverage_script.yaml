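# Happy-path conversation over the demo pack that touches every node type:
# branch (re-entry gate), message, assessment, rich media (poster),
# free text, update value, quick replies, and exit-module handling
# through the full outro chain.
steps:
  - score: 5                           # brief assessment (onboarding)
  - option: "Practice gratitude"       # module menu
  - text: "Feeling pretty grateful today"
  - option: "Get active"               # module menu
  - option: "Star jumps"               # quick replies -> update/branch
  - option: "Finish up"                # menu -> outro chain
  - score: 4                           # recheck of the brief assessment
  - option: "😊"                       # give feedback
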
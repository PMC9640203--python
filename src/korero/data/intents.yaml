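# Default intent registry: exactly 40 intents.
# The 8 mood/emotion intents and the 6 priority intents (fear is both)
# model the deployed configuration; the remainder are fixture-invented
# conversational intents that round the registry out to 40.
fallback_id: fallback
intents:
  # --- mood / emotion ------------------------------------------------------
  - intent_id: anger
    patterns: ["angry", "mad", "furious", "pissed off", "raging"]
  - intent_id: sadness
    patterns: ["sad", "down", "unhappy", "crying", "miserable", "gutted"]
  - intent_id: loneliness
    patterns: ["lonely", "alone", "isolated", "no friends", "left out"]
  - intent_id: stress
    patterns: ["stressed", "stress", "under pressure", "overloaded"]
  - intent_id: fear
    patterns: ["scared", "afraid", "frightened", "nervous", "terrified"]
    is_priority: true
    priority_target: ca_breath
  - intent_id: anxiety
    patterns: ["anxious", "anxiety", "worried", "worry", "on edge", "freaking out"]
  - intent_id: happiness
    patterns: ["happy", "great", "awesome", "really good", "cheerful"]
  - intent_id: excitement
    patterns: ["excited", "stoked", "thrilled", "pumped", "buzzing"]
  # --- priority intents (detected anywhere in the dialog) ------------------
  - intent_id: low_mood
    patterns: ["hopeless", "numb", "really low", "feeling low", "cant be bothered", "can't be bothered", "empty inside"]
    is_priority: true
    priority_target: get_expert_help_intro
  - intent_id: self_harm
    patterns: ["hurt myself", "harm myself", "self harm", "kill myself", "end it all"]
    is_priority: true
    priority_target: get_expert_help_intro
  - intent_id: boredom
    patterns: ["bored", "boring", "nothing to do", "so dull"]
    is_priority: true
    priority_target: distract_yourself_intro
  - intent_id: risk_of_abuse
    patterns: ["not safe at home", "hits me", "hurting me", "being abused", "scared of him", "scared of her"]
    is_priority: true
    priority_target: v_intro
  - intent_id: quit_exit
    patterns: ["quit", "exit", "bye", "goodbye", "want to leave", "finish the chat"]
    is_priority: true
    priority_target: worry_recheck
  # --- fixture-invented conversational intents -----------------------------
  - intent_id: greeting
    patterns: ["hello", "hi", "hey", "kia ora", "morena"]
  - intent_id: thanks
    patterns: ["thanks", "thank you", "cheers", "nga mihi"]
  - intent_id: affirmation
    patterns: ["yes", "yeah", "yep", "sure", "ok", "okay"]
  - intent_id: negation
    patterns: ["no", "nah", "nope", "not really"]
  - intent_id: help_request
    patterns: ["help", "i need help", "what can you do", "how does this work"]
  - intent_id: gratitude
    patterns: ["grateful", "thankful", "gratitude", "blessed"]
  - intent_id: tiredness
    patterns: ["tired", "exhausted", "worn out", "no energy"]
  - intent_id: sleep_trouble
    patterns: ["cant sleep", "can't sleep", "insomnia", "awake all night"]
  - intent_id: frustration
    patterns: ["frustrated", "annoyed", "fed up", "over it"]
  - intent_id: confusion
    patterns: ["confused", "dont understand", "don't understand", "what do you mean"]
  - intent_id: calm
    patterns: ["calm", "relaxed", "chill", "peaceful"]
  - intent_id: hope
    patterns: ["hopeful", "optimistic", "looking forward"]
  - intent_id: motivation
    patterns: ["motivated", "determined", "keen to start"]
  - intent_id: exercise
    patterns: ["exercise", "workout", "run", "gym", "sport"]
  - intent_id: food
    patterns: ["food", "eating", "hungry", "kai"]
  - intent_id: school
    patterns: ["school", "homework", "exams", "study", "ncea"]
  - intent_id: work
    patterns: ["work", "job", "shift", "boss"]
  - intent_id: family
    patterns: ["family", "whanau", "parents", "mum", "dad", "siblings"]
  - intent_id: friends
    patterns: ["friends", "mates", "friend group"]
  - intent_id: relationship
    patterns: ["boyfriend", "girlfriend", "partner", "break up", "crush"]
  - intent_id: money
    patterns: ["money", "broke", "rent", "bills", "cant afford", "can't afford"]
  - intent_id: health
    patterns: ["sick", "unwell", "headache", "doctor"]
  - intent_id: covid_info
    patterns: ["covid", "virus", "pandemic", "vaccine"]
  - intent_id: lockdown_info
    patterns: ["lockdown", "alert level", "bubble", "restrictions"]
  - intent_id: music
    patterns: ["music", "song", "playlist", "singing"]
  - intent_id: games
    patterns: ["games", "gaming", "minecraft", "fortnite"]
  - intent_id: weather
    patterns: ["weather", "raining", "sunny", "cold outside"]
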
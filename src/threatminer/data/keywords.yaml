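# Default keyword configuration for screening threat narratives for
# mentions of wild pigs (Sus scrofa).  Patterns ending in "*" match any
# token that begins with the given stem; all matching is case-insensitive.
patterns:
  - Pig
  - "pig*"
  - pigs
  - domesticus
  - Sus
  - scrofa
  - boar
  - "boar*"
  - boars
  - hog
  - "hog*"
  - hogs
  - swine
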
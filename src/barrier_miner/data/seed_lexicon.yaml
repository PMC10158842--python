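# Seed lexicon of treatment-barrier search expressions.
# Surfaces containing [..] are optional-infix alternations and expand to two
# variants at load time ("drug [ab]user" -> "drug user", "drug abuser").
version: 1
expressions:
  - {surface: insurance, theme: insurance}
  - {surface: junkie, theme: stigma}
  - {surface: stigma, theme: stigma}
  - {surface: "drug [ab]user", theme: stigma}
  - {surface: wait time, theme: logistics}
  - {surface: childcare, theme: logistics}
  - {surface: transport, theme: logistics}
  - {surface: clinic, theme: facility_location}
  - {surface: near, theme: facility_location}
changelog:
  - version: 1
    added: [insurance, junkie, stigma, "drug [ab]user", wait time, childcare, transport, clinic, near]
    removed: []
    note: seed set covering insurance, stigma, logistics and facility themes
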
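# Sentence templates for the synthetic corpus generator.
# Barrier templates carry one {expr} slot; a post planting several expressions
# concatenates one filled template per expression. Distractor posts are built
# from the distractor sentences only and are rejection-checked against the
# lexicon so they contain nothing within fuzzy-match range of any expression.
barrier:
  - "i lost my {expr} last month and everything fell apart"
  - "dealing with {expr} every single day is exhausting"
  - "the {expr} situation here makes it so hard to stay on treatment"
  - "cant believe i have to fight {expr} problems again this week"
  - "my {expr} keeps getting in the way of my recovery"
  - "honestly the {expr} part is what almost made me quit"
  - "nobody warned me how much {expr} would complicate getting my doses"
distractor:
  - "today marks ninety days for me and i feel hopeful"
  - "my dog kept me company through the rough nights"
  - "anyone else switch their dose schedule to mornings"
  - "the taper went smoother than i expected this week"
  - "i finally slept a full eight hours last night"
  - "been reading a lot of recovery stories on here lately"
  - "my doctor adjusted my dose and the cravings eased off"
  - "grateful for this community you all keep me going"
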
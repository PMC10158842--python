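# Methods

## The retrieval model

`barrier-miner` retrieves candidate treatment-barrier posts by approximate
lexical search: every search expression in a curated lexicon is compared
against every same-width (in words) sliding window of every post. The
similarity is the character-level Levenshtein ratio

    ratio(a, b) = (|a| + |b| − d(a, b)) / (|a| + |b|),

with d the Levenshtein distance using unit-cost insertions/deletions and
substitution cost 2. At substitution cost 2 a substitution is never cheaper
than a delete+insert pair, so d = |a| + |b| − 2·LCS(a, b) and the ratio
equals 2·LCS/(|a|+|b|); the implementation is validated against an
independent recursive DP oracle and, for the unit-cost convention, against
edlib. The ratio is 1.0 exactly when the strings are identical, and 1.0 by
convention for two empty strings.

A window matches when its ratio is **strictly** greater than the threshold
(default 0.9); ties at exactly 0.9 are excluded. Closed forms for an
expression of character length L against a singly-corrupted copy:

| corruption | ratio | passes 0.9 iff |
|---|---|---|
| one insertion | 2L/(2L+1) | L ≥ 5 |
| one deletion | (2L−2)/(2L−1) | L ≥ 6 |
| one substitution | 1 − 1/L | L ≥ 11 |

These bounds are asserted for L ∈ {3..15} in the test suite and are what
make the matcher's misspelling tolerance predictable. Substitution cost 1 is
exposed as a configuration alternative because it flips threshold outcomes
(one substitution in a 9-letter word scores 0.889 at cost 2 but 0.944 at
cost 1); cost 2 is the default and the convention used everywhere else.

Overlapping windows may each produce a match record; deduplication happens
only at the retrieved-post level, because the unit of analysis is the post,
not the span. Corpus scanning prunes windows by a length bound (the distance
is at least the length difference) and evaluates survivors with a banded
distance computation capped at the largest distance that could still pass
the threshold; the banded variant is property-tested against the full DP.

## Text normalization

Preprocessing is deliberately minimal: URL spans (`scheme://…`, `www.…`) are
removed first (stripping punctuation first would shred URLs into spurious
tokens), then per-character NFKC folding and lowercasing, deletion of all
Unicode P* punctuation (deleted, not blanked, so contractions collapse:
"i'm" → "im", "buprenorphine-naloxone" → "buprenorphinenaloxone"),
whitespace collapse, and splitting at word boundaries. No stemming,
stop-words or spell correction — misspellings are the fuzzy matcher's job.
The punctuation-deletion convention is a documented package choice, not an
inference about how any particular study preprocessed its text. Each token
keeps the raw-text character span it came from, so the original quote behind
any match is always recoverable (an invariant the suite checks by
re-normalizing the slice).

## Taxonomy and counting

Two major categories with five subcategories each (insurance: no insurance,
treatment not covered, fear of losing coverage, forced treatment switch,
general insurance difficulty; non-insurance: financial difficulty, stigma,
provider issues, poor treatment by clinician or pharmacist, fear of starting
treatment), plus exclusion codes (`unrelated`, `alcohol_use_disorder`) that
never co-occur with subcategories. Multi-label posts are stored with their
atomic codes; `multiple` is a *derived* counting bucket, not a stored label,
so data stay re-aggregatable while bucket counts are mutually exclusive and
partition the labeled posts (counts always sum to the total — the
conservation identity the fixtures assert as 40+44+8+5+68+13 = 178 and
22+40+4+3+1+14 = 84). A post labeled in both major categories contributes
independently to each category's report, which is why the two totals have
separate denominators.

Rule-based label suggestions (theme → at most one subcategory; default:
insurance → general insurance difficulty, stigma → stigma, logistics and
facility location → provider issues) are flagged `source=rule` and never
override manual labels.

Percentages are rounded half-up to one decimal — the convention that
reproduces printed study values (40/178 → 22.5; banker's rounding disagrees
on some buckets). Rounded columns may sum to 100 ± 0.3 (the non-insurance
column legitimately sums to 100.1) while count conservation is exact. One
flag's printed source value (fear, 6/19) appears as 31.5 in the original
report; 6/19 rounds to 31.6 under any one-decimal convention and the package
reports 31.6.

## Literature table fixture

The 19-publication table ships as a reviewed transcription of free-text
barrier lists into five boolean flags (stigma, logistical/financial,
gender-specific, fear, lack of knowledge) plus targeted-population tags.
Tags are multi-valued (semicolon-joined) because one publication — pregnant
women in rural and American Indian communities — genuinely belongs to the
women, racial/ethnic-minority and rural tallies at once; `pregnant` tags
count toward the women tally. The authoritative checks are the column
totals (15, 14, 7, 6, 5 of 19; 16 targeted; 7 women and 5 minorities of
16), which the fixture reproduces exactly; individual row flags involve
judgment calls on borderline phrasing and are transcription, not code.

## Synthetic corpus generator

The generator is the test substrate standing in for live platform data. It
emulates the *lexical* structure of short first-person forum posts: each
barrier post embeds one planted lexicon expression per gold subcategory
inside a template sentence ("i lost my ___ last month …"); `multiple`
posts plant two expressions from distinct subcategories; distractor posts
are built from barrier-free sentences and rejection-sampled (cap 100
attempts) until they contain nothing within fuzzy-match range of any
expression. Posts get synthetic ids, subreddits drawn from the three
medication forums, uniform timestamps over 2014-01 to 2021-08, and a 40%
comment share. All randomness flows through one seeded NumPy generator;
identical spec + seed + lexicon yields byte-identical corpora.

Defaults: the bucket mixture allocates 50% of posts to distractors (roughly
the observed share of unrelated posts among retrieved candidates in the
study setting this emulates) and splits the barrier half across the buckets
reachable under the default rulebook in proportion 68:40:4:14 (general
insurance difficulty : stigma : provider issues : multiple). The `multiple`
insurance bucket is unsatisfiable under the default rulebook (only one
lexicon theme maps into the insurance major category) and raises an explicit
error. `typo_rate` defaults to 0.2 with at most one edit per expression — a
tooling choice, since no empirical misspelling rate is available for this
domain.

Typo injection draws the operation (insert/delete/substitute) and position
uniformly over a lowercase alphabet, with one deliberate restriction: edits
never delete or substitute whitespace. An edit that merges two words changes
the token count of the planted phrase, which breaks the sliding-window
alignment and would invalidate the closed-form recall guarantees; insertions
may fall anywhere. Edits touch only the planted expression, never template
text, so each corrupted plant's ratio is exactly the closed form above —
which yields the two sharp, test-asserted predictions: single insert/delete
corruption of expressions ≥ 6 characters is always retrieved at threshold
0.9, and single substitutions on expressions ≤ 10 characters never are.

What the generator does *not* emulate: real vocabulary diversity, discourse
structure, thread dynamics, bots, code-switching, or barrier mentions phrased
without lexicon terms. Passing retrieval tests therefore demonstrate the
matcher's mechanical correctness (window arithmetic, threshold behavior,
typo tolerance), not real-world recall of barrier discussions — on real
data, recall depends on lexicon coverage, which is exactly why the lexicon
is versioned and refined iteratively with review sampling.

## Numerical and design notes

- Threshold comparisons use plain float arithmetic; at the boundary
  (e.g. ratio exactly 18/20) both sides round to the same double, so
  strict-greater exclusion is exact in practice.
- Window joining uses a single space between tokens, making scores
  reproducible bit-for-bit.
- Bracketed alternations in lexicon phrases ("drug [ab]user") expand to
  explicit variant surfaces at load.
- Review sampling (`sample_for_review`) is uniform without replacement via
  Python's seeded `random.Random`, so identical seeds reproduce samples
  across runs and platforms.
- Degenerate inputs are explicit errors, not silent zeros: empty frequency
  reports, empty gold sets, and an empty retrieved set's precision
  (undefined, reported as such rather than 0).
- Pipeline artifacts carry a provenance header (tool version, config hash,
  seed) and no timestamps, so identical configurations produce identical
  bytes.
- Problem sizes in the acceptance script — a 10,000-post typo-free corpus
  and a 2,000-post fully-corrupted corpus — are the package's chosen
  standard evaluation sizes; the measured recall/precision values are exact
  (1.0 / 0 false positives) by construction at any size, and the mixture
  calibration test uses 3-multinomial-SE bands at n = 4,000.

## Known limitations

- The retrieval model is purely lexical; no embeddings or classifiers, by
  design. Barriers phrased without lexicon vocabulary are invisible.
- The packaged lexicon is the seed set of printed example expressions; a
  production analysis would grow it through several review iterations.
- Qualitative coding is imported, not automated: the package validates and
  counts labels but does not produce final subcategory assignments itself.
- No inter-rater agreement statistics (labels are treated as consensus) and
  no statistical testing across categories or time.
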
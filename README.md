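# barrier-miner

Fuzzy-lexicon mining of opioid-use-disorder (OUD) treatment-barrier posts
from forum corpora.

People taking or considering medications for OUD (buprenorphine/naloxone,
methadone, naltrexone) discuss the obstacles they face — lack of insurance,
uncovered treatments, stigma, clinic logistics — candidly and anonymously on
forums such as Reddit's r/suboxone, r/Methadone and r/naltrexone.
`barrier-miner` implements the full retrieval-and-quantification pipeline for
that kind of infodemiology study: ingest a JSONL post corpus, normalize the
text, retrieve barrier-related posts by fuzzy matching a curated phrase
lexicon, categorize posts into a two-level barrier taxonomy, and report
per-category frequencies — plus a seeded synthetic-corpus generator that
makes every stage testable without platform data.

## Method

Each search expression *e* (e.g. `insurance`, `wait time`) is slid as a
window of the same width in words across every post's token stream. Window
tokens are joined with single spaces and compared to *e* at the character
level with the Levenshtein ratio

```
ratio(a, b) = (|a| + |b| − d(a, b)) / (|a| + |b|)
```

where *d* is the Levenshtein distance with unit-cost insertions/deletions
and substitutions costed 2. A window matches when ratio > 0.9 (strict), so
misspellings are captured: `wait times` still matches `wait time`
(ratio 18/19 ≈ 0.947) while `insurence` does not match `insurance`
(16/18 ≈ 0.889 — a single substitution only survives the threshold for
expressions of 11+ characters).

Retrieved posts are coded with subcategories from two major barrier
categories (insurance-related: no insurance, treatment not covered, fear of
losing coverage, forced treatment switch, general insurance difficulty;
non-insurance: financial difficulty, stigma, provider issues, poor treatment
by clinician or pharmacist, fear of starting treatment). Posts carrying two
or more subcategories within a major category are tallied once under a
derived `multiple` bucket, so bucket counts always partition the labeled
posts. A companion literature table (19 reviewed publications with boolean
barrier flags) supports the same prevalence arithmetic.

## Worked example

```
$ barrier-miner simulate --n 200 --typo-rate 0.2 --seed 42 \
      --out-corpus corpus.jsonl --out-gold gold.csv
wrote 200 posts
$ barrier-miner run --corpus corpus.jsonl --out-dir out --seed 42
matches out/matches.tsv
suggested       out/suggested.csv
report_insurance        out/report_insurance.tsv
report_non_insurance    out/report_non_insurance.tsv
$ cat out/report_non_insurance.tsv
# barrier-miner 0.1.0
# config=13d0ee6c7f4c seed=42
bucket  count   percentage
financial_difficulty    0       0.0
stigma  29      59.2
provider_issues 9       18.4
poor_treatment_by_clinician_or_pharmacist       0       0.0
fear_of_starting_treatment      0       0.0
multiple        11      22.4
TOTAL   49      100.0
```

`report_non_insurance.tsv` lists, for each counting bucket, how many
retrieved posts fell in it and the percentage of the non-insurance total;
`matches.tsv` records every fuzzy hit (post id, expression, token span,
window text, ratio) so the original quote behind any match can be inspected.
With `--typo-rate 0.2`, one in five planted expressions carries a random
character edit; single insertions/deletions on expressions of six or more
characters still match, which you can verify with
`barrier-miner evaluate --retrieved ids.txt --gold gold.csv`.

The packaged study numbers are recomputed and verified in one step:

```
$ barrier-miner reproduce
insurance_total 178     178     ok
insurance_no_insurance_pct      22.5    22.5    ok
...
literature_women_pct    43.8    43.8    ok
```

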
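# Methods

This note documents the models and procedures behind `healthlit`, the
defaults that matter, the numerical choices, and what the test fixtures do
and do not demonstrate.

## Text preparation and the document model

Raw UTF-8 text is segmented into paragraphs, sentences, and tokens with
0-based half-open character offsets; every token round-trips to the raw
text, so flags can always be anchored to exact spans.

* **Paragraphs** split on blank lines; a hard newline between two non-bullet
  lines also splits, so consecutive headings never merge. A lead-in line
  followed by bullets stays one paragraph.
* **Bullets** (markers `•`, `*`, `−`, `- `, and numbered `1.`/`1)`
  prefixes) are one sentence each,
  even without a full stop.
* **Sentences** split at terminal punctuation followed by whitespace, with
  guards for common abbreviations (`Dr.`, `e.g.`), dotted acronyms
  (`U.S.` is a single token), and decimals.
* **Headings** are detected heuristically: a standalone single-sentence line
  with no terminal punctuation and no finite verb. Detection is a default
  only — per-segment overrides are the authoritative mechanism, and they can
  flip every default decision.
* **Words** are tokens containing at least one letter; numerals and
  punctuation never count as words. Hyphenated alphanumerics
  (`COVID-19`) are one word.

Preparation marks short bullets and headings (< `min_segment_words`,
default 4) and URL segments as *excluded*: their tokens remain in the
document but feed no score.

The linguistic annotations (coarse part of speech, lemma, named-entity
mark) come from a rule-based engine: closed-class lookup tables
(determiners, prepositions, pronouns, conjunctions, auxiliaries), suffix
heuristics for open-class words, a small irregular table plus suffix
stripping for lemmas, and a gazetteer plus mid-sentence-capitalization
heuristic for named entities. This is deliberately procedural — fully
deterministic and auditable — at the cost of tagger accuracy on ambiguous
forms; the known consequences are noted per assessment below.

## Readability (SMOG)

The whole-text normalized SMOG formula is used:

    raw = 3.1291 + 1.0430 · sqrt(polysyllables × 30 / sentences)

over included sentences only, where a polysyllable is a word of three or
more syllables. The grade is `raw` rounded half-up (a deterministic tie
rule for "nearest whole number"). The original SMOG procedure samples 30
sentences; the normalized form scores documents of any length identically
under sentence-order permutation and self-concatenation (both are tested
invariants). Fewer than 10 assessable sentences triggers a warning rather
than an error, since the estimate is unstable on very short texts.

Syllables: dictionary lookup first (bundled TSV, case-insensitive), then a
vowel-group heuristic — count maximal runs of `aeiouy`, subtract a silent
terminal "e" unless it is the only vowel or preceded by "l" (so "gobble"
keeps 2), minimum 1. Acronyms absent from the dictionary are read letter by
letter (one syllable per letter); numerals are excluded from syllable
counting entirely. Both choices are package conventions: reading "MRI" as
three syllables reflects how such initialisms are spoken, and numbers have
no principled syllable count.

Long-word flags (≥3 syllables) and long-sentence flags (> 20 words,
configurable) cover included segments only.

## Complex language

* **Thesaurus**: entries carry string-search patterns and plain-language
  alternatives. Matching is case-insensitive on surface form, with lemmas
  also consulted for single-word patterns; multiword patterns win over
  shorter ones, scanning greedily left to right.
* **Uncommon words**: a word is common when its lemma *or* its lowercased
  surface form falls in the common region (default cutoff 5,000, capped at
  list length) of a frequency-ranked lemma list. The surface-form fallback
  compensates for the rule-based lemmatizer occasionally over-stripping; it
  can only reduce false positives, never create them. Named entities and
  acronyms are exempt (acronyms have their own category; exempting them
  avoids double counting, and the complexity score unions positions
  regardless).
* **Acronyms**: at least two capital letters, optionally with periods or
  lowercase letters in between (`WHO`, `U.S.`, `SHeLL`). This matches
  a declarative regular-expression oracle on random strings (tested).
* **Exclusion list**: at most 5 user-supplied words (error beyond the cap)
  suppress all three detectors, since all three constitute the
  complex-language assessment.

Text complexity = 100 × (distinct word positions carrying ≥1 of the three
flags) / included words. No target threshold is enforced; the score is
reported for tracking, not pass/fail.

## Passive voice

Pattern: a form of *to be* (`am is are was were be been being`), up to two
intervening adverbs or negations ("was **not really** checked"), then a
past participle. Participles are recognized contextlessly — an irregular
table plus the `-ed` suffix with a vowel-bearing stem and a short exception
list (`indeed`, `hundred`, …) — and the be-form requirement does the
disambiguation from simple past. Adjectival participles ("she was tired")
are flagged; this tagger noise is accepted and documented rather than
guessed away. Get-passives and bare passives are out of scope. Detection
runs over included segments, consistent with the other detectors.

## Lexical density and diversity

* **Density** = content words / function words over included words, where
  function = {preposition, pronoun, determiner, conjunction, auxiliary} and
  everything else is content. The plain overall ratio is reported (matching
  the worked 5:1 and 6:4 panel ratios and the spoken 1.5–2 / written 3–6
  ranges); a per-clause normalization is *not* attempted because clause
  boundaries are undefined in a rule-based setting. Zero function words
  yields an undefined sentinel with a warning.
* **TTR** = distinct lowercased word forms / total included words.
* **MTLD** (threshold 0.72, the conventional value from the measure's
  source literature): scan words accumulating a running TTR; each drop
  below the threshold counts one factor and resets; the remainder
  contributes a partial factor `(1 − TTR)/(1 − 0.72)`; the pass value is
  word count / factor total, and the reported MTLD is the mean of the
  forward and reverse passes. Texts under 10 words return the undefined
  sentinel, as does the degenerate case where a pass accrues no factor at
  all (a perfectly non-repeating text keeps TTR at 1.0, making the factor
  count zero and the measure undefined rather than merely large).

## Text structure

Paragraph flags: more than 8 included sentences or more than 150 included
words (boundaries: 9 sentences or 151 words trip, 8/150 do not). Question
flags: a sentence ending in "?" with at least 12 words and at least 3
tokens from {for, and, nor, but, or, yet, so}. Conjunctions are counted by
lowercase token string, so a prepositional "for" counts — deliberately, as
the flag is a proxy for working-memory overload, not a parse.

## Person-centered language

Case-insensitive longest-match search, aligned to token boundaries (so
"insufferable" never matches "sufferer") and never crossing a sentence
boundary. Each flag carries the lexicon entry's suggestion verbatim plus
its condition label. The bundled lexicon is a starter set distilled from
published language-guidance conventions; it is an editable TSV precisely
because condition-specific guidance keeps evolving.

## Reporting

All six assessments always run; the `active_assessments` toggle (default:
complex language, passive voice, readability — the three highest-priority
tiers) controls display only. Overlapping display spans are partitioned so
each character belongs to the highest-priority covering flag
(1 = complex language and person-centered, 2 = passive, 3 = readability,
4 = structure; within readability, word flags draw above sentence flags).
Person-centered language shares the top tier because its flags behave like
thesaurus entries (span + suggested replacement). JSON export is
schema-stable and key-sorted, so identical input and configuration produce
byte-identical bytes; Markdown replaces rich-text export with a diffable
surface.

## Synthetic fixtures

The generator builds prose from a closed filler vocabulary of common one-
and two-syllable words that can trip no detector, then plants requested
features — polysyllables, jargon, acronyms, uncommon words, a
subject + "was checked" passive, person-centered terms — one per sentence
at recorded character positions (an unsatisfiable request errors with the
reason). Ground-truth SMOG, complexity, and TTR are derived at generation
time from the plant counts and the assembled word list, independently of
the assessment pipeline. Default size is 2 paragraphs × 5 sentences × 8
words; the acceptance script uses 3 × 5 × 8 with 14 planted features —
small enough to run in milliseconds, large enough that every detector and
score is exercised.

What fixture passes show: the detectors recover exactly what was planted
(100% recall/precision at the planted spans) and the formulas match
independently computed tallies. What they do not show: lexicon coverage of
real medical prose, tagger accuracy on complex syntax, or heading/URL
detection on messy real-world formatting — those depend on the bundled
starter lexicons and the rule-based tagger, both documented as extensible.

## Known limitations

* The part-of-speech, lemma, and named-entity rules are far simpler than a
  trained statistical tagger; density and passive results on syntactically
  rich text carry corresponding noise.
* The bundled thesaurus, frequency list, and person-centered lexicons are
  small starter sets; production use should bring fuller lexicons in the
  same TSV formats (`--lexicon-dir`).
* SMOG on texts with heavy acronym or numeral content depends on the
  letter-per-syllable and numeral-exclusion conventions above.
* Guidance operating above the sentence level (coherence, ordering of
  ideas, risk communication) is out of scope.
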
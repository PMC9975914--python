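# healthlit

Objective, automated health-literacy assessment of written health information.

Most consumer health materials are written well above the reading level
recommended for the general population (Grade 8 or lower in Australia;
Grades 5–6 in the US), and guidance like "use everyday words" is hard to act
on without tooling. `healthlit` scores plain-text health documents against
objective, rule-based criteria and flags the exact spans that need work, so
writers and health services can iteratively simplify a text before consumer
testing.

## What it measures

* **Readability (SMOG).** The Simple Measure of Gobbledygook estimates the
  school grade needed for *full* comprehension from the density of
  polysyllabic words (>2 syllables) per sentence:

  `grade = 3.1291 + 1.0430 · sqrt(polysyllables × 30 / sentences)`

  computed over the whole prepared text and rounded to the nearest whole
  number. Words over 2 syllables and sentences over 20 words are flagged
  individually. Syllables come from a bundled dictionary with a vowel-group
  heuristic fallback.
* **Complex language.** Three detectors — a plain-language thesaurus
  (jargon with suggested alternatives), uncommon words (outside the common
  region of a frequency-ranked word list; named entities exempt), and
  acronyms (≥2 capital letters, periods/lowercase allowed) — plus an
  aggregate *text complexity*: the percentage of words carrying at least one
  of the three flags. Up to 5 words can be excluded by the user.
* **Passive voice.** A form of *to be* followed by a past participle
  ("the blood test **was ordered** by the doctor").
* **Text structure.** Paragraphs longer than 8 sentences or 150 words, and
  potentially double-barreled questions (≥12 words with more than 2 of
  "for, and, nor, but, or, yet, so").
* **Lexical density and diversity.** Content:function word ratio (spoken
  English ≈ 1.5–2, written ≈ 3–6), the type-token ratio, and MTLD (the
  Measure of Textual Lexical Diversity, threshold 0.72, forward/reverse
  averaged).
* **Person-centered language.** A string-search lexicon of stigmatizing
  wording with preferred alternatives ("sufferer" → "a person living with
  the condition") across diabetes, dementia, chronic pain, cancer, and
  mental health guidance.

Text preparation excludes short bullets and headings (under 4 words) and
URLs from score computations — without editing the text — and every decision
can be overridden per segment. Overlapping flags display by priority:
complex language and person-centered language, then passive voice,
readability, structure.

## Worked example

```bash
$ healthlit assess leaflet.txt
```

with `leaflet.txt`:

```
Hypertension management

Your blood pressure was checked by the nurse. Please obtain a reading
each morning. Ask your GP about medication.

- rest well
- drink more water every day
```

prints (abridged):

```
| Score | Value |
| --- | --- |
| SMOG grade reading score | 6 |
| Text complexity | 8.3% |
| Lexical density (content:function) | 1.67 |
| Type-token ratio | 0.958 |
| MTLD | 161.3 |

## Complex language
- "obtain" — 'obtain' may be jargon; simpler alternatives are available (try: get)
- "GP" — 'GP' is an acronym; spell it out at first use

## Passive voice
- "was checked" — passive voice: consider naming who performs the action

## Text preparation
- segment 0 (heading, 2 words): "Hypertension management"
- segment 4 (bullet, 2 words): "- rest well"
```

Reading: the text sits at Grade 6 (under the Grade 8 target); 8.3% of its
assessable words are complex; "was checked" should become active voice
("The nurse checked your blood pressure"); the two-word heading and bullet
were not counted toward readability. The density of 1.67 is in the
conversational range — appropriate for consumer materials.

The same pipeline is available as a library:

```python
from healthlit import run_all, PrepConfig

report = run_all(open("leaflet.txt").read(), PrepConfig())
print(report.smog_grade, report.complexity_percent)
```

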
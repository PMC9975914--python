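"""Synthetic fixture texts with known ground truth for every assessment.

Real validation texts for health-literacy tooling are rarely publishable,
so equivalence is demonstrated on generated documents instead: prose built
from a controlled vocabulary of short common words, into which a requested
number of polysyllabic words, jargon terms, acronyms, uncommon words,
passive constructions, and non-person-centered terms are planted at
recorded character positions. Every global score that follows from the
plant counts (SMOG inputs, complexity percentage, type-token ratio) is
derived at generation time, independently of the assessment pipeline, so
the pipeline can be checked against it.

The generator is deterministic given the seed. It emulates the *counting*
structure of health information — word, sentence, and paragraph layout with
known feature positions — not realistic medical prose: passing against
fixtures shows the detectors and formulas are correct, not that the
lexicons cover real-world jargon.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .complex_language import FrequencyLexicon, ThesaurusEntry
from .lexicons import LexiconSet
from .person_centered import PersonCenteredEntry
from .readability import SMOG_INTERCEPT, SMOG_SLOPE, SyllableLexicon

# --- controlled vocabulary ---------------------------------------------------
# Filler words: common, lowercase, 1-2 syllables, no "to be" forms, so they
# can never trip any detector.
FILLER_WORDS = (
    "the nurse can help you now take care at home each day drink more "
    "water rest well your team will check on this plan ask us about it "
    "keep notes in a book and we send them to you"
).split()

#: Polysyllabic plants (>= 3 syllables), all common words.
POLY_WORDS = {
    "important": 3,
    "hospital": 3,
    "together": 3,
    "remember": 3,
    "medication": 4,
}

#: Jargon plants: headword -> (plain alternative, syllables). All <= 2
#: syllables so they never contaminate the polysyllable count.
JARGON_WORDS = {
    "cease": ("stop", 1),
    "obtain": ("get", 2),
    "assist": ("help", 2),
    "prior": ("before", 2),
}

#: Acronym plants: two capitals -> two spoken letters, never polysyllabic.
ACRONYM_WORDS = ("GP", "ED", "BP", "UK")

#: Uncommon plants: real but rare words, <= 2 syllables.
UNCOMMON_WORDS = {"sedge": 1, "torpor": 2, "quoll": 1}

#: Passive plant: "to be" + past participle with its subject.
PASSIVE_PHRASE = ("the", "dose", "was", "checked")

#: Non-person-centered plants.
PERSON_WORDS = {"victim": "a person living with the condition"}

_SYLLABLES: dict[str, int] = {
    **{w: 1 for w in FILLER_WORDS},
    "about": 2,
    **POLY_WORDS,
    **{w: s for w, (_, s) in JARGON_WORDS.items()},
    **UNCOMMON_WORDS,
    "dose": 1,
    "was": 1,
    "checked": 1,
    "victim": 2,
    "sufferer": 3,
    "stop": 1,
    "get": 1,
    "before": 2,
}

_COMMON = tuple(
    dict.fromkeys(
        [
            *FILLER_WORDS,
            *POLY_WORDS,
            *JARGON_WORDS,
            "dose",
            "was",
            "checked",
            "victim",
            "stop",
            "get",
            "help",
            "before",
        ]
    )
)


def fixture_lexicons() -> LexiconSet:
    """Small lexicons consistent with the generator vocabulary: syllable
    counts for every vocabulary word, a frequency list containing everything
    except the uncommon plants, thesaurus entries for the jargon plants, and
    person-centered entries for the planted terms."""
    return LexiconSet(
        syllables=SyllableLexicon(_SYLLABLES),
        thesaurus=tuple(
            ThesaurusEntry(
                headword=word,
                match_patterns=(word,),
                alternatives=(alt,),
                source="fixture",
            )
            for word, (alt, _) in JARGON_WORDS.items()
        ),
        frequency=FrequencyLexicon(lemmas=_COMMON, common_cutoff=len(_COMMON)),
        person_centered=(
            PersonCenteredEntry(
                pattern="victim",
                suggestion=PERSON_WORDS["victim"],
                condition="general",
                rationale="avoids defining people by their condition",
            ),
            PersonCenteredEntry(
                pattern="sufferer",
                suggestion="a person living with X condition",
                condition="general",
                rationale="avoids defining people by their condition",
            ),
        ),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Size and plant counts for one generated document."""

    n_paragraphs: int = 2
    sentences_per_paragraph: int = 5
    words_per_sentence: int = 8
    n_polysyllabic: int = 0
    n_thesaurus_hits: int = 0
    n_acronyms: int = 0
    n_uncommon: int = 0
    n_passive: int = 0
    n_person_centered: int = 0
    seed: int = 0


@dataclass(frozen=True)
class PlantedItem:
    kind: str
    text: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about the text it built."""

    planted: tuple[PlantedItem, ...]
    n_sentences: int
    total_words: int
    n_polysyllabic: int
    raw_smog: float
    smog_grade: int
    complexity_percent: float
    ttr: float
    counts: dict[str, int] = field(default_factory=dict)

    def planted_of(self, kind: str) -> list[PlantedItem]:
        return [p for p in self.planted if p.kind == kind]


def _check_satisfiable(spec: FixtureSpec) -> None:
    n_sentences = spec.n_paragraphs * spec.sentences_per_paragraph
    n_units = (
        spec.n_polysyllabic
        + spec.n_thesaurus_hits
        + spec.n_acronyms
        + spec.n_uncommon
        + spec.n_passive
        + spec.n_person_centered
    )
    problems = []
    if spec.n_paragraphs < 1 or spec.sentences_per_paragraph < 1:
        problems.append("need at least one paragraph with one sentence")
    if spec.words_per_sentence < 5:
        problems.append(
            "words_per_sentence must be >= 5 so a sentence can host a "
            "4-word passive construction after its opening word"
        )
    if n_units > n_sentences:
        problems.append(
            f"{n_units} planted items do not fit in {n_sentences} sentences "
            "(the generator plants at most one item per sentence)"
        )
    if problems:
        raise ValueError("unsatisfiable fixture spec: " + "; ".join(problems))


def generate_fixture(spec: FixtureSpec) -> tuple[str, GroundTruth]:
    """Build the text and its ground truth; deterministic given the seed."""
    _check_satisfiable(spec)
    rng = random.Random(spec.seed)

    n_sentences = spec.n_paragraphs * spec.sentences_per_paragraph
    units: list[tuple[str, object]] = []
    poly_cycle = list(POLY_WORDS)
    jargon_cycle = list(JARGON_WORDS)
    uncommon_cycle = list(UNCOMMON_WORDS)
    person_cycle = list(PERSON_WORDS)
    for i in range(spec.n_polysyllabic):
        units.append(("polysyllabic", poly_cycle[i % len(poly_cycle)]))
    for i in range(spec.n_thesaurus_hits):
        units.append(("thesaurus", jargon_cycle[i % len(jargon_cycle)]))
    for i in range(spec.n_acronyms):
        units.append(("acronym", ACRONYM_WORDS[i % len(ACRONYM_WORDS)]))
    for i in range(spec.n_uncommon):
        units.append(("uncommon", uncommon_cycle[i % len(uncommon_cycle)]))
    for _ in range(spec.n_passive):
        units.append(("passive", PASSIVE_PHRASE))
    for i in range(spec.n_person_centered):
        units.append(("person_centered", person_cycle[i % len(person_cycle)]))

    host_sentences = rng.sample(range(n_sentences), len(units))
    plant_for_sentence: dict[int, tuple[str, object]] = dict(
        zip(host_sentences, units)
    )

    pieces: list[str] = []
    planted: list[PlantedItem] = []
    all_words: list[str] = []
    pos = 0
    sent_idx = 0
    for p in range(spec.n_paragraphs):
        if p > 0:
            pieces.append("\n\n")
            pos += 2
        for s in range(spec.sentences_per_paragraph):
            if s > 0:
                pieces.append(" ")
                pos += 1
            words = [rng.choice(FILLER_WORDS) for _ in range(spec.words_per_sentence)]
            plant_slots: dict[int, tuple[str, str]] = {}
            unit = plant_for_sentence.get(sent_idx)
            if unit is not None:
                kind, payload = unit
                if kind == "passive":
                    for k, w in enumerate(payload):
                        words[1 + k] = w
                        plant_slots[1 + k] = (kind if k in (2, 3) else "", w)
                else:
                    slot = rng.randrange(1, spec.words_per_sentence)
                    words[slot] = payload
                    plant_slots[slot] = (kind, payload)
            words[0] = words[0].capitalize()

            passive_span: list[int] = []
            for slot, w in enumerate(words):
                if slot > 0:
                    pieces.append(" ")
                    pos += 1
                start, end = pos, pos + len(w)
                pieces.append(w)
                pos = end
                all_words.append(w.lower())
                kind_here = plant_slots.get(slot, ("", ""))[0]
                if kind_here == "passive":
                    passive_span.append(start)
                    passive_span.append(end)
                elif kind_here:
                    planted.append(PlantedItem(kind_here, w, start, end))
            if passive_span:
                planted.append(
                    PlantedItem(
                        "passive",
                        " ".join(PASSIVE_PHRASE[2:]),
                        passive_span[0],
                        passive_span[-1],
                    )
                )
            pieces.append(".")
            pos += 1
            sent_idx += 1
    text = "".join(pieces)

    total_words = n_sentences * spec.words_per_sentence
    raw_smog = SMOG_INTERCEPT + SMOG_SLOPE * math.sqrt(
        spec.n_polysyllabic * 30 / n_sentences
    )
    n_complex = spec.n_thesaurus_hits + spec.n_acronyms + spec.n_uncommon
    truth = GroundTruth(
        planted=tuple(planted),
        n_sentences=n_sentences,
        total_words=total_words,
        n_polysyllabic=spec.n_polysyllabic,
        raw_smog=raw_smog,
        smog_grade=math.floor(raw_smog + 0.5),
        complexity_percent=100.0 * n_complex / total_words,
        ttr=len(set(all_words)) / len(all_words),
        counts={
            "thesaurus": spec.n_thesaurus_hits,
            "acronym": spec.n_acronyms,
            "uncommon": spec.n_uncommon,
            "passive": spec.n_passive,
            "person_centered": spec.n_person_centered,
            "readability_word": spec.n_polysyllabic,
        },
    )
    return text, truth
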
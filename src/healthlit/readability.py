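"""SMOG readability: syllable counting, grade estimation, and long-word /
long-sentence flags.

SMOG (Simple Measure of Gobbledygook) estimates the school grade at which a
reader fully comprehends the text, from the density of polysyllabic words
(more than two syllables) per sentence:

    grade = 3.1291 + 1.0430 * sqrt(polysyllables * 30 / sentences)

The whole-text normalized form is used (polysyllable count rescaled to a
30-sentence sample) rather than the original fixed 30-sentence sampling
procedure, since a document of any length is scored at once. Syllables come
from a dictionary lookup with a vowel-group heuristic fallback; acronyms
absent from the dictionary are read letter by letter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._lang import VOWELS, looks_like_acronym
from .config import PrepConfig
from .flags import Flag
from .textprep import Document, Token, word_count

#: Below this many assessable sentences the SMOG estimate is unstable.
MIN_STABLE_SENTENCES = 10

SMOG_INTERCEPT = 3.1291
SMOG_SLOPE = 1.0430
POLYSYLLABLE_MIN = 3  # "more than two syllables"


class SyllableLexicon(dict):
    """Case-insensitive word -> syllable-count map (all counts >= 1)."""

    def __init__(self, entries: dict[str, int] | None = None):
        super().__init__()
        for word, count in (entries or {}).items():
            if count < 1:
                raise ValueError(f"syllable count must be >= 1: {word!r} -> {count}")
            self[word.lower()] = count

    def lookup(self, word: str) -> int | None:
        return self.get(word.lower())


def _heuristic_syllables(word: str) -> int:
    """Count maximal vowel groups (a, e, i, o, u, y); subtract a silent
    terminal "e" unless it is the only vowel or is preceded by "l" (-le)."""
    lower = "".join(c for c in word.lower() if c.isalpha())
    groups = 0
    prev_vowel = False
    for c in lower:
        is_vowel = c in VOWELS
        if is_vowel and not prev_vowel:
            groups += 1
        prev_vowel = is_vowel
    if (
        groups > 1
        and lower.endswith("e")
        and len(lower) >= 2
        and lower[-2] not in VOWELS
        and lower[-2] != "l"
    ):
        groups -= 1
    return max(groups, 1)


def count_syllables(word: str, lex: SyllableLexicon) -> int:
    """Syllables in ``word``: dictionary value when present, else the
    vowel-group heuristic; acronyms not in the dictionary count one syllable
    per letter (read as individual letters)."""
    if not any(c.isalpha() for c in word):
        raise ValueError(f"not a word: {word!r}")
    from_dict = lex.lookup(word)
    if from_dict is not None:
        return from_dict
    if looks_like_acronym(word):
        return sum(1 for c in word if c.isalpha())
    return _heuristic_syllables(word)


def token_syllables(token: Token, lex: SyllableLexicon) -> int | None:
    """Syllable count for a word token; ``None`` for non-words (numerals and
    punctuation are excluded from syllable counting entirely)."""
    if not token.is_word:
        return None
    return count_syllables(token.surface, lex)


@dataclass(frozen=True)
class ReadabilityResult:
    raw_smog: float
    smog_grade: int
    n_included_sentences: int
    n_polysyllabic_words: int
    long_word_flags: tuple[Flag, ...] = ()
    long_sentence_flags: tuple[Flag, ...] = ()
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def smog(doc: Document, lex: SyllableLexicon) -> ReadabilityResult:
    """SMOG grade over included sentences only.

    Raises if the document has no included sentence containing a word; emits
    a warning marker when fewer than 10 sentences are assessable.
    """
    sentences = [s for s in doc.included_sentences() if s.words]
    if not sentences:
        raise ValueError("no assessable text")
    n_poly = 0
    for sent in sentences:
        for tok in sent.words:
            n = token_syllables(tok, lex)
            if n is not None and n >= POLYSYLLABLE_MIN:
                n_poly += 1
    raw = SMOG_INTERCEPT + SMOG_SLOPE * math.sqrt(n_poly * 30 / len(sentences))
    warnings = ()
    if len(sentences) < MIN_STABLE_SENTENCES:
        warnings = (
            f"only {len(sentences)} assessable sentences; the SMOG estimate "
            f"is unstable below {MIN_STABLE_SENTENCES}",
        )
    return ReadabilityResult(
        raw_smog=raw,
        smog_grade=_round_half_up(raw),
        n_included_sentences=len(sentences),
        n_polysyllabic_words=n_poly,
        warnings=warnings,
    )


def flag_long_words(doc: Document, lex: SyllableLexicon) -> list[Flag]:
    """One flag per polysyllabic word (>= 3 syllables) in included segments;
    these are the words driving the SMOG grade upward."""
    flags = []
    for sent in doc.included_sentences():
        for tok in sent.words:
            n = token_syllables(tok, lex)
            if n is not None and n >= POLYSYLLABLE_MIN:
                flags.append(
                    Flag(
                        category="readability_word",
                        char_start=tok.char_start,
                        char_end=tok.char_end,
                        message=f"'{tok.surface}' has {n} syllables; "
                        "consider a shorter word",
                    )
                )
    return flags


def flag_long_sentences(doc: Document, cfg: PrepConfig) -> list[Flag]:
    """One flag per included sentence longer than the threshold (default:
    flag at 21 words and above, i.e. strictly more than 20)."""
    flags = []
    for sent in doc.included_sentences():
        n = word_count(sent)
        if n > cfg.long_sentence_words:
            flags.append(
                Flag(
                    category="readability_sentence",
                    char_start=sent.char_start,
                    char_end=sent.char_end,
                    message=f"sentence has {n} words "
                    f"(aim for {cfg.long_sentence_words} or fewer)",
                )
            )
    return flags


def assess_readability(
    doc: Document, lex: SyllableLexicon, cfg: PrepConfig
) -> ReadabilityResult:
    """Full readability assessment: SMOG plus both flag kinds."""
    base = smog(doc, lex)
    return ReadabilityResult(
        raw_smog=base.raw_smog,
        smog_grade=base.smog_grade,
        n_included_sentences=base.n_included_sentences,
        n_polysyllabic_words=base.n_polysyllabic_words,
        long_word_flags=tuple(flag_long_words(doc, lex)),
        long_sentence_flags=tuple(flag_long_sentences(doc, cfg)),
        warnings=base.warnings,
    )
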
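"""Text-structure assessment: over-long paragraphs and complex questions.

Paragraphs longer than 8 sentences or more than 150 words (counting
included sentences) are flagged, per plain-language guidance on chunking.
Questions of at least 12 words containing more than 2 coordinating
conjunctions ("for", "and", "nor", "but", "or", "yet", "so") are flagged as
potentially double-barreled; conjunctions are counted by lowercase token
string, so a prepositional "for" counts — the flag is a proxy, not a parse.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PrepConfig
from .flags import Flag
from .textprep import Document, Paragraph, Sentence, word_count

COORDINATING_CONJUNCTIONS = frozenset(
    ["for", "and", "nor", "but", "or", "yet", "so"]
)


@dataclass(frozen=True)
class StructureResult:
    paragraph_flags: tuple[Flag, ...]
    question_flags: tuple[Flag, ...]

    @property
    def all_flags(self) -> tuple[Flag, ...]:
        return self.paragraph_flags + self.question_flags


def _included_counts(para: Paragraph) -> tuple[int, int]:
    sentences = [s for s in para.sentences if s.included]
    return len(sentences), sum(word_count(s) for s in sentences)


def flag_long_paragraphs(doc: Document, cfg: PrepConfig) -> list[Flag]:
    """At most one flag per paragraph exceeding either the sentence or the
    word limit (counting included sentences only)."""
    flags = []
    for para in doc.paragraphs:
        n_sent, n_words = _included_counts(para)
        if n_sent > cfg.paragraph_max_sentences or n_words > cfg.paragraph_max_words:
            flags.append(
                Flag(
                    category="structure",
                    char_start=para.char_start,
                    char_end=para.char_end,
                    message=f"paragraph has {n_sent} sentences and {n_words} "
                    f"words (aim for at most {cfg.paragraph_max_sentences} "
                    f"sentences and {cfg.paragraph_max_words} words)",
                )
            )
    return flags


def count_listed_conjunctions(sentence: Sentence) -> int:
    return sum(
        1 for t in sentence.tokens if t.lower in COORDINATING_CONJUNCTIONS
    )


def flag_complex_questions(doc: Document, cfg: PrepConfig) -> list[Flag]:
    """Flag questions meeting both the word-count and conjunction-count
    thresholds; declarative sentences are never flagged."""
    flags = []
    for sent in doc.sentences():
        if not sent.is_question():
            continue
        if (
            word_count(sent) >= cfg.question_min_words
            and count_listed_conjunctions(sent) >= cfg.question_min_conjunctions
        ):
            flags.append(
                Flag(
                    category="structure",
                    char_start=sent.char_start,
                    char_end=sent.char_end,
                    message="this question may be double-barreled; consider "
                    "splitting it into one question per idea",
                )
            )
    return flags


def assess_structure(doc: Document, cfg: PrepConfig) -> StructureResult:
    return StructureResult(
        paragraph_flags=tuple(flag_long_paragraphs(doc, cfg)),
        question_flags=tuple(flag_complex_questions(doc, cfg)),
    )
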
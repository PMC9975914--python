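"""Complex-language assessment: medical-jargon thesaurus matches, uncommon
words, acronyms, and the aggregate text-complexity percentage.

Three detectors run over included segments. A thesaurus of plain-language
alternatives is matched case-insensitively on surface form or lemma, longest
multiword pattern first. Uncommon words are those whose lemma (or surface
form) falls outside the common region of a frequency-ranked word list;
named entities and acronyms are exempt. Acronyms are a series of at least
two capital letters, optionally with periods or lowercase letters in
between. A user exclusion list (capped, 5 by default) suppresses all three
detectors for the listed words.

The text-complexity score is the percentage of word tokens carrying at
least one of the three flag kinds; a token flagged twice counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._lang import looks_like_acronym
from .config import PrepConfig, set_excluded_words  # re-export  # noqa: F401
from .flags import Flag
from .textprep import Document


@dataclass(frozen=True)
class ThesaurusEntry:
    """One jargon headword with its string-search patterns and plain-language
    alternatives."""

    headword: str
    match_patterns: tuple[str, ...]
    alternatives: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.match_patterns:
            raise ValueError(f"thesaurus entry {self.headword!r} has no patterns")
        if not self.alternatives:
            raise ValueError(f"thesaurus entry {self.headword!r} has no alternatives")


@dataclass(frozen=True)
class FrequencyLexicon:
    """Lemmas ranked by descending corpus frequency; ranks at or below
    ``common_cutoff`` count as common."""

    lemmas: tuple[str, ...]
    common_cutoff: int = 5000

    def __post_init__(self) -> None:
        if len(set(self.lemmas)) != len(self.lemmas):
            raise ValueError("frequency list contains duplicate lemmas")

    def common_set(self) -> frozenset[str]:
        return frozenset(self.lemmas[: self.common_cutoff])


@dataclass(frozen=True)
class ComplexityResult:
    thesaurus_flags: tuple[Flag, ...]
    uncommon_flags: tuple[Flag, ...]
    acronym_flags: tuple[Flag, ...]
    complexity_percent: float

    @property
    def all_flags(self) -> tuple[Flag, ...]:
        return self.thesaurus_flags + self.uncommon_flags + self.acronym_flags


def match_thesaurus(
    doc: Document, thesaurus: list[ThesaurusEntry], cfg: PrepConfig
) -> list[Flag]:
    """Flag thesaurus matches in included segments.

    Patterns are matched on lowercased surface forms, with single-word
    patterns also matched on lemmas; the longest multiword pattern wins on
    overlap, scanning greedily left to right. Excluded words are never
    flagged.
    """
    # pattern (as word tuple) -> entry
    patterns: dict[tuple[str, ...], ThesaurusEntry] = {}
    for entry in thesaurus:
        for pat in entry.match_patterns:
            words = tuple(pat.lower().split())
            if words:
                patterns.setdefault(words, entry)
    if not patterns:
        return []
    max_len = max(len(p) for p in patterns)
    excluded = set(cfg.excluded_words)

    flags = []
    for sent in doc.included_sentences():
        words = sent.words
        i = 0
        while i < len(words):
            matched = False
            for length in range(min(max_len, len(words) - i), 0, -1):
                window = words[i : i + length]
                keys = [tuple(t.lower for t in window)]
                if length == 1:
                    keys.append((window[0].lemma,))
                entry = next(
                    (patterns[k] for k in keys if k in patterns), None
                )
                if entry is None:
                    continue
                if any(t.lower in excluded or t.lemma in excluded for t in window):
                    continue
                flags.append(
                    Flag(
                        category="thesaurus",
                        char_start=window[0].char_start,
                        char_end=window[-1].char_end,
                        message=f"'{entry.headword}' may be jargon; "
                        "simpler alternatives are available",
                        suggestions=entry.alternatives,
                    )
                )
                i += length
                matched = True
                break
            if not matched:
                i += 1
    return flags


def detect_acronyms(doc: Document, cfg: PrepConfig) -> list[Flag]:
    """Flag acronym tokens (>= 2 capitals, periods/lowercase allowed) in
    included segments, unless listed in the exclusion list."""
    excluded = set(cfg.excluded_words)
    flags = []
    for sent in doc.included_sentences():
        for tok in sent.words:
            if tok.lower in excluded:
                continue
            if looks_like_acronym(tok.surface):
                flags.append(
                    Flag(
                        category="acronym",
                        char_start=tok.char_start,
                        char_end=tok.char_end,
                        message=f"'{tok.surface}' is an acronym; "
                        "spell it out at first use",
                    )
                )
    return flags


def detect_uncommon(
    doc: Document, freq: FrequencyLexicon, cfg: PrepConfig
) -> list[Flag]:
    """Flag words outside the common region of the frequency list.

    Named entities (people, places, organizations, languages, periods of
    time) are exempt, as are acronyms (handled by their own detector) and
    excluded words. A token is common when either its lemma or its
    lowercased surface form is in the common region.
    """
    common = freq.common_set()
    excluded = set(cfg.excluded_words)
    flags = []
    for sent in doc.included_sentences():
        for tok in sent.words:
            if tok.is_named_entity or tok.lower in excluded or tok.lemma in excluded:
                continue
            if looks_like_acronym(tok.surface):
                continue
            if tok.lemma in common or tok.lower in common:
                continue
            flags.append(
                Flag(
                    category="uncommon",
                    char_start=tok.char_start,
                    char_end=tok.char_end,
                    message=f"'{tok.surface}' is uncommon in everyday English",
                )
            )
    return flags


def complexity_score(
    doc: Document,
    thesaurus_flags: list[Flag],
    uncommon_flags: list[Flag],
    acronym_flags: list[Flag],
) -> ComplexityResult:
    """Aggregate text-complexity percentage: the share of included word
    tokens covered by at least one complex-language flag (a token flagged by
    two detectors counts once)."""
    words = doc.included_words()
    if not words:
        raise ValueError("no assessable text")
    spans = [
        (f.char_start, f.char_end)
        for f in (*thesaurus_flags, *uncommon_flags, *acronym_flags)
    ]
    flagged_positions = set()
    for i, tok in enumerate(words):
        for start, end in spans:
            if tok.char_start < end and start < tok.char_end:
                flagged_positions.add(i)
                break
    percent = 100.0 * len(flagged_positions) / len(words)
    return ComplexityResult(
        thesaurus_flags=tuple(thesaurus_flags),
        uncommon_flags=tuple(uncommon_flags),
        acronym_flags=tuple(acronym_flags),
        complexity_percent=percent,
    )


def assess_complex_language(
    doc: Document,
    thesaurus: list[ThesaurusEntry],
    freq: FrequencyLexicon,
    cfg: PrepConfig,
) -> ComplexityResult:
    """Run all three detectors and compute the aggregate score."""
    return complexity_score(
        doc,
        match_thesaurus(doc, thesaurus, cfg),
        detect_uncommon(doc, freq, cfg),
        detect_acronyms(doc, cfg),
    )
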
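"""Person-centered language assessment.

Flags words and phrases that peak-body guidance for diabetes, dementia,
chronic pain, cancer, and mental health identifies as blaming or
stigmatizing (e.g. "sufferer"), and suggests the preferred phrasing (e.g.
"a person living with the condition"). Matching is a case-insensitive,
token-boundary-aligned longest-match search within sentences of included
segments, so "insufferable" never matches "sufferer". The lexicon is a
deliberately editable starter set: condition-specific guidance can be added
as it is published.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flags import Flag
from .textprep import Document

CONDITIONS = (
    "diabetes",
    "dementia",
    "chronic_pain",
    "cancer",
    "mental_health",
    "general",
)


@dataclass(frozen=True)
class PersonCenteredEntry:
    pattern: str  # lowercase, may be multiword
    suggestion: str
    condition: str = "general"
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ValueError("person-centered pattern must be non-empty")
        if not self.suggestion.strip():
            raise ValueError(
                f"person-centered entry {self.pattern!r} has no suggestion"
            )


def flag_person_centered(
    doc: Document, lexicon: list[PersonCenteredEntry]
) -> list[Flag]:
    """Longest-match search for non-person-centered wording.

    Matches align to token boundaries and never cross a sentence boundary;
    each match carries the entry's suggestion verbatim plus its condition
    label.
    """
    patterns: dict[tuple[str, ...], PersonCenteredEntry] = {}
    for entry in lexicon:
        words = tuple(entry.pattern.lower().split())
        if words:
            patterns.setdefault(words, entry)
    if not patterns:
        return []
    max_len = max(len(p) for p in patterns)

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
                entry = next((patterns[k] for k in keys if k in patterns), None)
                if entry is None:
                    continue
                flags.append(
                    Flag(
                        category="person_centered",
                        char_start=window[0].char_start,
                        char_end=window[-1].char_end,
                        message=f"({entry.condition}) consider person-centered "
                        f"wording{': ' + entry.rationale if entry.rationale else ''}",
                        suggestions=(entry.suggestion,),
                    )
                )
                i += length
                matched = True
                break
            if not matched:
                i += 1
    return flags
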
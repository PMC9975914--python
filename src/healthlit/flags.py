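"""Flag objects shared by every assessment.

A flag marks one assessment hit on a character span of the raw text. Its
display priority is determined solely by its category, following the
hierarchy: complex language and person-centered language first (rank 1),
then passive voice (2), readability (3), and text structure (4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = (
    "thesaurus",
    "uncommon",
    "acronym",
    "person_centered",
    "passive",
    "readability_word",
    "readability_sentence",
    "structure",
)

CATEGORY_PRIORITY = {
    "thesaurus": 1,
    "uncommon": 1,
    "acronym": 1,
    "person_centered": 1,
    "passive": 2,
    "readability_word": 3,
    "readability_sentence": 3,
    "structure": 4,
}

# Which assessment toggle each flag category belongs to.
CATEGORY_ASSESSMENT = {
    "thesaurus": "complex_language",
    "uncommon": "complex_language",
    "acronym": "complex_language",
    "person_centered": "person_centered",
    "passive": "passive_voice",
    "readability_word": "readability",
    "readability_sentence": "readability",
    "structure": "structure",
}

# Within the shared readability tier, word flags draw above sentence flags.
_DISPLAY_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class Flag:
    """One assessment hit: a half-open character span plus advice."""

    category: str
    char_start: int
    char_end: int
    message: str
    suggestions: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown flag category: {self.category!r}")
        if not self.char_start < self.char_end:
            raise ValueError(
                f"flag span must be non-empty: [{self.char_start}, {self.char_end})"
            )

    @property
    def priority(self) -> int:
        return CATEGORY_PRIORITY[self.category]

    @property
    def assessment(self) -> str:
        return CATEGORY_ASSESSMENT[self.category]

    @property
    def display_rank(self) -> tuple[int, int]:
        """Sort key used when overlapping flags compete for a character."""
        return (self.priority, _DISPLAY_ORDER[self.category])
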
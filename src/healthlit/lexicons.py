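"""Lexicon file loading and validation.

Four tab-separated dialects are supported:

* ``thesaurus``: ``headword<TAB>pattern1|pattern2<TAB>alt1|alt2<TAB>source``
* ``frequency``: one lemma per line, descending frequency rank
* ``syllable``: ``word<TAB>syllables``
* ``person_centered``: ``pattern<TAB>suggestion<TAB>condition<TAB>rationale``

Malformed rows raise with line (and field) position; duplicate headwords
warn; an empty file yields an empty lexicon with a warning. Bundled starter
lexicons ship with the package and can be replaced by user files in the
same format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .complex_language import FrequencyLexicon, ThesaurusEntry
from .person_centered import CONDITIONS, PersonCenteredEntry
from .readability import SyllableLexicon

KINDS = ("thesaurus", "frequency", "syllable", "person_centered")


@dataclass(frozen=True)
class LexiconSet:
    """Everything the assessments need to look words up."""

    syllables: SyllableLexicon
    thesaurus: tuple[ThesaurusEntry, ...]
    frequency: FrequencyLexicon
    person_centered: tuple[PersonCenteredEntry, ...]


def _read_rows(path: Path) -> list[tuple[int, str]]:
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    rows = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, line))
    if not rows:
        warnings.warn(f"lexicon file {path} is empty", stacklevel=3)
    return rows


def _parse_thesaurus(path: Path) -> tuple[ThesaurusEntry, ...]:
    entries = []
    seen: set[str] = set()
    for lineno, line in _read_rows(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: thesaurus rows need at least 3 tab-separated "
                f"fields (headword, patterns, alternatives); got {len(fields)}"
            )
        headword, patterns, alternatives = fields[0], fields[1], fields[2]
        source = fields[3] if len(fields) > 3 else ""
        if not patterns.strip():
            raise ValueError(f"{path}:{lineno}: field 2 (patterns) is empty")
        if not alternatives.strip():
            raise ValueError(f"{path}:{lineno}: field 3 (alternatives) is empty")
        if headword.lower() in seen:
            warnings.warn(
                f"{path}:{lineno}: duplicate headword {headword!r}", stacklevel=3
            )
        seen.add(headword.lower())
        entries.append(
            ThesaurusEntry(
                headword=headword,
                match_patterns=tuple(
                    p.strip().lower() for p in patterns.split("|") if p.strip()
                ),
                alternatives=tuple(
                    a.strip() for a in alternatives.split("|") if a.strip()
                ),
                source=source,
            )
        )
    return tuple(entries)


def _parse_frequency(path: Path, common_cutoff: int | None = None) -> FrequencyLexicon:
    lemmas = []
    seen: set[str] = set()
    for lineno, line in _read_rows(path):
        lemma = line.strip().lower()
        if "\t" in line:
            raise ValueError(
                f"{path}:{lineno}: frequency rows are one lemma per line"
            )
        if lemma in seen:
            warnings.warn(f"{path}:{lineno}: duplicate lemma {lemma!r}", stacklevel=3)
            continue
        seen.add(lemma)
        lemmas.append(lemma)
    cutoff = common_cutoff if common_cutoff is not None else 5000
    return FrequencyLexicon(
        lemmas=tuple(lemmas), common_cutoff=min(cutoff, len(lemmas))
    )


def _parse_syllable(path: Path) -> SyllableLexicon:
    entries: dict[str, int] = {}
    for lineno, line in _read_rows(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: syllable rows are 'word<TAB>count'; "
                f"got {len(fields)} fields"
            )
        word, count_str = fields
        try:
            count = int(count_str)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: field 2 is not an integer: {count_str!r}"
            ) from None
        if count < 1:
            raise ValueError(f"{path}:{lineno}: syllable count must be >= 1")
        if word.lower() in entries:
            warnings.warn(f"{path}:{lineno}: duplicate word {word!r}", stacklevel=3)
        entries[word.lower()] = count
    return SyllableLexicon(entries)


def _parse_person_centered(path: Path) -> tuple[PersonCenteredEntry, ...]:
    entries = []
    for lineno, line in _read_rows(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(
                f"{path}:{lineno}: person-centered rows need at least 2 fields "
                f"(pattern, suggestion); got {len(fields)}"
            )
        pattern, suggestion = fields[0], fields[1]
        condition = fields[2] if len(fields) > 2 and fields[2].strip() else "general"
        rationale = fields[3] if len(fields) > 3 else ""
        if condition not in CONDITIONS:
            raise ValueError(
                f"{path}:{lineno}: field 3: unknown condition {condition!r} "
                f"(expected one of {', '.join(CONDITIONS)})"
            )
        entries.append(
            PersonCenteredEntry(
                pattern=pattern.strip().lower(),
                suggestion=suggestion.strip(),
                condition=condition,
                rationale=rationale.strip(),
            )
        )
    return tuple(entries)


def load_lexicon(path: str | Path, kind: str, **kwargs):
    """Load and validate one lexicon file of the given kind."""
    path = Path(path)
    if kind == "thesaurus":
        return _parse_thesaurus(path)
    if kind == "frequency":
        return _parse_frequency(path, kwargs.get("common_cutoff"))
    if kind == "syllable":
        return _parse_syllable(path)
    if kind == "person_centered":
        return _parse_person_centered(path)
    raise ValueError(f"unknown lexicon kind {kind!r} (expected one of {KINDS})")


_DATA_FILES = {
    "syllable": "syllables.tsv",
    "thesaurus": "thesaurus.tsv",
    "frequency": "frequency.txt",
    "person_centered": "person_centered.tsv",
}


def bundled_path(kind: str) -> Path:
    return Path(resources.files("healthlit") / "data" / _DATA_FILES[kind])


def load_bundled(common_cutoff: int | None = None) -> LexiconSet:
    """Load the starter lexicons shipped with the package."""
    return LexiconSet(
        syllables=load_lexicon(bundled_path("syllable"), "syllable"),
        thesaurus=load_lexicon(bundled_path("thesaurus"), "thesaurus"),
        frequency=load_lexicon(
            bundled_path("frequency"), "frequency", common_cutoff=common_cutoff
        ),
        person_centered=load_lexicon(
            bundled_path("person_centered"), "person_centered"
        ),
    )


def load_directory(directory: str | Path, common_cutoff: int | None = None) -> LexiconSet:
    """Load a user lexicon directory holding the four standard files
    (``syllables.tsv``, ``thesaurus.tsv``, ``frequency.txt``,
    ``person_centered.tsv``)."""
    directory = Path(directory)
    return LexiconSet(
        syllables=load_lexicon(directory / _DATA_FILES["syllable"], "syllable"),
        thesaurus=load_lexicon(directory / _DATA_FILES["thesaurus"], "thesaurus"),
        frequency=load_lexicon(
            directory / _DATA_FILES["frequency"], "frequency",
            common_cutoff=common_cutoff,
        ),
        person_centered=load_lexicon(
            directory / _DATA_FILES["person_centered"], "person_centered"
        ),
    )
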
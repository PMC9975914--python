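"""Assessment configuration: thresholds, toggles, and preparation overrides.

Defaults follow plain-language practice for consumer health information:
segments under 4 words are not counted toward readability, sentences over 20
words are flagged, paragraphs over 8 sentences or 150 words are flagged,
questions with at least 12 words and more than 2 coordinating conjunctions
are flagged as potentially double-barreled, and at most 5 words may be
exempted from the complex-language assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

ASSESSMENTS = (
    "complex_language",
    "passive_voice",
    "readability",
    "structure",
    "lexical",
    "person_centered",
)

DEFAULT_ACTIVE = frozenset({"complex_language", "passive_voice", "readability"})


@dataclass(frozen=True)
class PrepConfig:
    """Thresholds, assessment toggles, and text-preparation overrides."""

    min_segment_words: int = 4
    long_sentence_words: int = 20
    paragraph_max_sentences: int = 8
    paragraph_max_words: int = 150
    question_min_words: int = 12
    question_min_conjunctions: int = 3  # "more than 2"
    max_excluded_words: int = 5
    excluded_words: tuple[str, ...] = ()
    active_assessments: frozenset[str] = DEFAULT_ACTIVE
    segment_overrides: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.excluded_words) > self.max_excluded_words:
            raise ValueError(
                f"at most {self.max_excluded_words} words may be excluded from "
                f"the complex language assessment; got {len(self.excluded_words)}"
            )
        unknown = set(self.active_assessments) - set(ASSESSMENTS)
        if unknown:
            raise ValueError(f"unknown assessments: {sorted(unknown)}")


def set_excluded_words(cfg: PrepConfig, words: list[str]) -> PrepConfig:
    """Return a config whose exclusion list is ``words`` (lowercased).

    The list is capped at ``cfg.max_excluded_words`` (default 5); exceeding
    the cap is an error rather than a silent truncation.
    """
    lowered = tuple(w.lower() for w in words)
    if len(lowered) > cfg.max_excluded_words:
        raise ValueError(
            f"at most {cfg.max_excluded_words} words may be excluded from the "
            f"complex language assessment; got {len(lowered)}"
        )
    return replace(cfg, excluded_words=lowered)


_INT_KEYS = (
    "min_segment_words",
    "long_sentence_words",
    "paragraph_max_sentences",
    "paragraph_max_words",
    "question_min_words",
    "question_min_conjunctions",
    "max_excluded_words",
)


def load_config(path: str | Path) -> PrepConfig:
    """Parse a ``key = value`` config file into a :class:`PrepConfig`.

    Lists are comma-separated; segment overrides are ``index:true`` pairs.
    Unknown keys and malformed values raise with the offending line number.
    """
    kwargs: dict = {}
    for lineno, raw_line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            if key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key == "excluded_words":
                kwargs[key] = tuple(
                    w.strip().lower() for w in value.split(",") if w.strip()
                )
            elif key == "active_assessments":
                kwargs[key] = frozenset(
                    a.strip() for a in value.split(",") if a.strip()
                )
            elif key == "segment_overrides":
                overrides: dict[int, bool] = {}
                for pair in value.split(","):
                    if not pair.strip():
                        continue
                    idx, _, flag_val = pair.partition(":")
                    overrides[int(idx)] = flag_val.strip().lower() in ("true", "1", "yes")
                kwargs[key] = overrides
            else:
                raise ValueError(f"unknown key {key!r}")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return PrepConfig(**kwargs)
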
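"""Text preparation: segmentation into paragraphs, sentences, and tokens,
plus the inclusion rules deciding which segments feed score computations.

The raw text is split into paragraphs on blank lines (a hard newline between
two non-bullet lines also separates paragraphs, so that consecutive headings
do not merge). A line starting with a bullet marker is one sentence of kind
``bullet`` even without a full stop. Lines that are URLs become ``url``
segments; a short standalone line with no terminal punctuation and no finite
verb is heuristically a ``heading``.

Preparation then excludes short bullets and headings (under 4 words by
default) and URL segments from score computations, without deleting any
token; user-supplied per-segment overrides take precedence over every
default decision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ._lang import (
    ABBREVIATIONS,
    coarse_pos,
    lemma_of,
    looks_like_acronym,
    GAZETTEER,
)
from .config import PrepConfig

_BULLET_RE = re.compile(r"^\s*(?:[−–•‣◦*]|-\s|\d{1,2}[.)]\s)")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_TOKEN_RE = re.compile(
    r"""(?:https?://|www\.)\S+          # URL
      | (?:[A-Za-z]\.){2,}              # dotted acronym: U.S.
      | [A-Za-z0-9]+(?:[-'’][A-Za-z0-9]+)*
      | [^\sA-Za-z0-9]                  # single punctuation mark
    """,
    re.VERBOSE,
)
_TERMINAL = {".", "!", "?", "…"}


@dataclass(frozen=True)
class Token:
    """One token with character offsets into the raw text (0-based,
    half-open)."""

    surface: str
    lower: str
    lemma: str
    part_of_speech: str
    is_word: bool
    is_named_entity: bool
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not self.char_start < self.char_end:
            raise ValueError("token span must be non-empty")


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    kind: str = "prose"  # prose | bullet | heading | url
    included: bool = True

    @property
    def char_start(self) -> int:
        return self.tokens[0].char_start

    @property
    def char_end(self) -> int:
        return self.tokens[-1].char_end

    @property
    def words(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)

    def is_question(self) -> bool:
        return any(t.surface == "?" for t in self.tokens[-2:])


@dataclass(frozen=True)
class Paragraph:
    sentences: tuple[Sentence, ...]

    @property
    def char_start(self) -> int:
        return self.sentences[0].char_start

    @property
    def char_end(self) -> int:
        return self.sentences[-1].char_end


@dataclass(frozen=True)
class Document:
    raw_text: str
    paragraphs: tuple[Paragraph, ...] = field(default_factory=tuple)

    def sentences(self) -> list[Sentence]:
        return [s for p in self.paragraphs for s in p.sentences]

    def included_sentences(self) -> list[Sentence]:
        return [s for s in self.sentences() if s.included]

    def included_words(self) -> list[Token]:
        return [t for s in self.included_sentences() for t in s.words]


def word_count(span: Sentence | Paragraph) -> int:
    """Number of word tokens (tokens containing at least one letter)."""
    if isinstance(span, Sentence):
        return len(span.words)
    return sum(len(s.words) for s in span.sentences)


def _make_token(surface: str, start: int, sentence_initial: bool) -> Token:
    lower = surface.lower()
    is_url = bool(_URL_RE.fullmatch(surface))
    has_alpha = any(c.isalpha() for c in surface)
    if is_url:
        pos = "other"
    else:
        pos = coarse_pos(lower, surface)
    lemma = lemma_of(lower, pos) if has_alpha and not is_url else lower
    named = has_alpha and not is_url and (
        lower in GAZETTEER
        or (
            not sentence_initial
            and surface[0].isupper()
            and surface[1:].islower()
            and len(surface) > 1
        )
    )
    return Token(
        surface=surface,
        lower=lower,
        lemma=lemma,
        part_of_speech=pos,
        is_word=has_alpha and not is_url,
        is_named_entity=named,
        char_start=start,
        char_end=start + len(surface),
    )


def _tokenize(text: str, offset: int) -> list[Token]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(_make_token(m.group(), offset + m.start(), not tokens))
    return tokens


def _split_sentences(tokens: list[Token]) -> list[list[Token]]:
    """Group a token stream into sentences at terminal punctuation."""
    sentences: list[list[Token]] = []
    current: list[Token] = []
    for i, tok in enumerate(tokens):
        current.append(tok)
        if tok.surface in _TERMINAL or (tok.surface and set(tok.surface) <= _TERMINAL):
            prev = current[-2] if len(current) >= 2 else None
            if prev is not None and tok.surface == "." and prev.lower in ABBREVIATIONS:
                continue
            # Split only when whitespace follows the terminal mark, so
            # decimals ("3.5") and tight abbreviations stay intact.
            nxt = tokens[i + 1] if i + 1 < len(tokens) else None
            if nxt is None or nxt.char_start > tok.char_end:
                sentences.append(current)
                current = []
    if current:
        sentences.append(current)
    # Re-mark sentence-initial capitals as non-entities.
    fixed = []
    for sent in sentences:
        head = sent[0]
        if head.is_named_entity and head.lower not in GAZETTEER:
            sent[0] = replace(head, is_named_entity=False)
        fixed.append(sent)
    return fixed


def _has_finite_verb(tokens: list[Token]) -> bool:
    from ._lang import is_participle_candidate

    for t in tokens:
        if t.part_of_speech == "auxiliary":
            return True
        if (
            t.part_of_speech == "verb"
            and not is_participle_candidate(t.lower)
            and not t.lower.endswith("ing")
        ):
            return True
    return False


def _classify_line(line_tokens: list[Token], is_bullet: bool, standalone: bool) -> str:
    if any(_URL_RE.fullmatch(t.surface) for t in line_tokens):
        return "url"
    if is_bullet:
        return "bullet"
    if standalone:
        last = line_tokens[-1]
        if last.surface not in _TERMINAL and not _has_finite_verb(line_tokens):
            return "heading"
    return "prose"


def segment_text(raw: str) -> Document:
    """Deterministically segment raw text into a :class:`Document`.

    Empty input yields an empty document. All tokens carry offsets into
    ``raw`` so that every surface form round-trips exactly.
    """
    if not raw.strip():
        return Document(raw_text=raw)

    # Lines with absolute offsets.
    lines: list[tuple[str, int]] = []
    pos = 0
    for line in raw.split("\n"):
        lines.append((line, pos))
        pos += len(line) + 1

    # Group lines into paragraphs: blank line always breaks; a newline breaks
    # unless one side is a bullet line (so a lead-in line keeps its bullets).
    groups: list[list[tuple[str, int]]] = []
    current_group: list[tuple[str, int]] = []
    for line, off in lines:
        if not line.strip():
            if current_group:
                groups.append(current_group)
                current_group = []
            continue
        bullet = bool(_BULLET_RE.match(line))
        if current_group:
            prev_bullet = bool(_BULLET_RE.match(current_group[-1][0]))
            if not bullet and not prev_bullet:
                groups.append(current_group)
                current_group = []
        current_group.append((line, off))
    if current_group:
        groups.append(current_group)

    paragraphs = []
    for group in groups:
        sentences: list[Sentence] = []
        for line, off in group:
            bullet = bool(_BULLET_RE.match(line))
            tokens = _tokenize(line, off)
            tokens = [t for t in tokens if t.surface.strip()]
            if not tokens:
                continue
            if bullet:
                # Marker tokens are punctuation/number tokens; they stay in
                # the sentence but never count as words.
                kind = "url" if any(
                    _URL_RE.fullmatch(t.surface) for t in tokens
                ) else "bullet"
                sentences.append(Sentence(tokens=tuple(tokens), kind=kind))
            else:
                sent_tokens = _split_sentences(tokens)
                standalone = len(group) == 1 and len(sent_tokens) == 1
                for st in sent_tokens:
                    kind = _classify_line(st, is_bullet=False, standalone=standalone)
                    sentences.append(Sentence(tokens=tuple(st), kind=kind))
        if sentences:
            paragraphs.append(Paragraph(sentences=tuple(sentences)))

    doc = Document(raw_text=raw, paragraphs=tuple(paragraphs))
    for sent in doc.sentences():
        for tok in sent.tokens:
            assert raw[tok.char_start : tok.char_end] == tok.surface
    return doc


def apply_preparation(doc: Document, cfg: PrepConfig) -> Document:
    """Mark segments as included/excluded per the preparation rules.

    Default exclusions: bullets and headings under ``cfg.min_segment_words``
    words, and URL segments. ``cfg.segment_overrides`` (keyed by global
    sentence index) take precedence. Tokens are never deleted; exclusion only
    affects which segments feed score computations.
    """
    n_sentences = sum(len(p.sentences) for p in doc.paragraphs)
    for idx in cfg.segment_overrides:
        if not 0 <= idx < n_sentences:
            raise IndexError(
                f"segment override index {idx} out of range "
                f"(document has {n_sentences} segments)"
            )

    new_paragraphs = []
    global_idx = 0
    for para in doc.paragraphs:
        new_sentences = []
        for sent in para.sentences:
            if sent.kind == "url":
                included = False
            elif sent.kind in ("bullet", "heading"):
                included = word_count(sent) >= cfg.min_segment_words
            else:
                included = True
            if global_idx in cfg.segment_overrides:
                included = cfg.segment_overrides[global_idx]
            new_sentences.append(replace(sent, included=included))
            global_idx += 1
        new_paragraphs.append(Paragraph(sentences=tuple(new_sentences)))
    return Document(raw_text=doc.raw_text, paragraphs=tuple(new_paragraphs))


def prepare(raw: str, cfg: PrepConfig | None = None) -> Document:
    """Segment and apply preparation in one step."""
    cfg = cfg or PrepConfig()
    return apply_preparation(segment_text(raw), cfg)


__all__ = [
    "Token",
    "Sentence",
    "Paragraph",
    "Document",
    "segment_text",
    "apply_preparation",
    "prepare",
    "word_count",
]
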
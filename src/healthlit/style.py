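"""Style assessments: passive voice, lexical density, and lexical diversity.

Passive voice is detected as a form of "to be" followed — with up to two
intervening adverbs or negations — by a past participle ("the blood test
was ordered"). Lexical density is the ratio of content words (nouns,
most verbs, adjectives, most adverbs) to function words (prepositions,
pronouns, determiners, conjunctions, auxiliaries); spoken English typically
scores around 1.5–2 and written English 3–6. Diversity is reported both as
the raw type-token ratio (length-sensitive) and as MTLD, the Measure of
Textual Lexical Diversity, which counts how many words it takes for the
running type-token ratio to decay to a threshold (0.72 by convention) and
averages a forward and a reverse pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._lang import BE_FORMS, NEGATIONS, is_participle_candidate
from .flags import Flag
from .textprep import Document, Sentence, Token

FUNCTION_POS = frozenset(
    {"preposition", "pronoun", "determiner", "conjunction", "auxiliary"}
)

MTLD_THRESHOLD = 0.72
MTLD_MIN_WORDS = 10

#: Sentinel for scores that are undefined on the given text.
UNDEFINED = None


@dataclass(frozen=True)
class StyleResult:
    passive_flags: tuple[Flag, ...]
    lexical_density: float | None
    ttr: float
    mtld: float | None
    n_content_words: int
    n_function_words: int
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _is_intervener(token: Token) -> bool:
    return token.lower in NEGATIONS or token.part_of_speech == "adverb"


def detect_passive(doc: Document) -> list[Flag]:
    """Flag passive constructions in included segments.

    Pattern: a "to be" form, at most two intervening adverbs/negations, then
    a past participle. Adjective/participle ambiguity is resolved by the
    part-of-speech rules, with tagger error accepted as documented noise.
    """
    flags = []
    for sent in doc.included_sentences():
        tokens = sent.tokens
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            if tok.is_word and tok.lower in BE_FORMS:
                j = i + 1
                skipped = 0
                while (
                    j < len(tokens)
                    and skipped < 2
                    and tokens[j].is_word
                    and _is_intervener(tokens[j])
                ):
                    j += 1
                    skipped += 1
                if (
                    j < len(tokens)
                    and tokens[j].is_word
                    and is_participle_candidate(tokens[j].lower)
                ):
                    flags.append(
                        Flag(
                            category="passive",
                            char_start=tok.char_start,
                            char_end=tokens[j].char_end,
                            message="passive voice: consider naming who "
                            "performs the action",
                        )
                    )
                    i = j + 1
                    continue
            i += 1
    return flags


def classify_word_role(token: Token) -> str:
    """``"function"`` for prepositions, pronouns, determiners, conjunctions,
    and auxiliaries; ``"content"`` for every other part of speech."""
    if not token.is_word:
        raise ValueError(f"not a word token: {token.surface!r}")
    return "function" if token.part_of_speech in FUNCTION_POS else "content"


def _role_counts(doc: Document) -> tuple[int, int]:
    n_content = n_function = 0
    for tok in doc.included_words():
        if classify_word_role(tok) == "content":
            n_content += 1
        else:
            n_function += 1
    return n_content, n_function


def lexical_density(doc: Document) -> float | None:
    """Content:function word ratio over included words; ``None`` (with no
    meaningful ratio) when the text has no function words."""
    if not doc.included_words():
        raise ValueError("no assessable text")
    n_content, n_function = _role_counts(doc)
    if n_function == 0:
        return UNDEFINED
    return n_content / n_function


def type_token_ratio(doc: Document) -> float:
    """Distinct lowercased word forms divided by total included words."""
    words = [t.lower for t in doc.included_words()]
    if not words:
        raise ValueError("no assessable text")
    return len(set(words)) / len(words)


def _mtld_pass(words: list[str], threshold: float) -> float | None:
    """One directional MTLD pass; ``None`` when no factor (full or partial)
    accrues, i.e. the running type-token ratio never leaves 1.0."""
    factors = 0.0
    types: set[str] = set()
    token_count = 0
    ttr = 1.0
    for w in words:
        token_count += 1
        types.add(w)
        ttr = len(types) / token_count
        if ttr < threshold:
            factors += 1.0
            types.clear()
            token_count = 0
            ttr = 1.0
    if token_count > 0:
        factors += (1.0 - ttr) / (1.0 - threshold)
    if factors == 0.0:
        return None
    return len(words) / factors


def mtld(doc: Document, factor_threshold: float = MTLD_THRESHOLD) -> float | None:
    """Measure of Textual Lexical Diversity: mean of the forward and reverse
    factor-count passes at the given threshold.

    Returns ``None`` for texts under 10 included words, or when a pass
    accrues no factor at all (a short perfectly non-repeating text), where
    the measure is undefined.
    """
    words = [t.lower for t in doc.included_words()]
    if len(words) < MTLD_MIN_WORDS:
        return UNDEFINED
    forward = _mtld_pass(words, factor_threshold)
    reverse = _mtld_pass(words[::-1], factor_threshold)
    if forward is None or reverse is None:
        return UNDEFINED
    return (forward + reverse) / 2.0


def assess_style(doc: Document) -> StyleResult:
    """Passive flags plus density and diversity scores in one result."""
    n_content, n_function = _role_counts(doc)
    density = lexical_density(doc)
    diversity = mtld(doc)
    warnings = []
    if density is UNDEFINED:
        warnings.append("lexical density undefined: text has no function words")
    if diversity is UNDEFINED:
        warnings.append(
            f"MTLD undefined: fewer than {MTLD_MIN_WORDS} words or no "
            "type-token decay"
        )
    return StyleResult(
        passive_flags=tuple(detect_passive(doc)),
        lexical_density=density,
        ttr=type_token_ratio(doc),
        mtld=diversity,
        n_content_words=n_content,
        n_function_words=n_function,
        warnings=tuple(warnings),
    )
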
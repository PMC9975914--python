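"""Report aggregation: run every assessment, resolve the highlight
hierarchy, and export the result as JSON or Markdown.

The pipeline is a pure function of (raw text, config, lexicon contents):
segment, apply preparation, run the six assessments, and collect global
scores plus every flag. Overlapping flags are displayed according to the
hierarchy — complex language and person-centered language over passive
voice over readability over structure — but all flags remain in the report.
Only the three highest-ranked assessments are active by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .complex_language import assess_complex_language
from .config import DEFAULT_ACTIVE, PrepConfig
from .flags import CATEGORIES, Flag
from .lexicons import LexiconSet
from .person_centered import flag_person_centered
from .readability import assess_readability
from .structure import assess_structure
from .style import assess_style
from .textprep import Document, prepare, word_count

GRADE_GUIDANCE = (
    "Aim for Grade 8 or lower. Some words will stay highlighted; the goal "
    "is to make the text as simple as possible, not to clear every flag."
)

EXPORT_FORMATS = ("json", "markdown")


@dataclass(frozen=True)
class SegmentInfo:
    index: int
    kind: str
    included: bool
    word_count: int
    text: str


@dataclass(frozen=True)
class AssessmentReport:
    raw_text: str
    smog_grade: int
    raw_smog: float
    n_included_sentences: int
    n_polysyllabic_words: int
    complexity_percent: float
    lexical_density: float | None
    ttr: float
    mtld: float | None
    n_content_words: int
    n_function_words: int
    flags: tuple[Flag, ...]
    flag_counts: dict[str, int]
    excluded_segments: tuple[SegmentInfo, ...]
    excluded_words: tuple[str, ...]
    active_assessments: tuple[str, ...]
    warnings: tuple[str, ...] = ()
    guidance: str = GRADE_GUIDANCE


@dataclass(frozen=True)
class DisplaySpan:
    """One non-overlapping highlight: a character run attributed to the
    highest-priority flag covering it."""

    char_start: int
    char_end: int
    category: str
    priority: int


def resolve_highlights(
    flags: list[Flag] | tuple[Flag, ...], active: frozenset[str] | set[str]
) -> list[DisplaySpan]:
    """Partition overlapping active-flag spans by the display hierarchy.

    Only flags whose assessment is in ``active`` are displayable. Each
    character in the union of their spans is attributed to the
    highest-priority overlapping flag (within the readability tier, word
    flags draw above sentence flags); the returned spans never overlap and
    their union equals the union of the active flag spans.
    """
    visible = [f for f in flags if f.assessment in active]
    if not visible:
        return []
    boundaries = sorted({b for f in visible for b in (f.char_start, f.char_end)})
    spans: list[DisplaySpan] = []
    for a, b in zip(boundaries, boundaries[1:]):
        covering = [f for f in visible if f.char_start <= a and b <= f.char_end]
        if not covering:
            continue
        best = min(covering, key=lambda f: (*f.display_rank, f.char_start))
        if (
            spans
            and spans[-1].char_end == a
            and spans[-1].category == best.category
        ):
            spans[-1] = DisplaySpan(
                spans[-1].char_start, b, best.category, best.priority
            )
        else:
            spans.append(DisplaySpan(a, b, best.category, best.priority))
    return spans


def _module(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        raise ValueError(f"{name}: {exc}") from exc


def run_all(
    raw: str, cfg: PrepConfig | None = None, lexicons: LexiconSet | None = None
) -> AssessmentReport:
    """Run the full assessment pipeline on raw text.

    Deterministic: identical input, config, and lexicon contents yield an
    identical report (and a byte-identical JSON export).
    """
    if lexicons is None:
        from .lexicons import load_bundled

        lexicons = load_bundled()
    cfg = cfg or PrepConfig()
    doc = _module("textprep", prepare, raw, cfg)
    if not doc.included_words():
        raise ValueError("no assessable text")

    readability = _module(
        "readability", assess_readability, doc, lexicons.syllables, cfg
    )
    complexity = _module(
        "complex_language",
        assess_complex_language,
        doc,
        list(lexicons.thesaurus),
        lexicons.frequency,
        cfg,
    )
    style_res = _module("style", assess_style, doc)
    structure_res = _module("structure", assess_structure, doc, cfg)
    person_flags = _module(
        "person_centered", flag_person_centered, doc, list(lexicons.person_centered)
    )

    all_flags = sorted(
        [
            *complexity.all_flags,
            *person_flags,
            *style_res.passive_flags,
            *readability.long_word_flags,
            *readability.long_sentence_flags,
            *structure_res.all_flags,
        ],
        key=lambda f: (f.char_start, f.char_end, f.category),
    )
    counts = {cat: 0 for cat in CATEGORIES}
    for f in all_flags:
        counts[f.category] += 1

    excluded = []
    for idx, sent in enumerate(doc.sentences()):
        if not sent.included:
            excluded.append(
                SegmentInfo(
                    index=idx,
                    kind=sent.kind,
                    included=False,
                    word_count=word_count(sent),
                    text=raw[sent.char_start : sent.char_end],
                )
            )

    return AssessmentReport(
        raw_text=raw,
        smog_grade=readability.smog_grade,
        raw_smog=readability.raw_smog,
        n_included_sentences=readability.n_included_sentences,
        n_polysyllabic_words=readability.n_polysyllabic_words,
        complexity_percent=complexity.complexity_percent,
        lexical_density=style_res.lexical_density,
        ttr=style_res.ttr,
        mtld=style_res.mtld,
        n_content_words=style_res.n_content_words,
        n_function_words=style_res.n_function_words,
        flags=tuple(all_flags),
        flag_counts=counts,
        excluded_segments=tuple(excluded),
        excluded_words=tuple(cfg.excluded_words),
        active_assessments=tuple(sorted(cfg.active_assessments)),
        warnings=tuple(readability.warnings) + tuple(style_res.warnings),
    )


# --- serialization -----------------------------------------------------------

def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "raw_text": report.raw_text,
        "scores": {
            "smog_grade": report.smog_grade,
            "raw_smog": report.raw_smog,
            "n_included_sentences": report.n_included_sentences,
            "n_polysyllabic_words": report.n_polysyllabic_words,
            "complexity_percent": report.complexity_percent,
            "lexical_density": report.lexical_density,
            "ttr": report.ttr,
            "mtld": report.mtld,
            "n_content_words": report.n_content_words,
            "n_function_words": report.n_function_words,
        },
        "flags": [
            {
                "category": f.category,
                "priority": f.priority,
                "char_start": f.char_start,
                "char_end": f.char_end,
                "message": f.message,
                "suggestions": list(f.suggestions),
            }
            for f in report.flags
        ],
        "flag_counts": report.flag_counts,
        "preparation": {
            "excluded_segments": [
                {
                    "index": s.index,
                    "kind": s.kind,
                    "word_count": s.word_count,
                    "text": s.text,
                }
                for s in report.excluded_segments
            ],
            "excluded_words": list(report.excluded_words),
        },
        "active_assessments": list(report.active_assessments),
        "warnings": list(report.warnings),
        "guidance": report.guidance,
    }


def report_from_dict(data: dict) -> AssessmentReport:
    scores = data["scores"]
    return AssessmentReport(
        raw_text=data["raw_text"],
        smog_grade=scores["smog_grade"],
        raw_smog=scores["raw_smog"],
        n_included_sentences=scores["n_included_sentences"],
        n_polysyllabic_words=scores["n_polysyllabic_words"],
        complexity_percent=scores["complexity_percent"],
        lexical_density=scores["lexical_density"],
        ttr=scores["ttr"],
        mtld=scores["mtld"],
        n_content_words=scores["n_content_words"],
        n_function_words=scores["n_function_words"],
        flags=tuple(
            Flag(
                category=f["category"],
                char_start=f["char_start"],
                char_end=f["char_end"],
                message=f["message"],
                suggestions=tuple(f["suggestions"]),
            )
            for f in data["flags"]
        ),
        flag_counts=dict(data["flag_counts"]),
        excluded_segments=tuple(
            SegmentInfo(
                index=s["index"],
                kind=s["kind"],
                included=False,
                word_count=s["word_count"],
                text=s["text"],
            )
            for s in data["preparation"]["excluded_segments"]
        ),
        excluded_words=tuple(data["preparation"]["excluded_words"]),
        active_assessments=tuple(data["active_assessments"]),
        warnings=tuple(data["warnings"]),
        guidance=data["guidance"],
    )


_SECTION_TITLES = {
    "complex_language": "Complex language",
    "passive_voice": "Passive voice",
    "readability": "Readability",
    "structure": "Text structure",
    "person_centered": "Person-centered language",
    "lexical": "Lexical density and diversity",
}

_ASSESSMENT_CATEGORIES = {
    "complex_language": ("thesaurus", "uncommon", "acronym"),
    "passive_voice": ("passive",),
    "readability": ("readability_word", "readability_sentence"),
    "structure": ("structure",),
    "person_centered": ("person_centered",),
    "lexical": (),
}


def _fmt(value: float | None, digits: int = 2) -> str:
    return "undefined" if value is None else f"{value:.{digits}f}"


def export_report(report: AssessmentReport, format: str = "json") -> str:
    """Render the report as schema-stable JSON or as Markdown."""
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if format == "markdown":
        return _export_markdown(report)
    raise ValueError(
        f"unknown export format {format!r}; supported formats: "
        + ", ".join(EXPORT_FORMATS)
    )


def _export_markdown(report: AssessmentReport) -> str:
    lines = [
        "# Health literacy assessment",
        "",
        f"> {report.guidance}",
        "",
        "## Global scores",
        "",
        "| Score | Value |",
        "| --- | --- |",
        f"| SMOG grade reading score | {report.smog_grade} |",
        f"| Text complexity | {report.complexity_percent:.1f}% |",
        f"| Lexical density (content:function) | {_fmt(report.lexical_density)} |",
        f"| Type-token ratio | {report.ttr:.3f} |",
        f"| MTLD | {_fmt(report.mtld, 1)} |",
        "",
    ]
    for assessment in report.active_assessments:
        if assessment not in _SECTION_TITLES:
            continue
        lines.append(f"## {_SECTION_TITLES[assessment]}")
        lines.append("")
        if assessment == "lexical":
            lines.append(
                f"Content words: {report.n_content_words}; function words: "
                f"{report.n_function_words}."
            )
            lines.append("")
            continue
        cats = _ASSESSMENT_CATEGORIES[assessment]
        section_flags = [f for f in report.flags if f.category in cats]
        if not section_flags:
            lines.append("No flags.")
        for f in section_flags:
            quote = report.raw_text[f.char_start : f.char_end].replace("\n", " ")
            if len(quote) > 60:
                quote = quote[:57] + "..."
            item = f'- "{quote}" — {f.message}'
            if f.suggestions:
                item += f" (try: {', '.join(f.suggestions)})"
            lines.append(item)
        lines.append("")
    lines.append("## Text preparation")
    lines.append("")
    if report.excluded_segments:
        lines.append("Segments excluded from score computations:")
        for s in report.excluded_segments:
            lines.append(
                f'- segment {s.index} ({s.kind}, {s.word_count} words): "{s.text}"'
            )
    else:
        lines.append("No segments were excluded.")
    if report.excluded_words:
        lines.append("")
        lines.append(
            "Words excluded from the complex language assessment: "
            + ", ".join(report.excluded_words)
        )
    if report.warnings:
        lines.append("")
        lines.append("## Warnings")
        lines.append("")
        for w in report.warnings:
            lines.append(f"- {w}")
    lines.append("")
    return "\n".join(lines)
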
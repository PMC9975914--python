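"""Closed-class word lists and morphology rules for the rule-based text engine.

The engine assigns coarse part-of-speech tags from membership in closed-class
lists plus suffix heuristics, lemmatizes with a small irregular table and
regular suffix stripping, and marks probable named entities with a gazetteer
and a capitalization heuristic. It is deliberately procedural: every decision
is a table lookup or a string rule, so behaviour is deterministic and
auditable.
"""

from __future__ import annotations

import re

# --- closed classes (all lowercase) -----------------------------------------

DETERMINERS = frozenset(
    """the a an this that these those each every some any no either neither
    another such much many few several all both half enough""".split()
)

PREPOSITIONS = frozenset(
    """in on at by with from to of about over under after before between
    during through into onto off near against without within across around
    among toward towards until upon per via since behind beyond above below
    along despite except inside outside throughout underneath versus""".split()
)

PRONOUNS = frozenset(
    """i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves yourselves themselves who whom whose someone anyone everyone
    somebody anybody everybody nobody something anything everything nothing
    one oneself""".split()
)

CONJUNCTIONS = frozenset(
    """and or but nor yet so because although though while whereas if unless
    when whenever wherever than as whether""".split()
)

AUXILIARIES = frozenset(
    """am is are was were be been being have has had having do does did will
    would shall should can could may might must ought got""".split()
)

BE_FORMS = frozenset("am is are was were be been being".split())

NEGATIONS = frozenset(["not", "never", "n't", "no"])

# Frequent adverbs that may sit between an auxiliary and a participle.
COMMON_ADVERBS = frozenset(
    """also often always usually sometimes just already recently now then
    really very too quite rather still soon later here there well
    first once again almost only even mostly largely generally""".split()
)

# Words ending in -ed that are not past participles.
ED_EXCEPTIONS = frozenset(
    """indeed need hundred naked wicked sacred hatred kindred jagged rugged
    wretched crooked dogged learned beloved aged blessed ragged""".split()
)

IRREGULAR_PARTICIPLES = frozenset(
    """given taken written done made seen known shown told found driven
    broken chosen eaten spoken stolen thrown worn drawn grown held kept left
    lost met paid put read said sent set sold spent taught thought understood
    born borne built bought brought caught cut dealt felt fought heard hidden
    hit hurt led lent meant sung swum won begun gone sworn torn woken frozen
    forgotten forgiven beaten bitten proven risen shaken fed bred laid lain
    slept swept wept fled spread shut struck stuck stung spun run become
    come overcome withdrawn mistaken undertaken sung hung sunk drunk""".split()
)

IRREGULAR_LEMMAS = {
    "written": "write", "wrote": "write",
    "given": "give", "gave": "give",
    "taken": "take", "took": "take",
    "seen": "see", "saw": "see",
    "done": "do", "did": "do",
    "made": "make",
    "known": "know", "knew": "know",
    "shown": "show",
    "told": "tell",
    "found": "find",
    "gone": "go", "went": "go",
    "said": "say",
    "thought": "think",
    "brought": "bring",
    "bought": "buy",
    "caught": "catch",
    "taught": "teach",
    "felt": "feel",
    "kept": "keep",
    "left": "leave",
    "held": "hold",
    "heard": "hear",
    "meant": "mean",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "mice": "mouse",
    "people": "people",
    "better": "good",
    "worse": "bad",
}

# Small gazetteer backing the named-entity heuristic: countries and other
# place/time names that appear in everyday health writing.
GAZETTEER = frozenset(
    """australia canada england america india china japan france germany
    italy spain brazil mexico ireland scotland wales zealand sydney melbourne
    brisbane perth adelaide london paris
    january february march april may june july august september october
    november december
    monday tuesday wednesday thursday friday saturday sunday
    english spanish french mandarin arabic hindi vietnamese greek italian
    john mary david sarah james emma michael anna peter lucy""".split()
)

# Sentence-splitting guard: a period directly after one of these does not end
# a sentence.
ABBREVIATIONS = frozenset(
    """dr mr mrs ms prof st vs etc eg ie e.g i.e no fig al approx dept""".split()
)

VOWELS = frozenset("aeiouy")

_ACRONYM_RE = re.compile(r"[A-Za-z.\-]+")


def looks_like_acronym(surface: str) -> bool:
    """True for a series of at least two capital letters, optionally with
    periods or lowercase letters in between (e.g. ``WHO``, ``U.S.``,
    ``SHeLL``)."""
    if sum(1 for c in surface if c.isupper()) < 2:
        return False
    return _ACRONYM_RE.fullmatch(surface) is not None


def is_participle_candidate(lower: str) -> bool:
    """True when a word form could be a past participle.

    Contextless test: irregular participles by table, regular ones by the
    ``-ed`` suffix with a vowel-bearing stem. Disambiguation from simple past
    is left to the passive matcher, which requires a preceding "to be" form.
    """
    if lower in IRREGULAR_PARTICIPLES:
        return True
    if lower in ED_EXCEPTIONS or lower in AUXILIARIES:
        return False
    if len(lower) >= 4 and lower.endswith("ed"):
        stem = lower[:-2]
        return any(c in VOWELS for c in stem)
    return False


def coarse_pos(lower: str, surface: str) -> str:
    """Coarse part-of-speech tag for a word token (closed-class lookup first,
    then suffix heuristics; open-class default is noun)."""
    if lower in DETERMINERS:
        return "determiner"
    if lower in AUXILIARIES:
        return "auxiliary"
    if lower in PREPOSITIONS:
        return "preposition"
    if lower in PRONOUNS:
        return "pronoun"
    if lower in CONJUNCTIONS:
        return "conjunction"
    if not any(c.isalpha() for c in surface):
        return "number" if any(c.isdigit() for c in surface) else "punctuation"
    if lower in NEGATIONS or lower in COMMON_ADVERBS or (
        lower.endswith("ly") and len(lower) > 3
    ):
        return "adverb"
    if is_participle_candidate(lower) or (
        len(lower) > 4 and lower.endswith("ing")
    ):
        return "verb"
    return "noun"


def lemma_of(lower: str, pos: str) -> str:
    """Rule-based lemma: irregular table, then regular suffix stripping for
    open-class words; closed-class words are their own lemma."""
    if lower in IRREGULAR_LEMMAS:
        return IRREGULAR_LEMMAS[lower]
    if pos not in ("noun", "verb", "adjective", "adverb"):
        return lower
    w = lower
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 4 and w.endswith("es") and w[-3] in "sxz":
        return w[:-2]
    if len(w) > 5 and w.endswith("es") and w[-4:-2] in ("ch", "sh"):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not w.endswith("ss") and not w.endswith("us"):
        return w[:-1]
    for suffix in ("ing", "ed"):
        if len(w) > len(suffix) + 2 and w.endswith(suffix):
            stem = w[: -len(suffix)]
            if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in VOWELS:
                stem = stem[:-1]  # running -> run
            if any(c in VOWELS for c in stem):
                return stem
    return w
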
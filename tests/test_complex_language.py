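"""Thesaurus, uncommon-word, and acronym detectors plus the complexity score."""

import random
import re

import pytest

from healthlit import (
    PrepConfig,
    complexity_score,
    detect_acronyms,
    detect_uncommon,
    match_thesaurus,
    prepare,
    set_excluded_words,
)
from healthlit._lang import looks_like_acronym


class TestExcludedWords:
    def test_cap_is_enforced(self, cfg):
        with pytest.raises(ValueError, match="5"):
            set_excluded_words(cfg, ["a", "b", "c", "d", "e", "f"])

    def test_five_words_allowed(self, cfg):
        out = set_excluded_words(cfg, ["One", "two", "three", "four", "five"])
        assert out.excluded_words == ("one", "two", "three", "four", "five")

    def test_empty_list_is_noop(self, cfg):
        assert set_excluded_words(cfg, []).excluded_words == ()

    def test_exclusion_suppresses_all_three_detectors(self, flex, cfg):
        raw = "You can obtain the GP letter and the sedge now."
        doc = prepare(raw)
        assert len(match_thesaurus(doc, list(flex.thesaurus), cfg)) == 1
        assert len(detect_acronyms(doc, cfg)) == 1
        assert len(detect_uncommon(doc, flex.frequency, cfg)) >= 1
        excl = set_excluded_words(cfg, ["obtain", "gp", "sedge"])
        assert match_thesaurus(doc, list(flex.thesaurus), excl) == []
        assert detect_acronyms(doc, excl) == []
        assert [
            f for f in detect_uncommon(doc, flex.frequency, excl)
            if doc.raw_text[f.char_start : f.char_end] == "sedge"
        ] == []

    def test_exclusion_is_monotone(self, flex, cfg):
        """Adding an excluded word never increases any flag count."""
        raw = "You must cease now and obtain help at the ED."
        doc = prepare(raw)
        counts = []
        current = cfg
        for words in ([], ["cease"], ["cease", "obtain"], ["cease", "obtain", "ed"]):
            current = set_excluded_words(cfg, list(words))
            counts.append(
                (
                    len(match_thesaurus(doc, list(flex.thesaurus), current)),
                    len(detect_acronyms(doc, current)),
                    len(detect_uncommon(doc, flex.frequency, current)),
                )
            )
        for before, after in zip(counts, counts[1:]):
            assert all(b >= a for b, a in zip(before, after))


class TestThesaurus:
    def test_match_carries_alternative(self, flex, cfg):
        doc = prepare("Please obtain a test kit.")
        (flag,) = match_thesaurus(doc, list(flex.thesaurus), cfg)
        assert flag.suggestions == ("get",)
        assert doc.raw_text[flag.char_start : flag.char_end] == "obtain"

    def test_no_overlap_no_flags(self, flex, cfg):
        doc = prepare("You can rest at home now.")
        assert match_thesaurus(doc, list(flex.thesaurus), cfg) == []

    def test_multiword_longest_pattern_wins(self, cfg):
        from healthlit import ThesaurusEntry

        entries = [
            ThesaurusEntry("prior", ("prior",), ("earlier",)),
            ThesaurusEntry("prior to", ("prior to",), ("before",)),
        ]
        doc = prepare("Fast prior to the test.")
        (flag,) = match_thesaurus(doc, entries, cfg)
        assert doc.raw_text[flag.char_start : flag.char_end] == "prior to"
        assert flag.suggestions == ("before",)

    def test_every_flag_has_alternative(self, flex, cfg):
        doc = prepare("You must cease now. Please obtain help. We assist you.")
        for flag in match_thesaurus(doc, list(flex.thesaurus), cfg):
            assert len(flag.suggestions) >= 1

    def test_match_is_case_insensitive(self, flex, cfg):
        doc = prepare("Cease all doses now.")
        assert len(match_thesaurus(doc, list(flex.thesaurus), cfg)) == 1


class TestAcronyms:
    @pytest.mark.parametrize(
        "token, expected",
        [
            ("WHO", True),
            ("SHeLL", True),  # internal lowercase allowed
            ("U.S.", True),  # periods in between
            ("A", False),  # needs at least 2 capitals
            ("Ab", False),
            ("GP", True),
            ("the", False),
        ],
    )
    def test_boundaries(self, token, expected, cfg):
        doc = prepare(f"We saw {token} again today.")
        hits = [
            doc.raw_text[f.char_start : f.char_end]
            for f in detect_acronyms(doc, cfg)
        ]
        assert (token in hits) is expected

    def test_matches_regex_oracle_on_random_strings(self, cfg):
        """Brute-force oracle over 1,000 random strings from the
        {uppercase, lowercase, period} alphabet."""
        oracle = re.compile(r"(?=(?:[^A-Z]*[A-Z]){2})[A-Za-z.]+")
        rng = random.Random(0)
        alphabet = "ABCDEFabcdef."
        for _ in range(1000):
            s = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 8)))
            assert looks_like_acronym(s) == bool(oracle.fullmatch(s)), s


class TestUncommon:
    def test_common_word_not_flagged(self, flex, cfg):
        doc = prepare("The team can help you now.")
        assert detect_uncommon(doc, flex.frequency, cfg) == []

    def test_named_entity_exempt(self, flex, cfg):
        doc = prepare("The team will help Canada now.")
        assert detect_uncommon(doc, flex.frequency, cfg) == []

    def test_rare_word_flagged(self, flex, cfg):
        doc = prepare("The team saw a borborygmus now.")
        hits = [
            doc.raw_text[f.char_start : f.char_end]
            for f in detect_uncommon(doc, flex.frequency, cfg)
        ]
        assert "borborygmus" in hits

    def test_acronyms_exempt_from_uncommon(self, flex, cfg):
        doc = prepare("Ask the GP about this plan.")
        assert detect_uncommon(doc, flex.frequency, cfg) == []


class TestComplexityScore:
    def test_arithmetic(self, flex, cfg):
        doc = prepare(" ".join(["word"] * 99 + ["obtain"]) + ".")
        thes = match_thesaurus(doc, list(flex.thesaurus), cfg)
        res = complexity_score(doc, thes, [], [])
        assert res.complexity_percent == pytest.approx(1.0)

    def test_no_flags_zero(self, flex, cfg):
        doc = prepare("You can rest at home now.")
        res = complexity_score(doc, [], [], [])
        assert res.complexity_percent == 0.0

    def test_double_flagged_token_counts_once(self, cfg):
        doc = prepare(" ".join(["word"] * 9 + ["zargon"]) + ".")
        tok = [t for t in doc.included_words() if t.lower == "zargon"][0]
        from healthlit import Flag

        f1 = Flag("thesaurus", tok.char_start, tok.char_end, "m", ("x",))
        f2 = Flag("uncommon", tok.char_start, tok.char_end, "m")
        res = complexity_score(doc, [f1], [f2], [])
        assert res.complexity_percent == pytest.approx(10.0)

    def test_zero_words_errors(self, flex):
        with pytest.raises(ValueError):
            complexity_score(prepare(""), [], [], [])

    def test_permutation_invariance(self, flex, cfg):
        a = "You must cease now. The GP can help. Rest at home today."
        b = "Rest at home today. You must cease now. The GP can help."
        def score(raw):
            doc = prepare(raw)
            return complexity_score(
                doc,
                match_thesaurus(doc, list(flex.thesaurus), cfg),
                detect_uncommon(doc, flex.frequency, cfg),
                detect_acronyms(doc, cfg),
            ).complexity_percent
        assert score(a) == pytest.approx(score(b))
        assert 0.0 <= score(a) <= 100.0
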
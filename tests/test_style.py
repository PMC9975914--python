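"""Passive voice, lexical density, TTR, and MTLD."""

import random

import pytest

from healthlit import (
    FixtureSpec,
    detect_passive,
    generate_fixture,
    lexical_density,
    mtld,
    prepare,
    type_token_ratio,
)
from healthlit.style import MTLD_THRESHOLD, classify_word_role


class TestPassive:
    def test_flags_passive_not_active(self):
        passive = prepare("the blood test was ordered by the doctor.")
        active = prepare("the doctor ordered the blood test.")
        assert len(detect_passive(passive)) == 1
        assert detect_passive(active) == []

    def test_flag_span_covers_construction(self):
        doc = prepare("the blood test was ordered by the doctor.")
        (flag,) = detect_passive(doc)
        assert doc.raw_text[flag.char_start : flag.char_end] == "was ordered"

    @pytest.mark.parametrize(
        "text, n",
        [
            ("she is happy.", 0),  # adjective, not participle
            ("the medicine was quickly delivered.", 1),  # one adverb between
            ("the dose was not really checked.", 1),  # two interveners
            ("the results are often carefully never reviewed.", 0),  # three
            ("the letter was given to you.", 1),  # irregular participle
            ("you were seen by the nurse and the plan was changed.", 2),
            ("we are being careful.", 0),
        ],
    )
    def test_patterns(self, text, n):
        assert len(detect_passive(prepare(text))) == n


class TestWordRoles:
    @pytest.mark.parametrize(
        "text, index, role",
        [
            ("the doctor", 0, "function"),  # determiner
            ("the doctor", 1, "content"),  # noun
            ("we do care", 1, "function"),  # auxiliary "do"
            ("she got help", 1, "function"),  # auxiliary "got"
            ("walk in slowly", 1, "function"),  # preposition
        ],
    )
    def test_classification(self, text, index, role):
        doc = prepare(text)
        words = [t for s in doc.sentences() for t in s.tokens if t.is_word]
        assert classify_word_role(words[index]) == role

    def test_non_word_raises(self):
        doc = prepare("stop.")
        punct = doc.sentences()[0].tokens[-1]
        with pytest.raises(ValueError):
            classify_word_role(punct)

    def test_roles_conserve_word_count(self):
        doc = prepare("The nurse will check your blood pressure at the clinic.")
        roles = [classify_word_role(t) for t in doc.included_words()]
        assert len(roles) == len(doc.included_words())
        assert set(roles) <= {"content", "function"}


class TestLexicalDensity:
    def test_five_to_one_ratio(self):
        # 5 content (smoking causes lung cancer people) : 1 function (in)
        doc = prepare("Smoking causes lung cancer in people.")
        assert lexical_density(doc) == pytest.approx(5.0)

    def test_six_to_four_ratio(self):
        # 6 content (nurse check blood pressure readings clinic)
        # : 4 function (the will at the)
        doc = prepare("The nurse will check blood pressure readings at the clinic.")
        assert lexical_density(doc) == pytest.approx(1.5)

    def test_no_function_words_is_undefined(self):
        assert lexical_density(prepare("dogs chase cats.")) is None

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            lexical_density(prepare(""))

    def test_spoken_style_below_nominalized_rewrite(self):
        spoken = prepare("You can ask us for help with your pain.")
        written = prepare("Patients must request assistance regarding pain management.")
        assert lexical_density(spoken) < lexical_density(written)


class TestDiversity:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("the cat and the dog.", 0.8),
            ("one two three four.", 1.0),
            ("no no no no.", 0.25),
        ],
    )
    def test_ttr(self, text, expected):
        assert type_token_ratio(prepare(text)) == pytest.approx(expected)

    def test_ttr_of_doubled_text_not_higher(self):
        text, _ = generate_fixture(FixtureSpec(seed=11))
        single = type_token_ratio(prepare(text))
        doubled = type_token_ratio(prepare(text + "\n\n" + text))
        assert doubled <= single

    def test_mtld_undefined_below_ten_words(self):
        assert mtld(prepare("one two three four five six seven eight.")) is None

    def test_mtld_reversal_invariance(self):
        text, _ = generate_fixture(FixtureSpec(seed=2))
        words = [t.lower for t in prepare(text).included_words()]
        from healthlit.style import _mtld_pass

        fwd = _mtld_pass(words, MTLD_THRESHOLD)
        doc_value = mtld(prepare(text))
        rev = _mtld_pass(words[::-1], MTLD_THRESHOLD)
        assert doc_value == pytest.approx((fwd + rev) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_mtld_matches_brute_force_oracle(self, seed):
        """Independent re-implementation of the factor count, written as a
        windowed scan over prefix types, must agree on generated fixtures."""

        def oracle_pass(words):
            factors = 0.0
            start = 0
            i = 0
            while i < len(words):
                seg = words[start : i + 1]
                ttr = len(set(seg)) / len(seg)
                if ttr < MTLD_THRESHOLD:
                    factors += 1.0
                    start = i + 1
                i += 1
            seg = words[start:]
            if seg:
                ttr = len(set(seg)) / len(seg)
                factors += (1.0 - ttr) / (1.0 - MTLD_THRESHOLD)
            return len(words) / factors if factors else None

        rng = random.Random(seed)
        spec = FixtureSpec(
            n_paragraphs=rng.randint(1, 3),
            sentences_per_paragraph=rng.randint(2, 5),
            words_per_sentence=rng.randint(5, 9),
            seed=seed,
        )
        text, _ = generate_fixture(spec)
        doc = prepare(text)
        words = [t.lower for t in doc.included_words()]
        fwd, rev = oracle_pass(words), oracle_pass(words[::-1])
        expected = None if fwd is None or rev is None else (fwd + rev) / 2
        result = mtld(doc)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)
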
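"""Syllable counting and SMOG grade computation."""

import math
import random

import pytest

from healthlit import (
    FixtureSpec,
    PrepConfig,
    count_syllables,
    flag_long_sentences,
    flag_long_words,
    generate_fixture,
    prepare,
    smog,
)
from healthlit.readability import SMOG_INTERCEPT, SMOG_SLOPE, SyllableLexicon


class TestCountSyllables:
    @pytest.mark.parametrize(
        "word, expected",
        [
            ("cat", 1),
            ("be", 1),  # terminal e is the only vowel
            ("gobbledygook", 4),
            ("cake", 1),  # silent terminal e
            ("gobble", 2),  # -le keeps its syllable
            ("rhythm", 1),  # y as vowel
        ],
    )
    def test_heuristic(self, word, expected):
        assert count_syllables(word, SyllableLexicon()) == expected

    def test_dictionary_overrides_heuristic(self):
        lex = SyllableLexicon({"science": 2})
        assert count_syllables("science", SyllableLexicon()) == 1  # heuristic wrong
        assert count_syllables("science", lex) == 2
        assert count_syllables("SCIENCE", lex) == 2  # case-insensitive

    def test_acronym_reads_one_syllable_per_letter(self):
        assert count_syllables("MRI", SyllableLexicon()) == 3
        assert count_syllables("U.S.", SyllableLexicon()) == 2

    def test_non_word_raises(self):
        with pytest.raises(ValueError):
            count_syllables("123", SyllableLexicon())

    def test_agrees_with_bundled_dictionary_entries(self):
        from healthlit.lexicons import load_bundled

        lex = load_bundled().syllables
        for word, n in lex.items():
            assert count_syllables(word, lex) == n


class TestSmog:
    def test_thirty_monosyllabic_sentences(self, flex):
        doc = prepare("Yes. " * 30)
        res = smog(doc, flex.syllables)
        assert res.n_included_sentences == 30
        assert res.n_polysyllabic_words == 0
        assert res.raw_smog == pytest.approx(3.1291)
        assert res.smog_grade == 3

    def test_thirty_sentences_thirty_polysyllables(self, flex):
        doc = prepare("Hospital staff can help. " * 30)
        res = smog(doc, flex.syllables)
        assert res.n_polysyllabic_words == 30
        assert res.raw_smog == pytest.approx(3.1291 + 1.0430 * math.sqrt(30))
        assert res.smog_grade == 9

    def test_empty_document_raises(self, flex):
        with pytest.raises(ValueError, match="no assessable text"):
            smog(prepare(""), flex.syllables)

    def test_few_sentences_warns(self, flex):
        res = smog(prepare("You can rest now."), flex.syllables)
        assert res.warnings

    def test_adding_polysyllable_never_decreases_raw(self, flex):
        base = smog(prepare("You can rest now. " * 12), flex.syllables)
        more = smog(
            prepare("You can rest now. " * 11 + "Hospital care can help you now."),
            flex.syllables,
        )
        assert more.raw_smog >= base.raw_smog

    def test_sentence_permutation_invariance(self, flex):
        rng = random.Random(7)
        text, _ = generate_fixture(FixtureSpec(n_polysyllabic=4, seed=3))
        sentences = text.replace("\n\n", " ").split(". ")
        shuffled = list(sentences)
        rng.shuffle(shuffled)
        a = smog(prepare(". ".join(sentences)), flex.syllables)
        b = smog(prepare(". ".join(shuffled)), flex.syllables)
        assert a.raw_smog == pytest.approx(b.raw_smog)

    def test_self_concatenation_invariance(self, flex):
        text, _ = generate_fixture(FixtureSpec(n_polysyllabic=3, seed=5))
        single = smog(prepare(text), flex.syllables)
        double = smog(prepare(text + "\n\n" + text), flex.syllables)
        assert double.raw_smog == pytest.approx(single.raw_smog)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_formula_on_planted_tallies(self, seed, flex):
        """Closed-form oracle: the grade must equal the SMOG formula applied
        to the generator's independently planted polysyllable/sentence
        tallies."""
        rng = random.Random(seed)
        spec = FixtureSpec(
            n_paragraphs=rng.randint(1, 3),
            sentences_per_paragraph=rng.randint(2, 6),
            words_per_sentence=rng.randint(5, 10),
            n_polysyllabic=rng.randint(0, 5),
            seed=seed,
        )
        if spec.n_polysyllabic > spec.n_paragraphs * spec.sentences_per_paragraph:
            spec = FixtureSpec(seed=seed, n_polysyllabic=2)
        text, truth = generate_fixture(spec)
        res = smog(prepare(text), flex.syllables)
        expected_raw = SMOG_INTERCEPT + SMOG_SLOPE * math.sqrt(
            truth.n_polysyllabic * 30 / truth.n_sentences
        )
        assert res.n_polysyllabic_words == truth.n_polysyllabic
        assert res.n_included_sentences == truth.n_sentences
        assert res.raw_smog == pytest.approx(expected_raw)
        assert res.smog_grade == math.floor(expected_raw + 0.5)


class TestReadabilityFlags:
    def test_long_word_flagged_short_word_not(self, flex):
        from healthlit.lexicons import load_bundled

        lex = load_bundled().syllables
        doc = prepare("The information sheet lists your blood test results.")
        flagged = {f.char_start for f in flag_long_words(doc, lex)}
        assert doc.raw_text[4:15] == "information"
        assert 4 in flagged  # "information", 4 syllables
        surfaces = [
            doc.raw_text[f.char_start : f.char_end] for f in flag_long_words(doc, lex)
        ]
        assert "blood" not in surfaces

    def test_excluded_heading_not_flagged(self, flex):
        from healthlit.lexicons import load_bundled

        lex = load_bundled().syllables
        doc = prepare("Consultation details")
        assert doc.sentences()[0].included is False
        assert flag_long_words(doc, lex) == []

    def test_long_sentence_boundary(self, cfg, flex):
        doc21 = prepare(" ".join(["word"] * 21) + ".")
        assert sum(len(s.words) for s in doc21.sentences()) == 21
        assert len(flag_long_sentences(doc21, cfg)) == 1
        doc20 = prepare(" ".join(["word"] * 20) + ".")
        assert sum(len(s.words) for s in doc20.sentences()) == 20
        assert flag_long_sentences(doc20, cfg) == []

    def test_excluded_bullet_never_flagged_long(self, cfg):
        words = " ".join(["word"] * 25)
        doc = prepare(f"• {words}", PrepConfig(segment_overrides={0: False}))
        assert flag_long_sentences(doc, cfg) == []
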
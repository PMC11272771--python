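import itertools

import pytest
from hypothesis import given, strategies as st

from apephon.coding import (
    CodedUtterance,
    CodingScheme,
    RawTranscription,
    Syllable,
    UnparseableError,
    code,
    map_slots,
    normalize_text,
    syllabify,
)

from oracle_coding import oracle_code


def _raw(text):
    return RawTranscription(listener_id="L1", utterance_id="u1", text=text)


def _slots(result: CodedUtterance):
    return (result.c1, result.v1, result.c2, result.v2)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Ma-Ma!", "ma-ma"),
            ("mamma", "mama"),
            ("", ""),
            ("MÁMÁ", "mama"),  # diacritics fold to base letters
            ("ma  ma", "ma ma"),
            ("ma - ma", "ma-ma"),
            ("ma2ma?!", "mama"),  # digits and punctuation dropped
            ("nnyaa", "nyaa"),  # consonant geminates collapse, vowel pairs survive
            ("--mama--", "mama"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_text(raw) == expected

    @given(st.text(max_size=30))
    def test_idempotent(self, text):
        once = normalize_text(text)
        assert normalize_text(once) == once


class TestSyllabify:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("ma-ma", [("m", "a", ""), ("m", "a", "")]),
            ("mama", [("m", "a", ""), ("m", "a", "")]),
            ("ash-ma-ma", [("", "a", "sh"), ("m", "a", ""), ("m", "a", "")]),
            ("homo-mo", [("h", "o", ""), ("m", "o", ""), ("m", "o", "")]),
            ("fnaya", [("fn", "a", ""), ("y", "a", "")]),
            ("maima", [("m", "ai", ""), ("m", "a", "")]),
            ("my", [("m", "y", "")]),  # y as nucleus of last resort
            ("kuma-mao", [("k", "u", ""), ("m", "a", ""), ("m", "ao", "")]),
        ],
    )
    def test_examples(self, text, expected):
        got = [(s.onset, s.nucleus, s.coda) for s in syllabify(text)]
        assert got == expected

    def test_no_vowel_is_unparseable(self):
        with pytest.raises(UnparseableError):
            syllabify("pfft")

    def test_intervocalic_consonants_maximize_onset(self):
        # without phonotactic constraints every medial consonant joins the
        # next onset, deterministically
        got = [(s.onset, s.nucleus) for s in syllabify("mampa")]
        assert got == [("m", "a"), ("mp", "a")]


class TestMapSlots:
    def test_plain_mama(self):
        syls = (Syllable("m", "a"), Syllable("m", "a"))
        assert map_slots(syls) == ("m", "a", "m", "a")

    def test_cluster_kept_whole(self):
        syls = (Syllable("fn", "a"), Syllable("y", "a"))
        assert map_slots(syls)[0] == "fn"

    def test_diphthong_single_label(self):
        syls = (Syllable("m", "ai"), Syllable("m", "a"))
        assert map_slots(syls)[1] == "ai"

    def test_vowel_initial_marker(self):
        syls = (Syllable("", "a"), Syllable("m", "a"))
        assert map_slots(syls)[0] == "V"

    def test_requires_two_syllables(self):
        with pytest.raises(ValueError):
            map_slots((Syllable("m", "a"),))


class TestCode:
    def test_spelling_equivalence_class(self, strict_scheme, relabeled_scheme):
        for scheme in (strict_scheme, relabeled_scheme):
            results = {_slots(code(_raw(t), scheme)) for t in ("mama", "ma-ma", "mamma")}
            assert results == {("m", "a", "m", "a")}

    def test_real_word_excluded_under_both(self, strict_scheme, relabeled_scheme):
        for scheme in (strict_scheme, relabeled_scheme):
            r = code(_raw("my house"), scheme)
            assert r.na_reason == "real_word"
            assert _slots(r) == (None, None, None, None)

    def test_three_syllables_strict_vs_relabeled(self, strict_scheme, relabeled_scheme):
        strict = code(_raw("Homo-mo"), strict_scheme)
        assert strict.na_reason == "wrong_syllable_count"
        relab = code(_raw("Homo-mo"), relabeled_scheme)
        assert _slots(relab) == ("m", "o", "m", "o")
        assert relab.relabeled

    def test_five_syllables_na_under_both(self, strict_scheme, relabeled_scheme):
        for scheme in (strict_scheme, relabeled_scheme):
            assert code(_raw("ma-ma-ma-ma-ma"), scheme).na_reason == "wrong_syllable_count"

    def test_one_syllable_na(self, strict_scheme):
        assert code(_raw("ma"), strict_scheme).na_reason == "wrong_syllable_count"

    def test_empty_and_unparseable(self, strict_scheme):
        assert code(_raw(""), strict_scheme).na_reason == "empty"
        assert code(_raw("123?!"), strict_scheme).na_reason == "empty"
        assert code(_raw("pfft"), strict_scheme).na_reason == "unparseable"

    def test_relabeled_flag_only_for_3_4_syllables(self, relabeled_scheme):
        assert not code(_raw("mama"), relabeled_scheme).relabeled
        assert code(_raw("ku-ash-ma-ma"), relabeled_scheme).relabeled

    @given(st.text(alphabet="mahou -y", max_size=12))
    def test_scheme_monotonicity(self, lexicon, text):
        """Relabeling can only rescue responses: NA(relabeled) is a subset of NA(strict)."""
        strict = code(_raw(text), CodingScheme("strict", lexicon))
        relab = code(_raw(text), CodingScheme("relabeled", lexicon))
        if strict.na_reason == "none":
            assert relab.na_reason == "none"
            assert _slots(relab) == _slots(strict)

    @given(st.text(alphabet="mnah", min_size=1, max_size=8))
    def test_disyllabic_stability(self, text):
        """For any 2-syllable response the two schemes code identically."""
        strict = code(_raw(text), CodingScheme("strict"))
        relab = code(_raw(text), CodingScheme("relabeled"))
        if strict.na_reason == "none" and not relab.relabeled:
            assert _slots(strict) == _slots(relab)


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["strict", "relabeled"])
    def test_exhaustive_small_alphabet(self, variant):
        """code() agrees with the brute-force rule enumerator on all strings
        of length <= 4 over {m, a, o, h} (the acceptance run extends to 6)."""
        scheme = CodingScheme(variant)
        for n in range(1, 5):
            for letters in itertools.product("maoh", repeat=n):
                text = "".join(letters)
                r = code(_raw(text), scheme)
                got = (r.c1, r.v1, r.c2, r.v2, r.na_reason, r.relabeled)
                assert got == oracle_code(text, variant), text
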
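"""Feature extraction: counts, proportions, lexical and keyboard predictors."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from typability import (
    ATTRIBUTE_MAP,
    CANDIDATE_VARIABLES,
    TextItem,
    extract_features,
)
from typability.features import (
    char_class_profile,
    count_syllables,
    mean_bigram_frequency,
    prop_high_frequency_words,
    prop_nonword_characters,
    prop_right_side,
    words_nominal,
    words_whitespace,
)


@pytest.mark.parametrize(
    "word,expected",
    [
        ("", 0),
        ("cat", 1),
        ("sending", 2),
        ("the", 1),
        ("people", 2),  # lexicon entry: silent-e rule alone would miscount
        ("strength", 1),
        ("banana", 3),
        ("make", 1),  # silent final e
        ("little", 2),  # consonant-le keeps its syllable
        ("42", 0),
    ],
)
def test_count_syllables(word, expected, resources):
    assert count_syllables(word, resources) == expected


@pytest.mark.parametrize(
    "text,expected", [("", 0.0), ("hello", 1.0), ("Thanks for sending this.", 4.8)]
)
def test_words_nominal(text, expected):
    assert words_nominal(text) == pytest.approx(expected)


@pytest.mark.parametrize(
    "text,expected", [("", 0), ("Thanks for sending this.", 4), ("a  b", 2), ("  ", 0)]
)
def test_words_whitespace(text, expected):
    assert words_whitespace(text) == expected


class TestCharClassProfile:
    def test_homogeneous(self):
        profile = char_class_profile("abc")
        assert profile.prop_all["lowercase"] == 1.0

    def test_hand_counted_sentence(self):
        profile = char_class_profile("Thanks for sending this.")
        assert profile.prop_nonspace["lowercase"] == pytest.approx(19 / 21)
        assert profile.counts["uppercase"] == 1
        assert profile.counts["punctuation"] == 1
        assert profile.counts["space"] == 3

    def test_apostrophe_is_symbol(self):
        profile = char_class_profile("I'm")
        assert profile.prop_nonspace["symbol"] == pytest.approx(1 / 3)

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            char_class_profile("")


class TestMeanBigramFrequency:
    def test_single_pair_equals_table_entry(self, resources):
        value, n = mean_bigram_frequency("th", resources)
        assert n == 1
        assert value == resources.bigram_freq[("t", "h")]

    def test_mean_of_two_lookups(self, resources):
        value, n = mean_bigram_frequency("the", resources)
        expected = (resources.bigram_freq[("t", "h")] + resources.bigram_freq[("h", "e")]) / 2
        assert n == 2
        assert value == pytest.approx(expected)

    def test_no_letter_pair_flagged(self, resources):
        assert mean_bigram_frequency("a b", resources) == (0.0, 0)

    def test_pairs_do_not_span_nonletters(self, resources):
        # "o, t" has no adjacent letter-letter pair around the comma
        _, n = mean_bigram_frequency("go to", resources)
        assert n == 2  # 'go' and 'to' only; the space breaks the middle pair


@pytest.mark.parametrize(
    "text,expected",
    [("the", 1.0), ("the zyzzyva", 0.5), ("Zyzzyva!", 0.0), ("The THE the.", 1.0)],
)
def test_prop_high_frequency_words(text, expected, resources):
    assert prop_high_frequency_words(text, resources) == pytest.approx(expected)


def test_prop_high_frequency_words_requires_tokens(resources):
    with pytest.raises(ValueError):
        prop_high_frequency_words("   ", resources)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("the cat sat", 0.0),
        ("xyzzy cat", 5 / 9),
        ("42", 0.0),  # purely numeric tokens are not non-words
        ("I'll go", 0.0),  # contraction resolved via the dictionary
    ],
)
def test_prop_nonword_characters(text, expected, resources):
    proportion, _ = prop_nonword_characters(text, resources)
    assert proportion == pytest.approx(expected)


@pytest.mark.parametrize("text,expected", [("jkl", 1.0), ("fff", 0.0), ("fj", 0.5), ("f j", 0.5)])
def test_prop_right_side(text, expected, layout):
    assert prop_right_side(text, layout) == pytest.approx(expected)


class TestExtractFeatures:
    def test_hand_counted_fixture(self, layout, resources):
        fv = extract_features(TextItem("t1", "Thanks for sending this."), layout, resources)
        assert fv.total_keystrokes == 25
        assert fv.words_nominal == pytest.approx(4.8)
        assert fv.lowercase_prop_nonspace == pytest.approx(19 / 21)
        assert fv.punctuation_count == 1
        assert fv.uppercase_count == 1
        assert fv.syllables_per_word == pytest.approx(5 / 4.8)

    def test_keystrokes_per_word_ratio(self, layout, resources):
        fv = extract_features(TextItem("t2", "aaaaa"), layout, resources)
        assert fv.keystrokes_per_word == pytest.approx(5.0)

    def test_deterministic(self, layout, resources):
        item = TextItem("t3", "The wind was strong and gusting.")
        assert extract_features(item, layout, resources) == extract_features(item, layout, resources)

    def test_error_carries_item_id(self, layout, resources):
        with pytest.raises(Exception, match="bad_item"):
            extract_features(TextItem("bad_item", "café"), layout, resources)

    def test_roster_is_30_variables_over_17_attributes(self):
        assert len(CANDIDATE_VARIABLES) == 30
        assert len(set(CANDIDATE_VARIABLES)) == 30
        assert len(ATTRIBUTE_MAP) == 17


@given(text=st.text(alphabet="abcXYZ019 ,.!?';", min_size=1, max_size=60).filter(str.strip))
def test_nonspace_proportions_sum_to_one(text, layout, resources):
    fv = extract_features(TextItem("p", text), layout, resources)
    total = (
        fv.lowercase_prop_nonspace
        + fv.uppercase_prop_nonspace
        + fv.digit_prop_nonspace
        + fv.symbol_prop_nonspace
    )
    if fv.total_chars > fv.space_count:  # at least one non-space character
        assert math.isclose(total, 1.0, abs_tol=1e-12)
    # the four bigram-class proportions also partition the letter pairs
    if fv.bigram_pair_count:
        class_total = (
            fv.bigram_char_repeat_prop
            + fv.bigram_finger_repeat_prop
            + fv.bigram_hand_repeat_prop
            + fv.bigram_hand_alternate_prop
        )
        assert math.isclose(class_total, 1.0, abs_tol=1e-12)


@given(text=st.text(alphabet="abc ", min_size=1, max_size=30).filter(str.strip))
def test_appending_word_adds_one_token(text, layout, resources):
    base = extract_features(TextItem("p", text), layout, resources)
    extended = extract_features(TextItem("p", text + " cat"), layout, resources)
    assert extended.words_whitespace == base.words_whitespace + 1


@given(text=st.text(alphabet="abcdefgh ", min_size=1, max_size=40).filter(lambda s: any(c.isalpha() for c in s)))
def test_uppercasing_one_letter_adds_one_keystroke(text, layout, resources):
    base = extract_features(TextItem("p", text), layout, resources)
    idx = next(i for i, c in enumerate(text) if c.isalpha())
    upped = text[:idx] + text[idx].upper() + text[idx + 1 :]
    assert (
        extract_features(TextItem("p", upped), layout, resources).total_keystrokes
        == base.total_keystrokes + 1
    )


def _naive_profile(text, layout):
    """Independent single-pass oracle for the count/proportion features."""
    lower = sum(c.islower() for c in text)
    upper = sum(c.isupper() for c in text)
    digit = sum(c.isdigit() for c in text)
    space = text.count(" ")
    symbol = len(text) - lower - upper - digit - space
    keystrokes = len(text) + sum(layout.lookup(c)[1] for c in text)
    nonspace = len(text) - space
    return {
        "lowercase_count": lower,
        "uppercase_count": upper,
        "digit_count": digit,
        "symbol_count": symbol,
        "space_count": space,
        "total_chars": len(text),
        "total_keystrokes": keystrokes,
        "words_nominal": len(text) / 5,
        "words_whitespace": len(text.split()),
        "lowercase_prop_nonspace": lower / nonspace if nonspace else 0.0,
        "symbol_prop_all": symbol / len(text),
    }


def test_extract_features_matches_naive_oracle(layout, resources):
    import random

    rng = random.Random(7)
    alphabet = "abcdefghij XYZ019,.!?'"
    for _ in range(1000):
        text = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 50)))
        if not text.strip():
            continue
        fv = extract_features(TextItem("r", text), layout, resources)
        for key, expected in _naive_profile(text, layout).items():
            assert getattr(fv, key) == pytest.approx(expected), (key, text)
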
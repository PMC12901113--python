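"""Candidate predictor extraction for text items.

Computes every candidate predictor of typing difficulty for one text item:
character-class composition (with proportions over all characters and over
non-space characters), keystroke counts, word counts (nominal,
characters / 5, and whitespace-run), syllables per word, high-frequency
word proportion, non-word character proportion, mean English letter-bigram
frequency, right-side key proportion, mean distance from the home row, and
the four bigram hand-class proportions.

The full roster holds 30 candidate variables over 17 text/key attributes;
several attributes carry multiple calculation variants (e.g. proportion of
all characters vs. of non-space characters) and the training pipeline
selects the most explanatory variant per attribute.  The roster is a
reconstruction: the exact operationalisation used to fit the published
index is not fully printed, so :data:`ATTRIBUTE_MAP` is the single source
of truth here.

Word-list, bigram and syllable resources are compact plain-text tables
packaged with the library (built for this package; they are deliberately
small stand-ins for full corpus resources) and can be replaced by the user
via the :class:`ResourceBundle` loaders.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dataclass_fields
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .keyboard import (
    KeyboardLayout,
    UnsupportedCharacterError,
    default_layout,
    expand_keystrokes,
)

__all__ = [
    "TextItem",
    "ResourceBundle",
    "FeatureVector",
    "ATTRIBUTE_MAP",
    "CANDIDATE_VARIABLES",
    "default_resources",
    "count_syllables",
    "words_nominal",
    "words_whitespace",
    "char_class_profile",
    "mean_bigram_frequency",
    "prop_high_frequency_words",
    "prop_nonword_characters",
    "prop_right_side",
    "mean_home_row_distance",
    "extract_features",
    "features_to_frame",
    "read_stimulus_file",
]

#: punctuation characters tracked as a sub-count of the symbol class
PUNCTUATION = set(",.!?';:")

_VOWELS = set("aeiouy")


@dataclass(frozen=True)
class TextItem:
    """One stimulus string with an identifier."""

    item_id: str
    text: str

    def __post_init__(self):
        if not self.text:
            raise ValueError(f"item {self.item_id!r}: text must be non-empty")
        if any(not (c.isprintable() or c == " ") for c in self.text):
            raise ValueError(f"item {self.item_id!r}: text contains non-printable characters")


class ResourceBundle:
    """Lexical resources used by the feature extractor.

    Parameters
    ----------
    high_freq_words
        Exactly 1,000 lowercase words, most frequent first.
    bigram_freq
        ``(first_letter, second_letter) -> frequency``; must cover all
        26 x 26 lowercase letter pairs (zeros allowed).
    dictionary
        Set of lowercase English words (union of US/UK/CA/AU spellings).
    syllable_lexicon
        ``word -> syllable count`` for words where the rule-based counter
        is unreliable.
    metadata
        Free-form provenance notes; the bigram frequency scale is recorded
        here because linear-index coefficients are scale-bound.
    """

    def __init__(
        self,
        high_freq_words: list[str],
        bigram_freq: Mapping[tuple[str, str], float],
        dictionary: set[str],
        syllable_lexicon: Mapping[str, int],
        metadata: dict | None = None,
    ):
        if len(high_freq_words) != 1000:
            raise ValueError(f"high_freq_words must have exactly 1,000 entries, got {len(high_freq_words)}")
        missing = 26 * 26 - sum(
            (a, b) in bigram_freq
            for a in "abcdefghijklmnopqrstuvwxyz"
            for b in "abcdefghijklmnopqrstuvwxyz"
        )
        if missing:
            raise ValueError(f"bigram_freq must cover all 26x26 letter pairs ({missing} missing)")
        self.high_freq_words = [w.casefold() for w in high_freq_words]
        self.high_freq_set = frozenset(self.high_freq_words)
        self.bigram_freq = dict(bigram_freq)
        self.dictionary = {w.casefold() for w in dictionary}
        self.syllable_lexicon = {w.casefold(): int(n) for w, n in syllable_lexicon.items()}
        self.metadata = metadata or {}

    @classmethod
    def from_paths(
        cls,
        high_freq_path: str | Path,
        bigram_path: str | Path,
        dictionary_path: str | Path,
        syllable_path: str | Path,
        metadata: dict | None = None,
    ) -> "ResourceBundle":
        def read_words(p):
            return [
                line.strip()
                for line in Path(p).read_text(encoding="utf-8").splitlines()
                if line.strip() and not line.startswith("#")
            ]

        bigrams = {}
        for line in Path(bigram_path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            a, b, v = line.split("\t")
            bigrams[(a, b)] = float(v)
        lexicon = {}
        for line in Path(syllable_path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            w, n = line.split("\t")
            lexicon[w] = int(n)
        meta = {"bigram_scale": "per million bigram occurrences"}
        meta.update(metadata or {})
        return cls(read_words(high_freq_path), bigrams, set(read_words(dictionary_path)), lexicon, meta)


_DEFAULT_RESOURCES: ResourceBundle | None = None


def default_resources() -> ResourceBundle:
    """The packaged resource bundle (cached)."""
    global _DEFAULT_RESOURCES
    if _DEFAULT_RESOURCES is None:
        root = _importlib_resources.files("typability.resources")
        with _importlib_resources.as_file(root) as base:
            _DEFAULT_RESOURCES = ResourceBundle.from_paths(
                base / "top1000_words.txt",
                base / "bigram_freq.tsv",
                base / "dictionary_words.txt",
                base / "syllables.tsv",
            )
    return _DEFAULT_RESOURCES


# --------------------------------------------------------------------------
# tokenisation helpers

_TOKEN_RE = re.compile(r"\S+")


def _tokens(text: str) -> list[str]:
    """Maximal non-space runs, in order."""
    return _TOKEN_RE.findall(text)


def _strip_token(token: str) -> str:
    """Case-folded token with leading/trailing non-letters removed.

    Internal apostrophes survive ("I'll" -> "i'll"); a token with no
    letters strips to the empty string.
    """
    token = token.casefold()
    start, end = 0, len(token)
    while start < end and not token[start].isalpha():
        start += 1
    while end > start and not token[end - 1].isalpha():
        end -= 1
    return token[start:end]


def _in_dictionary(core: str, resources: ResourceBundle) -> bool:
    """Dictionary membership, trying the whole token then the apostrophe-free stem."""
    if core in resources.dictionary:
        return True
    if "'" in core:
        stem = core.split("'", 1)[0]
        return bool(stem) and stem in resources.dictionary
    return False


# --------------------------------------------------------------------------
# elementary operations


def count_syllables(word: str, resources: ResourceBundle | None = None) -> int:
    """Syllables in one word: lexicon lookup, else a rule-based count.

    The fallback counts vowel groups (a e i o u y), drops a silent final
    'e' (but keeps consonant-'le' as a syllable) and never returns less
    than 1 for a word containing a letter.  Words with no letters count 0.
    """
    resources = resources or default_resources()
    core = _strip_token(word)
    if not core:
        return 0
    if core in resources.syllable_lexicon:
        return resources.syllable_lexicon[core]
    letters = "".join(c for c in core if c.isalpha())
    if not letters:
        return 0
    groups = len(re.findall(r"[aeiouy]+", letters))
    if letters.endswith("e") and not letters.endswith(("le", "ee")) and groups > 1:
        groups -= 1
    return max(groups, 1)


def words_nominal(text: str) -> float:
    """Nominal word count: characters (including spaces) divided by 5."""
    return len(text) / 5.0


def words_whitespace(text: str) -> int:
    """Word count as the number of maximal non-space runs."""
    return len(_tokens(text))


@dataclass(frozen=True)
class CharClassProfile:
    """Character-class composition with both proportion denominators."""

    counts: dict[str, int]  # lowercase/uppercase/digit/symbol/space (+ punctuation sub-count)
    prop_all: dict[str, float]
    prop_nonspace: dict[str, float]
    total_chars: int
    nonspace_chars: int


def char_class_profile(text: str) -> CharClassProfile:
    """Assign every character to one class and compute both proportion variants.

    Classes are lowercase, uppercase, digit, symbol (any other non-space
    character) and space; punctuation is tracked as a sub-count of symbol.
    """
    if not text:
        raise ValueError("char_class_profile requires non-empty text")
    counts = {"lowercase": 0, "uppercase": 0, "digit": 0, "symbol": 0, "space": 0, "punctuation": 0}
    for c in text:
        if c == " ":
            counts["space"] += 1
        elif c.islower():
            counts["lowercase"] += 1
        elif c.isupper():
            counts["uppercase"] += 1
        elif c.isdigit():
            counts["digit"] += 1
        else:
            counts["symbol"] += 1
            if c in PUNCTUATION:
                counts["punctuation"] += 1
    total = len(text)
    nonspace = total - counts["space"]
    classes = ("lowercase", "uppercase", "digit", "symbol", "punctuation", "space")
    prop_all = {k: counts[k] / total for k in classes}
    prop_nonspace = {
        k: (counts[k] / nonspace if nonspace else 0.0) for k in classes if k != "space"
    }
    return CharClassProfile(counts, prop_all, prop_nonspace, total, nonspace)


def _letter_pairs(text: str) -> list[tuple[str, str]]:
    """Adjacent case-folded letter-letter pairs; pairs spanning a non-letter are excluded."""
    folded = text.casefold()
    return [
        (folded[i], folded[i + 1])
        for i in range(len(folded) - 1)
        if folded[i].isalpha() and folded[i + 1].isalpha()
    ]


def mean_bigram_frequency(
    text: str, resources: ResourceBundle | None = None
) -> tuple[float, int]:
    """Mean English-frequency of the text's letter bigrams.

    Returns ``(mean, n_pairs)``; a text with no adjacent letter pair
    returns ``(0.0, 0)`` so callers can flag the degenerate case.
    """
    resources = resources or default_resources()
    pairs = _letter_pairs(text)
    if not pairs:
        return 0.0, 0
    values = [resources.bigram_freq.get(p, 0.0) for p in pairs]
    return sum(values) / len(values), len(pairs)


def prop_high_frequency_words(text: str, resources: ResourceBundle | None = None) -> float:
    """Proportion of whitespace tokens found in the top-1,000 word list."""
    resources = resources or default_resources()
    tokens = _tokens(text)
    if not tokens:
        raise ValueError("prop_high_frequency_words requires at least one token")
    hits = sum(_strip_token(t) in resources.high_freq_set for t in tokens)
    return hits / len(tokens)


def prop_nonword_characters(text: str, resources: ResourceBundle | None = None) -> tuple[float, int]:
    """Proportion of characters inside non-word tokens, and the non-word count.

    A token is a non-word iff its stripped, case-folded form contains
    letters and is absent from the dictionary (whole token, then the
    apostrophe-free stem).  Purely numeric or letter-free tokens are never
    non-words.  The proportion denominator is the total character count,
    including spaces.
    """
    if not text:
        raise ValueError("prop_nonword_characters requires non-empty text")
    resources = resources or default_resources()
    nonword_chars = 0
    nonword_count = 0
    for token in _tokens(text):
        core = _strip_token(token)
        if core and not _in_dictionary(core, resources):
            nonword_chars += len(token)
            nonword_count += 1
    return nonword_chars / len(text), nonword_count


def prop_right_side(text: str, layout: KeyboardLayout | None = None) -> float:
    """Right-side keys as a proportion of non-neutral (non-space) characters."""
    layout = layout or default_layout()
    right = nonneutral = 0
    for pos, c in enumerate(text):
        rec, _ = layout.lookup(c, pos)
        if rec.side == "neutral":
            continue
        nonneutral += 1
        if rec.side == "right":
            right += 1
    return right / nonneutral if nonneutral else 0.0


def mean_home_row_distance(text: str, layout: KeyboardLayout | None = None) -> float:
    """Mean vertical row distance from the home row over all characters."""
    layout = layout or default_layout()
    if not text:
        raise ValueError("mean_home_row_distance requires non-empty text")
    total = 0
    for pos, c in enumerate(text):
        rec, _ = layout.lookup(c, pos)
        total += abs(rec.row - 2)
    return total / len(text)


# --------------------------------------------------------------------------
# the full feature vector


@dataclass(frozen=True)
class FeatureVector:
    """Named values of every candidate predictor for one text item."""

    item_id: str
    # character-class counts
    lowercase_count: int
    uppercase_count: int
    digit_count: int
    symbol_count: int
    punctuation_count: int
    space_count: int
    total_chars: int
    total_keystrokes: int
    # proportions (two denominators)
    lowercase_prop_all: float
    lowercase_prop_nonspace: float
    uppercase_prop_all: float
    uppercase_prop_nonspace: float
    digit_prop_all: float
    digit_prop_nonspace: float
    symbol_prop_all: float
    symbol_prop_nonspace: float
    punctuation_prop_all: float
    punctuation_prop_nonspace: float
    space_prop_all: float
    # word-level
    words_nominal: float
    words_whitespace: int
    keystrokes_per_word: float
    syllables_per_word: float
    prop_high_freq_words: float
    nonword_count: int
    prop_nonword_chars: float
    # keyboard-level
    mean_bigram_freq: float
    bigram_pair_count: int
    prop_right_side: float
    mean_home_row_distance: float
    # bigram hand classes
    bigram_char_repeat_count: int
    bigram_finger_repeat_count: int
    bigram_hand_repeat_count: int
    bigram_hand_alternate_count: int
    bigram_char_repeat_prop: float
    bigram_finger_repeat_prop: float
    bigram_hand_repeat_prop: float
    bigram_hand_alternate_prop: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self) if f.name != "item_id"}

    def __getitem__(self, name: str) -> float:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(name) from None


#: attribute -> calculation variants; 17 attributes, 30 candidate variables.
#: Multi-variant attributes are collapsed to their most explanatory variant
#: in Stage 1 of the training pipeline.
ATTRIBUTE_MAP: dict[str, tuple[str, ...]] = {
    "letter_case": (
        "lowercase_prop_all",
        "lowercase_prop_nonspace",
        "uppercase_count",
        "uppercase_prop_all",
        "uppercase_prop_nonspace",
    ),
    "digits": ("digit_count", "digit_prop_all", "digit_prop_nonspace"),
    "symbols_punctuation": (
        "symbol_prop_all",
        "symbol_prop_nonspace",
        "punctuation_count",
        "punctuation_prop_all",
        "punctuation_prop_nonspace",
    ),
    "spaces": ("space_count", "space_prop_all"),
    "total_keystrokes": ("total_keystrokes",),
    "total_words": ("words_nominal", "words_whitespace"),
    "keystrokes_per_word": ("keystrokes_per_word",),
    "syllables_per_word": ("syllables_per_word",),
    "word_frequency": ("prop_high_freq_words",),
    "nonwords": ("nonword_count", "prop_nonword_chars"),
    "bigram_frequency": ("mean_bigram_freq",),
    "right_side": ("prop_right_side",),
    "home_row_distance": ("mean_home_row_distance",),
    "bigram_char_repeat": ("bigram_char_repeat_prop",),
    "bigram_finger_repeat": ("bigram_finger_repeat_prop",),
    "bigram_hand_repeat": ("bigram_hand_repeat_prop",),
    "bigram_hand_alternate": ("bigram_hand_alternate_prop",),
}

#: the 30 candidate predictor variables, in roster order
CANDIDATE_VARIABLES: tuple[str, ...] = tuple(
    v for variants in ATTRIBUTE_MAP.values() for v in variants
)

#: variable -> attribute (inverse of ATTRIBUTE_MAP)
VARIABLE_ATTRIBUTE: dict[str, str] = {
    v: attr for attr, variants in ATTRIBUTE_MAP.items() for v in variants
}


def extract_features(
    item: TextItem,
    layout: KeyboardLayout | None = None,
    resources: ResourceBundle | None = None,
) -> FeatureVector:
    """Compute the full candidate predictor set for one text item."""
    layout = layout or default_layout()
    resources = resources or default_resources()
    text = item.text
    try:
        profile = char_class_profile(text)
        n_keystrokes, _ = expand_keystrokes(text, layout)
        w_nominal = words_nominal(text)
        w_ws = words_whitespace(text)
        syllables = sum(count_syllables(t, resources) for t in _tokens(text))
        hf = prop_high_frequency_words(text, resources)
        nonword_prop, nonword_n = prop_nonword_characters(text, resources)
        bigram_mean, n_pairs = mean_bigram_frequency(text, resources)
        right = prop_right_side(text, layout)
        home = mean_home_row_distance(text, layout)

        from .keyboard import bigram_hand_class

        class_counts = dict.fromkeys(
            ("char_repeat", "finger_repeat", "hand_repeat", "hand_alternate"), 0
        )
        for a, b in _letter_pairs(text):
            class_counts[bigram_hand_class(a, b, layout)] += 1
        class_props = {
            k: (v / n_pairs if n_pairs else 0.0) for k, v in class_counts.items()
        }
    except UnsupportedCharacterError as exc:
        wrapped = UnsupportedCharacterError(exc.char, exc.position)
        wrapped.args = (f"item {item.item_id!r}: {wrapped.args[0]}",)
        raise wrapped from exc
    except Exception as exc:
        raise type(exc)(f"item {item.item_id!r}: {exc}") from exc

    return FeatureVector(
        item_id=item.item_id,
        lowercase_count=profile.counts["lowercase"],
        uppercase_count=profile.counts["uppercase"],
        digit_count=profile.counts["digit"],
        symbol_count=profile.counts["symbol"],
        punctuation_count=profile.counts["punctuation"],
        space_count=profile.counts["space"],
        total_chars=profile.total_chars,
        total_keystrokes=n_keystrokes,
        lowercase_prop_all=profile.prop_all["lowercase"],
        lowercase_prop_nonspace=profile.prop_nonspace["lowercase"],
        uppercase_prop_all=profile.prop_all["uppercase"],
        uppercase_prop_nonspace=profile.prop_nonspace["uppercase"],
        digit_prop_all=profile.prop_all["digit"],
        digit_prop_nonspace=profile.prop_nonspace["digit"],
        symbol_prop_all=profile.prop_all["symbol"],
        symbol_prop_nonspace=profile.prop_nonspace["symbol"],
        punctuation_prop_all=profile.prop_all["punctuation"],
        punctuation_prop_nonspace=profile.prop_nonspace["punctuation"],
        space_prop_all=profile.prop_all["space"],
        words_nominal=w_nominal,
        words_whitespace=w_ws,
        keystrokes_per_word=n_keystrokes / w_nominal,
        syllables_per_word=syllables / w_nominal,
        prop_high_freq_words=hf,
        nonword_count=nonword_n,
        prop_nonword_chars=nonword_prop,
        mean_bigram_freq=bigram_mean,
        bigram_pair_count=n_pairs,
        prop_right_side=right,
        mean_home_row_distance=home,
        bigram_char_repeat_count=class_counts["char_repeat"],
        bigram_finger_repeat_count=class_counts["finger_repeat"],
        bigram_hand_repeat_count=class_counts["hand_repeat"],
        bigram_hand_alternate_count=class_counts["hand_alternate"],
        bigram_char_repeat_prop=class_props["char_repeat"],
        bigram_finger_repeat_prop=class_props["finger_repeat"],
        bigram_hand_repeat_prop=class_props["hand_repeat"],
        bigram_hand_alternate_prop=class_props["hand_alternate"],
    )


def features_to_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame indexed by item_id."""
    rows = {fv.item_id: fv.as_dict() for fv in vectors}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_stimulus_file(path: str | Path) -> list[TextItem]:
    """Read a stimulus file: plain text, one item per line, no header."""
    items = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if line.strip():
            items.append(TextItem(item_id=f"line_{i:04d}", text=line))
    if not items:
        raise ValueError(f"stimulus file {path} contains no items")
    return items
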
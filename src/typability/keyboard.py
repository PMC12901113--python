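"""Physical QWERTY keyboard model.

Encodes key coordinates, hand/finger/side assignment and shift pairs for a
US ANSI QWERTY keyboard, and answers the per-character and per-bigram
queries used by the text feature extractor: keystroke expansion (shift
counting), key side, vertical distance from the home row, and the four
bigram hand classes (character repetition, finger repetition, hand
repetition, hand alternation).

The layout is shipped as a plain-text table (``resources/qwerty_ansi.tsv``)
and is user-replaceable, so other physical layouts can be modelled without
code changes.  Finger assignment follows the standard touch-typing chart.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "KeyRecord",
    "KeyboardLayout",
    "UnsupportedCharacterError",
    "load_layout",
    "default_layout",
    "expand_keystrokes",
    "key_side",
    "home_row_distance",
    "bigram_hand_class",
    "BIGRAM_CLASSES",
]

#: Ordered bigram hand classes; every ordered letter pair maps to exactly one.
BIGRAM_CLASSES = ("char_repeat", "finger_repeat", "hand_repeat", "hand_alternate")

HOME_ROW = 2  # row index of the middle (home) row of letter keys


class UnsupportedCharacterError(KeyError):
    """A character has no key on the loaded layout."""

    def __init__(self, char: str, position: int | None = None):
        self.char = char
        self.position = position
        where = "" if position is None else f" at position {position}"
        super().__init__(f"character {char!r}{where} is not supported by the keyboard layout")


@dataclass(frozen=True)
class KeyRecord:
    """One physical key: what it produces and which finger strikes it."""

    key_id: str
    base_char: str
    shifted_char: str | None
    row: int
    column: float
    hand: str  # left | right | thumb
    finger: int  # 1-10, pinky-to-pinky with thumbs 5/6
    side: str  # left | right | neutral


class KeyboardLayout:
    """A set of :class:`KeyRecord` plus a character -> (key, shift) index."""

    def __init__(self, records: Iterable[KeyRecord], name: str = "custom"):
        self.name = name
        self.records: tuple[KeyRecord, ...] = tuple(records)
        self.char_index: dict[str, tuple[KeyRecord, bool]] = {}
        for rec in self.records:
            if rec.base_char in self.char_index:
                raise ValueError(f"duplicate mapping for character {rec.base_char!r}")
            self.char_index[rec.base_char] = (rec, False)
            if rec.shifted_char is not None:
                if rec.shifted_char in self.char_index:
                    raise ValueError(f"duplicate mapping for character {rec.shifted_char!r}")
                self.char_index[rec.shifted_char] = (rec, True)

    def lookup(self, char: str, position: int | None = None) -> tuple[KeyRecord, bool]:
        """Return ``(record, needs_shift)`` for ``char`` or raise."""
        try:
            return self.char_index[char]
        except KeyError:
            raise UnsupportedCharacterError(char, position) from None

    def supports(self, char: str) -> bool:
        return char in self.char_index

    @property
    def supported_characters(self) -> frozenset[str]:
        return frozenset(self.char_index)


def load_layout(path: str | Path, name: str | None = None) -> KeyboardLayout:
    """Load a layout from the delimited text format described in the resource file."""
    path = Path(path)
    records = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key_id, base, shifted, row, column, hand, finger, side = line.split("\t")
        if base == "<space>":
            base = " "
        records.append(
            KeyRecord(
                key_id=key_id,
                base_char=base,
                shifted_char=None if shifted == "-" else shifted,
                row=int(row),
                column=float(column),
                hand=hand,
                finger=int(finger),
                side=side,
            )
        )
    return KeyboardLayout(records, name=name or path.stem)


_DEFAULT: KeyboardLayout | None = None


def default_layout() -> KeyboardLayout:
    """The packaged US ANSI QWERTY layout (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = _importlib_resources.files("typability.resources") / "qwerty_ansi.tsv"
        with _importlib_resources.as_file(ref) as path:
            _DEFAULT = load_layout(path, name="qwerty_ansi")
    return _DEFAULT


def expand_keystrokes(
    text: str, layout: KeyboardLayout | None = None
) -> tuple[int, list[str]]:
    """Total keystrokes required to type ``text``, including shift presses.

    Each character that requires shift contributes one extra keystroke; the
    returned sequence lists each ``"shift"`` event immediately before its
    target key id.  Caps lock is never modelled.
    """
    layout = layout or default_layout()
    sequence: list[str] = []
    for pos, ch in enumerate(text):
        rec, shifted = layout.lookup(ch, pos)
        if shifted:
            sequence.append("shift")
        sequence.append(rec.key_id)
    return len(sequence), sequence


def key_side(char: str, layout: KeyboardLayout | None = None) -> str:
    """Which side of the keyboard a character's key sits on (left/right/neutral)."""
    layout = layout or default_layout()
    rec, _ = layout.lookup(char)
    return rec.side


def home_row_distance(char: str, layout: KeyboardLayout | None = None) -> int:
    """Vertical distance, in rows, from the home row to the character's key."""
    layout = layout or default_layout()
    rec, _ = layout.lookup(char)
    return abs(rec.row - HOME_ROW)


def bigram_hand_class(a: str, b: str, layout: KeyboardLayout | None = None) -> str:
    """Classify an ordered letter pair by the hands/fingers that type it.

    Returns one of ``char_repeat`` (same letter, case-folded),
    ``finger_repeat`` (different letters, same finger), ``hand_repeat``
    (same hand, different fingers) or ``hand_alternate``.
    """
    if not (a.isalpha() and b.isalpha()):
        raise ValueError(f"bigram_hand_class requires letters, got ({a!r}, {b!r})")
    layout = layout or default_layout()
    if a.casefold() == b.casefold():
        return "char_repeat"
    rec_a, _ = layout.lookup(a)
    rec_b, _ = layout.lookup(b)
    if rec_a.finger == rec_b.finger:
        return "finger_repeat"
    if rec_a.hand == rec_b.hand:
        return "hand_repeat"
    return "hand_alternate"
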
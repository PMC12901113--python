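"""Synthetic stimuli and keystroke sessions with known ground truth.

Generates text items under the training-corpus stimulus constraints (at
least three words, at most 70 characters, at most four digits, only the
simple punctuation marks ,.!?') and simulates typing sessions with the
statistical structure the analysis assumes: each participant has a
baseline speed drawn from Normal(51.56, 20.20) wpm truncated to [4, 158],
and each sentence carries a known standardized difficulty injected through
a linear index model, so the outcome-variable pipeline can be checked
against an exact truth table.

Difficulty enters additively on the wpm scale, scaled by the within-person
trial-to-trial SD: ``speed = baseline + within_sd * (T(item) + noise)``.
Under the z-scored outcome definition the participant z-score of a trial
is then ``T(item) + noise`` up to the finite-sample estimate of the
participant's own mean and SD, making the pipeline the inverse of the
generator (exactly so when every participant types every item and noise
is zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    ResourceBundle,
    TextItem,
    default_resources,
    extract_features,
    features_to_frame,
)
from .keyboard import KeyboardLayout, default_layout
from .metrics import KeyEvent, ParticipantRecord, TypingTrial
from .scoring import LinearIndexModel, default_typability_model, predict

__all__ = [
    "SimConfig",
    "TextGenConfig",
    "TruthTable",
    "generate_text_items",
    "simulate_sessions",
    "make_feature_target_set",
    "make_selection_fixture",
]


@dataclass(frozen=True)
class TextGenConfig:
    """Rates controlling the composition of generated sentences."""

    min_words: int = 3
    max_words: int = 10
    max_chars: int = 70
    max_digits: int = 4
    capital_rate: float = 0.9  # probability the sentence starts with a capital
    digit_token_rate: float = 0.08  # probability of one numeric token
    terminal_punct_rate: float = 0.85
    comma_rate: float = 0.15
    nonword_rate: float = 0.05  # probability a word is replaced by a pronounceable non-word
    uppercase_word_rate: float = 0.05  # extra capitalised (name-like) word


@dataclass(frozen=True)
class SimConfig:
    """Study-structure parameters for simulated typing sessions.

    Defaults mirror the training corpus: 15 randomly selected sentences
    per participant; baseline speeds Normal(51.56, 20.20) wpm truncated to
    [4, 158].  ``within_person_sd_wpm`` scales how strongly sentence
    difficulty (in z units) moves a trial's speed; ``noise_sd_z`` is
    trial-level noise on the z scale.
    """

    n_items: int = 100
    n_participants: int = 200
    trials_per_participant: int = 15
    speed_mean_wpm: float = 51.56
    speed_sd_wpm: float = 20.20
    speed_bounds: tuple[float, float] = (4.0, 158.0)
    within_person_sd_wpm: float = 5.0
    noise_sd_z: float = 0.5
    error_rate: float = 0.0
    true_model: LinearIndexModel | None = None
    text: TextGenConfig = field(default_factory=TextGenConfig)
    seed: int = 0

    def __post_init__(self):
        if self.speed_bounds[0] >= self.speed_bounds[1]:
            raise ValueError("speed_bounds must be ordered (low, high)")
        if min(self.speed_sd_wpm, self.within_person_sd_wpm, self.noise_sd_z) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.trials_per_participant > self.n_items:
            raise ValueError("trials_per_participant cannot exceed n_items")
        if self.n_participants < 1 or self.n_items < 1:
            raise ValueError("need at least one participant and one item")


@dataclass
class TruthTable:
    """Injected standardized difficulty per item (mean 0, sample SD 1)."""

    values: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="truth")

    def to_csv(self, path) -> None:
        self.as_series().rename_axis("item_id").to_csv(path, float_format="%.10f", lineterminator="\n")


_NONWORD_ONSETS = ["br", "cl", "dr", "fl", "gr", "pl", "sk", "tr", "sp", "vl"]
_NONWORD_CODAS = ["ax", "ex", "ix", "ozz", "uzz", "yx", "orp", "ilk", "ust", "omp"]


def _make_nonword(rng: np.random.Generator, dictionary: set[str]) -> str:
    for _ in range(50):
        w = (
            _NONWORD_ONSETS[int(rng.integers(0, len(_NONWORD_ONSETS)))]
            + "aeiou"[int(rng.integers(0, 5))]
            + _NONWORD_CODAS[int(rng.integers(0, len(_NONWORD_CODAS)))]
        )
        if w not in dictionary:
            return w
    return "zqvrk"  # unreachable in practice


def generate_text_items(
    n: int,
    config: TextGenConfig | None = None,
    seed: int = 0,
    resources: ResourceBundle | None = None,
) -> list[TextItem]:
    """Generate ``n`` stimulus sentences satisfying the corpus constraints.

    Words are sampled from the packaged vocabulary with a bias toward the
    high-frequency list; rates of capitals, digits, punctuation and
    non-words are tunable.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or TextGenConfig()
    resources = resources or default_resources()
    if config.min_words < 1 or config.min_words > config.max_words:
        raise ValueError("word-count bounds are unsatisfiable")
    # a sentence of min_words shortest words plus punctuation must fit
    if config.min_words * 2 - 1 > config.max_chars:
        raise ValueError(f"cannot satisfy min_words={config.min_words} within {config.max_chars} chars")
    rng = np.random.default_rng(seed)
    top = resources.high_freq_words
    vocab = sorted(w for w in resources.dictionary if "'" not in w)
    contractions = sorted(w for w in resources.dictionary if "'" in w and len(w) > 2)
    items = []
    for i in range(n):
        for _attempt in range(200):
            n_words = int(rng.integers(config.min_words, config.max_words + 1))
            words = []
            for _ in range(n_words):
                r = rng.random()
                if r < 0.6:
                    words.append(top[int(rng.integers(0, len(top)))])
                elif r < 0.62 and contractions:
                    words.append(contractions[int(rng.integers(0, len(contractions)))])
                else:
                    words.append(vocab[int(rng.integers(0, len(vocab)))])
            if rng.random() < config.nonword_rate:
                words[int(rng.integers(0, len(words)))] = _make_nonword(rng, resources.dictionary)
            if rng.random() < config.digit_token_rate:
                n_digits = int(rng.integers(1, config.max_digits + 1))
                number = "".join(str(int(d)) for d in rng.integers(0, 10, n_digits))
                words.insert(int(rng.integers(0, len(words) + 1)), number)
            if rng.random() < config.uppercase_word_rate:
                j = int(rng.integers(0, len(words)))
                if words[j].isalpha():
                    words[j] = words[j].capitalize()
            if rng.random() < config.capital_rate:
                words[0] = words[0][0].upper() + words[0][1:]
            if len(words) > 3 and rng.random() < config.comma_rate:
                j = int(rng.integers(1, len(words) - 1))
                words[j] = words[j] + ","
            text = " ".join(words)
            if rng.random() < config.terminal_punct_rate:
                text += str(rng.choice([".", ".", ".", "!", "?"]))
            n_digit_chars = sum(c.isdigit() for c in text)
            if (
                len(text) <= config.max_chars
                and len(words) >= config.min_words
                and n_digit_chars <= config.max_digits
            ):
                items.append(TextItem(item_id=f"item_{i:04d}", text=text))
                break
        else:
            raise ValueError("could not satisfy the stimulus constraints; relax the config")
    return items


def _truth_table(
    items: list[TextItem],
    model: LinearIndexModel,
    layout: KeyboardLayout,
    resources: ResourceBundle,
) -> TruthTable:
    raw = np.array([predict(model, extract_features(it, layout, resources)) for it in items])
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("injected difficulty is constant across items; cannot standardize")
    z = (raw - raw.mean()) / sd
    return TruthTable({it.item_id: float(v) for it, v in zip(items, z)})


def _synthesize_trial(
    participant_id: str,
    item: TextItem,
    wpm: float,
    rng: np.random.Generator,
    error_rate: float,
) -> TypingTrial:
    typed = item.text
    if error_rate > 0:
        chars = list(typed)
        letters = "abcdefghijklmnopqrstuvwxyz"
        for j, c in enumerate(chars):
            if c.isalpha() and rng.random() < error_rate:
                chars[j] = letters[int(rng.integers(0, 26))]
        typed = "".join(chars)
    # uniform inter-key intervals spanning exactly the implied duration
    duration = (len(typed) / 5.0) / wpm * 60.0
    n_keys = len(typed)
    if n_keys == 1:
        presses = np.array([0.0])
        releases = np.array([duration])
    else:
        presses = np.linspace(0.0, duration, n_keys)
        releases = presses.copy()
    events = [
        KeyEvent(key_label=c, press_time=float(p), release_time=float(r))
        for c, p, r in zip(typed, presses, releases)
    ]
    return TypingTrial(
        participant_id=participant_id,
        item_id=item.item_id,
        presented_text=item.text,
        typed_text=typed,
        events=events,
    )


def simulate_sessions(
    items: list[TextItem],
    config: SimConfig,
    layout: KeyboardLayout | None = None,
    resources: ResourceBundle | None = None,
) -> tuple[list[ParticipantRecord], TruthTable]:
    """Simulate typing sessions over ``items`` with a known truth table.

    Each participant draws a truncated-normal baseline speed, selects
    ``trials_per_participant`` items at random without replacement (all
    items when equal to ``n_items``), and types each at
    ``baseline + within_sd * (T(item) + Normal(0, noise_sd_z))`` wpm, with
    key events at uniform inter-key intervals matching the implied
    duration.  Non-positive implied speeds are resampled (counted in the
    truth table's resample log).  Character substitution errors are
    injected at ``error_rate``.
    """
    if len(items) != config.n_items:
        config = replace(config, n_items=len(items))
    layout = layout or default_layout()
    resources = resources or default_resources()
    model = config.true_model or default_typability_model()
    truth = _truth_table(items, model, layout, resources)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.speed_bounds
    records = []
    n_resampled = 0
    for p in range(config.n_participants):
        pid = f"p{p:05d}"
        if config.trials_per_participant == len(items):
            chosen = list(range(len(items)))
        else:
            chosen = list(rng.choice(len(items), config.trials_per_participant, replace=False))
        # A participant's baseline must admit positive speeds on all their
        # items; deterministically non-positive combinations (very slow
        # baseline on a very hard item with little noise) redraw the
        # baseline, so the additive speed structure is never distorted.
        for _attempt in range(1000):
            while True:
                baseline = rng.normal(config.speed_mean_wpm, config.speed_sd_wpm)
                if lo <= baseline <= hi:
                    break
            speeds = []
            for idx in chosen:
                t_val = truth.values[items[idx].item_id]
                wpm = -1.0
                for _ in range(100):
                    noise = rng.normal(0.0, config.noise_sd_z) if config.noise_sd_z > 0 else 0.0
                    wpm = baseline + config.within_person_sd_wpm * (t_val + noise)
                    if wpm > 0.5:
                        break
                    n_resampled += 1
                    if config.noise_sd_z == 0:
                        break  # deterministic: only a new baseline can help
                if wpm <= 0.5:
                    break
                speeds.append(wpm)
            if len(speeds) == len(chosen):
                break
        else:
            raise ValueError(f"cannot draw positive speeds for participant {pid}")
        trials = [
            _synthesize_trial(pid, items[idx], wpm, rng, config.error_rate)
            for idx, wpm in zip(chosen, speeds)
        ]
        records.append(ParticipantRecord(pid, trials))
    truth.resampled = n_resampled  # type: ignore[attr-defined]
    return records, truth


def make_feature_target_set(
    n: int,
    true_model: LinearIndexModel | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, LinearIndexModel]:
    """Feature matrix + linear target for parameter-recovery checks.

    Features named by the model's coefficients are drawn from plausible
    per-feature ranges (proportions in [0, 1], counts as integers, rates on
    their natural scales); the target is the model's prediction plus
    Normal(0, noise_sd) noise.
    """
    true_model = true_model or default_typability_model()
    if n <= len(true_model.coefficients) + 1:
        raise ValueError("n must exceed the number of coefficients + 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in true_model.coefficients:
        if "bigram_freq" in name:
            cols[name] = rng.uniform(5_000, 25_000, n)
        elif "keystrokes_per_word" in name or "syllables_per_word" in name:
            cols[name] = rng.uniform(0.8, 3.0, n)
        elif "count" in name or name in ("total_keystrokes", "total_chars"):
            cols[name] = rng.integers(10, 80, n).astype(float)
        elif "prop" in name:
            cols[name] = rng.uniform(0.0, 1.0, n)
        else:
            cols[name] = rng.standard_normal(n)
    X = pd.DataFrame(cols, index=[f"row_{i:05d}" for i in range(n)])
    target = true_model.intercept + X.values @ np.array(list(true_model.coefficients.values()))
    if noise_sd > 0:
        target = target + rng.normal(0.0, noise_sd, n)
    return X, np.asarray(target, dtype=float), true_model


def make_selection_fixture(
    n: int = 1000,
    n_informative: int = 8,
    n_noise: int = 12,
    coef: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str], dict[str, str]]:
    """Informative + pure-noise candidates for selection-recovery checks.

    All columns are standard normal; informative columns enter the target
    with equal coefficients so permutation importances are comparable and
    the importance elbow falls at the informative/noise boundary.  Returns
    (features, target, informative names, variable -> attribute map with
    one attribute per variable).
    """
    rng = np.random.default_rng(seed)
    informative = [f"signal_{i:02d}" for i in range(n_informative)]
    noise_vars = [f"noise_{i:02d}" for i in range(n_noise)]
    X = pd.DataFrame(
        rng.standard_normal((n, n_informative + n_noise)),
        columns=informative + noise_vars,
        index=[f"row_{i:05d}" for i in range(n)],
    )
    y = X[informative].values.sum(axis=1) * coef + rng.normal(0.0, noise_sd, n)
    attribute_map = {v: v for v in X.columns}
    return X, np.asarray(y), informative, attribute_map
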
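"""Linear typability index models.

Houses the eight-predictor Typability Index, Bell's 1949 typewriting
Difficulty Index, and the three-predictor refit of Bell's variables on the
modern training corpus, plus prediction and a human-readable model-file
format.

A model is an intercept plus named unstandardised coefficients (B) over
:class:`~typability.features.FeatureVector` fields; predictions are in
z-score units of relative typing speed (0 = typed at one's average speed,
positive = easier/faster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "LinearIndexModel",
    "predict",
    "default_typability_model",
    "bell_difficulty_index",
    "bell_refit_model",
    "write_model",
    "read_model",
    "DEFAULT_BIGRAM_COEFFICIENT",
]

#: Default unstandardised coefficient for mean bigram frequency (per-million
#: scale).  The published value is printed only as "< 0.001", so the shipped
#: default is a nominal placeholder chosen to match the reported positive
#: standardised weight (beta = 0.192) at the packaged bigram-frequency scale;
#: it is recorded as PLACEHOLDER in the model notes and can be overridden via
#: a model file, the ``bigram_coefficient`` argument, or a refit.
DEFAULT_BIGRAM_COEFFICIENT = 2.5e-05


@dataclass(frozen=True)
class LinearIndexModel:
    """Intercept + named coefficients of a linear difficulty/typability index."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    standardized_coefficients: dict[str, float] | None = None
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


def predict(model: LinearIndexModel, features: Mapping[str, float]) -> float:
    """Apply a linear index model to a feature vector (no clamping).

    ``features`` may be a :class:`~typability.features.FeatureVector` or any
    mapping of feature name to value; a missing feature raises ``KeyError``
    naming it.
    """
    score = model.intercept
    for name, coef in model.coefficients.items():
        try:
            value = features[name]
        except KeyError:
            raise KeyError(f"model {model.name!r} requires feature {name!r}, which is missing") from None
        score += coef * value
    return score


def default_typability_model(bigram_coefficient: float | None = None) -> LinearIndexModel:
    """The published eight-predictor Typability Index.

    All coefficients are the printed unstandardised values except the
    bigram-frequency term, whose published value rounds below the printed
    precision; see :data:`DEFAULT_BIGRAM_COEFFICIENT`.
    """
    bigram = DEFAULT_BIGRAM_COEFFICIENT if bigram_coefficient is None else bigram_coefficient
    return LinearIndexModel(
        name="typability_index_v1",
        intercept=-4.022,
        coefficients={
            "lowercase_prop_nonspace": 4.694,
            "total_keystrokes": -0.012,
            "syllables_per_word": -0.431,
            "prop_high_freq_words": 0.693,
            "symbol_prop_nonspace": -4.037,
            "mean_bigram_freq": bigram,
            "prop_nonword_chars": -1.665,
            "prop_right_side": 0.462,
        },
        standardized_coefficients={
            "lowercase_prop_nonspace": 0.533,
            "total_keystrokes": -0.433,
            "syllables_per_word": -0.300,
            "prop_high_freq_words": 0.266,
            "symbol_prop_nonspace": -0.220,
            "mean_bigram_freq": 0.192,
            "prop_nonword_chars": -0.157,
            "prop_right_side": 0.100,
        },
        notes={
            "mean_bigram_freq": (
                "PLACEHOLDER: published B prints as < 0.001; shipped default "
                f"{bigram!r} assumes the packaged per-million bigram scale"
            ),
            "scale": "features on the typability.features.FeatureVector scale",
        },
    )


def bell_difficulty_index(
    syllables_per_word: float, pct_frequent_words: float, keystrokes_per_word: float
) -> float:
    """Bell's 1949 typewriting Difficulty Index (closed form).

    ``pct_frequent_words`` is a percentage on the 0-100 scale, matching the
    original 0.08 coefficient.  Higher values mean easier text.
    """
    for name, v in (
        ("syllables_per_word", syllables_per_word),
        ("pct_frequent_words", pct_frequent_words),
        ("keystrokes_per_word", keystrokes_per_word),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return 7.81 + 3.49 * syllables_per_word + 0.08 * pct_frequent_words - 2.44 * keystrokes_per_word


def bell_refit_model() -> LinearIndexModel:
    """Bell's three predictors refit to the modern training corpus.

    Word frequency enters as a proportion (0-1), unlike the 0-100
    percentage of the 1949 formula.
    """
    return LinearIndexModel(
        name="bell_refit",
        intercept=-0.462,
        coefficients={
            "prop_high_freq_words": 1.249,
            "keystrokes_per_word": -0.114,
            "syllables_per_word": 0.073,
        },
        standardized_coefficients={
            "prop_high_freq_words": 0.479,
            "keystrokes_per_word": -0.236,
            "syllables_per_word": 0.051,
        },
        notes={"scale": "prop_high_freq_words is a 0-1 proportion"},
    )


# --------------------------------------------------------------------------
# model file format: plain-text key-value lines


def write_model(model: LinearIndexModel, path: str | Path) -> None:
    """Serialise a model to the human-readable key-value format."""
    lines = [f"name: {model.name}", f"intercept: {model.intercept!r}"]
    for name, value in model.coefficients.items():
        lines.append(f"coef {name}: {value!r}")
    for name, value in (model.standardized_coefficients or {}).items():
        lines.append(f"beta {name}: {value!r}")
    for key, note in model.notes.items():
        lines.append(f"note {key}: {note}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path: str | Path) -> LinearIndexModel:
    """Read a model written by :func:`write_model`."""
    name = "unnamed"
    intercept = 0.0
    coefficients: dict[str, float] = {}
    betas: dict[str, float] = {}
    notes: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if not _:
            raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
        if key == "name":
            name = value
        elif key == "intercept":
            intercept = float(value)
        elif key.startswith("coef "):
            coefficients[key[5:]] = float(value)
        elif key.startswith("beta "):
            betas[key[5:]] = float(value)
        elif key.startswith("note "):
            notes[key[5:]] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return LinearIndexModel(name, intercept, coefficients, betas or None, notes)
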
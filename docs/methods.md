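# Methods

## The outcome variable: typability

A typing trial yields gross words per minute,
`wpm = (characters incl. spaces / 5) / elapsed seconds × 60`, measured
from the first key press to the last key release and unadjusted for
errors.  The character count defaults to the typed string (a
`typed|presented` switch is exposed; with per-sentence accuracy above
~97% the choice is near-immaterial).

Within each participant, trial speeds are z-scored, `z = (x − μ)/σ`, with
μ and σ that participant's own mean and *sample* (n−1) standard deviation
over their trials (a ddof switch is exposed).  A sentence's **actual
typability** is the mean z across the participants who typed it.  The
z-transform removes baseline speed differences, so typability is a pure
relative-difficulty scale: 0 = typed at one's average speed.

Transcription accuracy is `1 − Levenshtein(typed, presented) / length(presented)`
(unit-cost edit distance via edlib, cross-checked in tests against an
exhaustive recursive oracle); it is not clamped, so pathological typed
strings can go negative.

Participant exclusions mirror the training-corpus conventions: fewer than
15 completed sentences, mean error rate (1 − accuracy averaged over
trials) ≥ 25 %, or any inter-key interval (successive press-time
difference) above 50 s.  Error rate is defined at the trial level because
no finer-grained definition is available; the thresholds and the
definition are parameters.  Participants with (numerically) zero speed
variance are also excluded, since their z-scores are undefined.

## The candidate predictor roster

`extract_features` computes 30 candidate variables over 17 text/key
attributes.  Attributes with several defensible operationalisations carry
multiple *calculation variants*; the training pipeline (Stage 1) keeps
the most explanatory variant per attribute:

* letter case (5 variants: lowercase proportion of all / of non-space
  characters; uppercase count / both proportions),
* symbols and punctuation (5 variants: symbol proportions; punctuation
  count / proportions — punctuation is a tracked subset of the symbol
  class),
* digits (count + two proportions), spaces (count + proportion),
* total words (characters/5 vs whitespace runs),
* single-variant attributes: total keystrokes (incl. one shift per
  character that needs it; caps-lock is never modelled), keystrokes per
  word, syllables per word, top-1,000-word proportion, non-word count and
  non-word character proportion, mean letter-bigram frequency, right-side
  key proportion, mean home-row distance, and the four bigram hand-class
  proportions (character repeat / finger repeat / hand repeat / hand
  alternation).

This roster is a *reconstruction*: the published operationalisation is
not fully printed, so `typability.features.ATTRIBUTE_MAP` is the single
source of truth here.  Per-word ratios use the characters/5 denominator;
word-membership features use whitespace tokens stripped of surrounding
non-letters, with contractions looked up whole and then by their
apostrophe-free stem.  A token with no letters (e.g. "42") is never a
non-word.  Home-row distance is vertical row distance only (|row − 2|);
the layout table carries column positions so a Euclidean variant could be
added without API change.

## The keyboard model

A US ANSI QWERTY table (plain text, user-replaceable) assigns every
supported character a key, row, column, hand, finger (standard
touch-typing chart) and side.  Space is thumb-typed and neutral: it is
excluded from the right-side proportion.  Shift events are counted as
keystrokes but are not themselves scored for side or row.  Bigram hand
classes partition all ordered letter pairs: same character (case-folded),
same finger, same hand, different hands.

## Lexical resources

The packaged resources are deliberately compact, plain-text stand-ins for
full corpus resources, and every loader accepts replacements:

* `top1000_words.txt` — 1,000 common English words, roughly frequency
  ordered, assembled for this package.
* `dictionary_words.txt` — ~4,400 words: the high-frequency list plus
  additional bases, simple rule-based inflections and US/UK variant
  spellings.  It deliberately excludes proper nouns, so name-like tokens
  count as non-words.
* `bigram_freq.tsv` — all 26×26 letter pairs, derived from the top-1,000
  list under Zipfian rank weights and normalised to per-million
  occurrences.  The scale is recorded in the bundle metadata because
  linear-index coefficients are scale-bound.
* `syllables.tsv` — a curated lexicon for words where the rule-based
  fallback (vowel groups, silent final e, consonant-le, minimum 1) is
  unreliable.

Because the dictionary and frequency lists are small, absolute feature
values for exotic text differ from what exhaustive resources would give;
rank orderings of ordinary English sentences are much less sensitive.

## The index models

`default_typability_model()` carries the published eight-predictor
coefficients verbatim, except the bigram-frequency term, which is printed
only as "< 0.001".  The shipped default, B = 2.5e-5, was chosen to match
the published standardised weight (β = 0.192) at the packaged
per-million bigram scale (SD ≈ 3,300 across generated sentences, outcome
SD ≈ 0.43) and is marked PLACEHOLDER in the model notes; it can be
overridden per call, via a model file, or by refitting.  Bell's 1949
Difficulty Index is provided as a closed form (word frequency as a 0–100
percentage, matching its 0.08 coefficient), and the three-predictor
refit of Bell's variables uses a 0–1 proportion, matching its printed
1.249 coefficient.  Models serialise to a human-readable key-value file.

## The training pipeline

Stage 1 runs a random-forest regression over all candidates and keeps the
best calculation variant per attribute.  Importance is **out-of-bag
permutation importance**: each variable is permuted within each tree's
OOB sample and the increase in that tree's OOB MSE averaged over trees,
expressed as a percent of the mean OOB MSE (% Inc MSE).  OOB evaluation
matters — an interpolating forest scored on its training data inflates
pure-noise variables dramatically.  Defaults: 500 trees, one third of the
variables per split, 5 permutation repeats; all in `TrainConfig` and
recorded in the model notes.

Stage 2 removes exact linear dependencies (detected via the design
matrix's null space) and then iteratively removes variables with VIF
above 10, always dropping the least important member of the offending
group.  Stage 3 reruns the forest on the survivors, keeps the top
variables up to the *inflection point* — the position of the largest drop
between consecutive sorted importances, ties to the smaller count, with a
warning when the curve has no clear elbow — fits OLS, and removes
non-significant predictors one at a time (least significant first,
refitting) until all p < 0.05.  The full audit trail (every retained or
removed variable, with reason and value) is returned as a
`SelectionReport`.

Standardised β comes from a second fit on z-scored predictors and target,
so the identity β = B·SD(x)/SD(y) is a genuine cross-check.  RMSE is the
root mean squared residual; AIC uses the statsmodels Gaussian convention
(recorded in the fit summary — AIC comparisons are only meaningful within
one convention).  Note that stepwise p-pruning applies no multiplicity
control: on a pure-noise corpus it retains a lone spurious predictor with
probability roughly 1 − 0.95^k.

`validate` regresses actual scores on a model's predictions; slope ≈ 1
with a non-zero intercept diagnoses a pure calibration shift (relative
ordering preserved), which is the practically relevant failure mode when
transferring the index across corpora.

## Stimulus grouping

Three deliberately simple, deterministic algorithms over scored items:

* **matched** — rank by score, deal round-robin (lowest to group 1); with
  a group size, the k·size ranks closest to the median are selected
  first, taking one extra item below the median when the window is
  uneven.  Each consecutive block of k ranks contributes one item per
  group, bounding the spread of group means by (range / group size).
* **divergent-simple** — extremes from the bottom and top; intermediate
  groups are centred on evenly spaced quantile ranks, with colliding
  windows shifted inward deterministically (the collision rule is a
  documented choice; it matters only when k·size approaches n).
* **divergent-clusters** — one-dimensional K-means initialised at score
  quantiles (so the result is reproducible and the seed only breaks exact
  ties), groups labelled in ascending centre order, optionally trimmed to
  the `size` items nearest each centre.

## The synthetic-data generator

`generate_text_items` builds sentences from the packaged vocabulary under
the training-corpus stimulus constraints (≥ 3 words, ≤ 70 characters,
≤ 4 digits, punctuation limited to `, . ! ? '`), with tunable rates of
capitals, digit tokens, punctuation and pronounceable non-words.

`simulate_sessions` emulates the study structure: each participant draws
a baseline speed from Normal(51.56, 20.20) wpm truncated to [4, 158] and
types 15 randomly selected sentences (the defaults; both are
parameters).  Sentence difficulty enters additively on the wpm scale,

```
speed = baseline + within_sd · (T(item) + Normal(0, noise_sd_z))
```

where T is the *standardized* (mean 0, sample SD 1) prediction of a known
linear model over the items.  Under the z-scored outcome definition the
participant z of a trial is then T + noise up to the finite-sample
estimate of the participant's own μ and σ — i.e. the analysis pipeline is
the inverse of the generator, *exactly* so when every participant types
every item and noise is zero.  With the 15-of-100 random-selection
design, that finite-sample estimation alone caps the sentence-level
recovery correlation around 0.996–0.998 even at zero noise, which is why
the identity check uses a full crossing.  The within-person SD default of
5 wpm is a realistic trial-to-trial spread for copy typing; baselines
whose implied speeds would be non-positive on a sampled hard item are
redrawn (counted and logged) so the additive structure is never
distorted.  Key events are placed at uniform inter-key intervals spanning
exactly the implied duration — only trial-level timing feeds the outcome
variable, so per-key latency realism is out of scope.

What passing the synthetic checks shows — and what it does not: the
pipeline arithmetic (wpm, z, aggregation, exclusions, selection, fitting)
is correct and self-consistent, and parameter recovery works at realistic
sizes.  It does not validate the published coefficient *values* against
human data, which would require the external keystroke corpus; the
package faithfully carries those printed values instead.

## Problem sizes and numerical choices

The verification script uses 100 items × 200 participants (full crossing)
for the z-identity, n = 1,000 for coefficient and selection recovery
(8 informative + 12 noise candidates), 100 scores for the grouping
contracts and a 60-item × 80-participant corpus for the CLI round trip —
sizes chosen so each check is decisive yet runs in minutes on one CPU.
Proportions are exact rational arithmetic on counts; tolerance choices:
z-sets are checked to 1e-10, noiseless OLS recovery to 1e-8, and the
bigram table look-up is exact.  CSV outputs round scores to 3 decimals
(full precision is kept internally); all file outputs are UTF-8 with
line-feed endings so repeated runs are byte-identical.

## Known limitations

* The packaged lexical resources are compact; for production scoring of
  unusual vocabulary, supply fuller word lists and a corpus bigram table
  via `ResourceBundle.from_paths`.
* The bigram-frequency coefficient of the default model is a documented
  placeholder (see above).
* The index is sentence-scale, (American) English, physical-QWERTY; other
  units, languages or layouts need refitting (the layout table is
  replaceable, the pipeline is corpus-agnostic).
* Grouping algorithms optimise nothing; they are intentionally simple
  rank/cluster heuristics.
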
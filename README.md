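# typability

Predict and measure the **typability** — the relative typing speed — of
English text.

In copy-typing tasks (typing tests, experiments that use typing as a task
or a proxy), some sentences are intrinsically harder to type than others.
If that difficulty is not controlled, differences between conditions can
be created or masked by the stimuli rather than the typists.  This package
provides the **Typability Index**: a linear model over text/key attributes
that predicts how fast a sentence is typed *relative to a typist's own
average speed*, in within-person z-score units — 0 means typed at one's
average speed, +1 means one within-person standard deviation faster.

The index is

```
typability = −4.022
           + 4.694 · P(lowercase | non-space)
           − 0.012 · total keystrokes (incl. shift)
           − 0.431 · syllables per word
           + 0.693 · P(token ∈ top-1,000 words)
           − 4.037 · P(symbol | non-space)
           +     β · mean letter-bigram frequency
           − 1.665 · P(character ∈ non-dictionary word)
           + 0.462 · P(right-hand key | non-space)
```

where words are counted as characters/5 (the typing convention).  The
bigram-frequency coefficient is published only as "< 0.001"; the shipped
default (2.5e-5 on the packaged per-million scale) is marked PLACEHOLDER
in the model metadata and can be overridden or refit.

The package is aimed at researchers who need to **score** candidate
stimuli, **group** them into matched or deliberately divergent sets,
**analyze** keystroke logs into actual typability scores (gross WPM →
within-participant z-scores → per-sentence means, with Levenshtein
accuracy and the standard exclusion filters), **refit** the index on a new
corpus via the three-stage random-forest / VIF / significance pipeline,
and **simulate** realistic keystroke sessions with known ground truth.

## Worked example

`input.txt`, one stimulus per line, no header:

```
Thanks for sending this.
The wind was strong and gusting.
Suite 2750 in Downtown Denver.
```

```sh
typability score input.txt --out scores.csv
```

prints `scored 3/3 items -> scores.csv` and writes:

```
item_id,text,typability,error
line_0001,Thanks for sending this.,0.362,
line_0002,The wind was strong and gusting.,0.506,
line_0003,Suite 2750 in Downtown Denver.,-1.603,
```

The first two sentences (short, lowercase, high-frequency words) are
predicted to be typed faster than the typist's average; the third
(capitals, digits, rare proper nouns) is predicted well below average.
Scores are comparable *within* one scored set: select or match stimuli on
these values, or use them as a covariate.

Grouping the scored items:

```sh
typability group scores.csv --type matched --groups 2 --size 10 --out groups.csv
```

adds a `group` column plus a `groups.summary.csv` with per-group mean, SD
and n.  `--type divergent-simple` builds easy/hard extremes and
`--type divergent-clusters` uses one-dimensional K-means.  `analyze`,
`train` and `simulate` complete the pipeline (see `typability --help`).

As a library:

```python
from typability import TextItem, default_typability_model, extract_features, predict

fv = extract_features(TextItem("s1", "Thanks for sending this."))
print(round(predict(default_typability_model(), fv), 3))  # 0.362
```

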
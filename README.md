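# meme-ed

Multiple-embedding modelling of emergency-department (ED) electronic health
records via clinical *pseudo-notes*.

## The problem

Structured ED records live in half a dozen tables — stay metadata, triage
assessments, medication reconciliation, periodic vitals, dispensed
medications (pyxis), and discharge diagnoses — whose schemas differ across
institutions. Harmonizing them into a common feature space is brittle.
This package takes the text route instead: each concept's rows are
serialized into a short templated clinical paragraph (a pseudo-note), each
paragraph is embedded with a **frozen** text encoder, and a small trainable
head fuses the six concept embeddings with self-attention to predict

* **ED disposition** — discharged home vs admitted (binary), and
* **decompensation** among admitted patients — discharge location, ICU
  requirement, in-hospital mortality (three independent binary labels).

It is aimed at clinical-informatics researchers who want to experiment with
text-serialized EHR modelling end to end — serialization, frozen encoders,
fusion heads, ablations, and a rigorous evaluation harness — without
credentialed data: a synthetic cohort generator emulates the six-table
dialect with configurable outcome signal per stream.

## The model

For an encounter with concept notes $c_1,\dots,c_6$ (fixed order: arrival,
triage, medrecon, vitals, pyxis, diagnosis):

$$\vec v_i = \mathrm{Encoder}(c_i), \qquad
\vec V_{concat} = [\vec v_1; \dots; \vec v_6]$$

The six vectors form a length-6 sequence fed to scaled dot-product
self-attention with learned query/key/value projections (the attention
weights are a per-concept relevance pattern), then a fully connected ReLU
layer and a linear classifier:

$$\vec V_{att} = \mathrm{SelfAttention}(\vec V_{concat}),\quad
\vec V_{fc} = \mathrm{ReLU}(FC(\vec V_{att})),\quad
\vec z = \mathrm{Classifier}(\vec V_{fc})$$

Each logit gets an independent sigmoid; training minimises summed binary
cross-entropy $L=\sum_i\sum_l \mathrm{BCE}(\sigma(z_{i,l}),\,y_{i,l})$
(one logit for disposition, three for decompensation). The encoder is
never updated — only the head trains.

Ablations and baselines ship alongside: **MSEM** (the whole narrative as a
single 512-token-truncated embedding plus a linear classifier — no
attention), six **single-concept** heads, and three tabular baselines
(logistic regression, gradient-boosted trees, a five-layer MLP) that see
structured features only, never text.

The default encoder is a deterministic offline one: token-hashed
bag-of-words through a seeded fixed Gaussian projection, L2-normalized
(768-d). A pretrained-transformer backend satisfies the same frozen
contract when `transformers` and local weights are available.

## Worked example

```bash
python examples/01_generate_and_render.py
```

prints a 60-encounter synthetic cohort summary and the six pseudo-notes of
its first encounter, e.g.

```
cohort of 60 encounters
median age 58, admitted 22 (36.7%)

--- arrival
The patient is a 61 year old F patient of WHITE race who arrived at the
emergency department by AMBULANCE.
--- triage
At triage: heart rate was 50 bpm, blood pressure was 130/75 mmHg, ...
The triage acuity was 4. The chief complaint was minor laceration.
--- medrecon [fallback]
Medications were not administered.
...
```

The fallback line is the fixed sentence used whenever a stream has no rows,
so every encounter always yields exactly six paragraphs.

```bash
python examples/02_embed_and_train.py
```

embeds a 2000-encounter cohort and trains the fusion head on the
disposition task:

```
trained 22 epochs; best val loss 0.4189
test AUROC for ED disposition: 0.868
(0.5 would be chance; the default cohort carries a strong signal)
```

`examples/03_benchmark.py` prints the full model-comparison table with
bootstrap CI half-widths, and `examples/04_few_shot_transfer.py` adapts a
trained head to a shifted five-stream institution with 2–256 labelled
encounters. A thin CLI mirrors these flows
(`meme-ed generate|render|embed|train|benchmark|fewshot`).

## Evaluation harness

F1 thresholds are chosen by exhaustive search over 1000 evenly spaced
thresholds in [0, 1] **on validation scores** and applied to test scores;
AUROC/AUPRC are threshold-free. 95% CIs come from resampling the test set
1000 times (percentile interval; the reported parenthetical is the
half-width). Partition leakage (a key in two splits) is a hard error.

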
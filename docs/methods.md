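# Methods

## Pipeline overview

Six EHR concept streams per ED encounter — arrival/stay metadata, triage,
medication reconciliation (medrecon), periodic vitals, dispensed
medications (pyxis), discharge diagnoses — are rendered into templated
clinical paragraphs ("pseudo-notes"), embedded independently with a frozen
text encoder, and fused by a trainable self-attention head into a patient
representation for outcome prediction. The concept order (arrival, triage,
medrecon, vitals, pyxis, diagnosis) is fixed everywhere a sequence of
concepts appears.

Two prediction tasks are hierarchical: ED disposition (home vs admitted)
is defined on every encounter; the decompensation triple (discharge home,
ICU requirement, in-hospital mortality) is defined **only** on admitted
encounters — for non-admitted encounters the labels are absent, not zero,
and the multilabel head trains and evaluates on the admitted subset only.

## Schema layer

Tables arrive as per-concept CSVs; a YAML schema-variant file maps each
dialect's column names onto canonical field names. Two variants ship:
`mimic_ed` (six tables) and `ucla_like` (five tables — no medrecon; such
bundles carry the stream flagged *absent* and its pseudo-note falls back).
Rows referencing unknown encounter ids are dropped with a logged count;
duplicate rows are kept. The admission-code vocabulary is configuration
(`admit_codes` in the variant file), not code.

Splitting is visit-level: encounters are shuffled with a seeded generator
and cut at sizes computed by the **largest-remainder rule** (floor each
share, hand leftover units to the largest fractional remainders, ties in
train → val → test order). This rule reproduces exactly the 70/15/15
partition sizes of a 400,019-encounter cohort (280,013/60,003/60,003) and
of its 158,007-encounter admitted subset (110,605/23,701/23,701).
Reference figures for this arithmetic are sometimes quoted inconsistently
— an admitted-subset total of 158,010 appears in prose where the
accompanying outcome counts and split sizes imply 158,007 — and the
arithmetic here follows the internally consistent 158,007.
Patients are not grouped: the same patient may appear in two partitions,
which matches the visit-independent design and is a known limitation.

Summary tables round percentages half-up to one decimal; demographics and
disposition use the whole cohort as denominator, decompensation outcomes
the admitted subset.

## Pseudo-notes

Templates are data, not code: per concept a skeleton with named slots, a
per-row phrase joined by a separator, and a fixed fallback sentence for an
empty stream (e.g. "Medications were not administered." for medrecon).
Rendering is pure — identical inputs yield byte-identical text. Rows are
ordered by timestamp, then input order. Design choices:

* Field-level nulls inside a present row render as "not recorded" rather
  than dropping the sentence, keeping note structure stable for the
  encoder.
* Numbers print as integers when integral, else to one decimal (clinical
  charting granularity).
* Timestamps render as clock time (HH:MM). Full date-times are unique per
  encounter; under any bag-of-words encoder they become sample-identifying
  tokens that let a classifier memorize rather than learn, and they waste
  context under a real tokenizer's budget.

The MSEM note is the six texts joined in canonical order with a blank-line
separator; it is one text and is truncated at the encoder's 512-token
budget like any other note — which is precisely why the single-embedding
model loses information from later concepts.

## Encoders

The encoder contract is frozen: a pseudo-note maps to a fixed-dimension
vector and no gradient ever reaches encoder parameters. Default dimension
768, truncation at 512 tokens.

* **hashed-projection** (default, fully offline, bit-deterministic):
  lowercase alphanumeric tokenization, first 512 tokens, token-hashed
  bag-of-words over 4096 buckets (BLAKE2 hashing), multiplied by a seeded
  fixed Gaussian projection to `dim`, then L2-normalized. Word order is
  ignored by construction; a text with no tokens maps to the constant
  vector of a reserved `<empty>` marker so outputs always have unit norm.
* **pretrained-transformer**: wraps a HuggingFace encoder in inference
  mode with first-token (default) or mean pooling. Pooling strategy and
  dimensionality are exposed as configuration because different backbones
  make different choices. If `torch`/`transformers` or weights are not
  available locally the backend raises an explicit error naming the
  hashed-projection alternative.

Cohort embeddings are cached with a spec fingerprint; a stale cache
(different fingerprint) is refused rather than silently reused.

## Fusion head and variants

The six embeddings form a (6, dim) sequence. Self-attention uses learned
query/key/value projections and scaled dot-product softmax; there is no
output projection, so with a length-1 sequence the layer reduces to the
value projection — attention weights are then exactly 1. A deliberately
resolved ambiguity: the attention operates over the six concept
*positions* (weights say how much each concept attends to the others),
not over the flat concatenated vector, where a single-position softmax
would make attention a no-op. The attended sequence is flattened and
passed through FC(→256)+ReLU and a linear classifier.

Variants: `meme` (the full head), `msem` (one whole-narrative embedding →
linear classifier, no attention, matching a linear-probe reading of the
single-embedding design), `single:<concept>` (one stream through the same
head with sequence length 1).

Losses are summed per-logit sigmoid binary cross-entropy; the binary task
is the m = 1 case of the multilabel loss (a 2-class softmax would be
equivalent; the single-logit form keeps thresholding machinery uniform).
Logits are clamped to ±30 inside the numerically stable log-sum-exp form.

Training is minibatch Adam on precomputed embeddings. Defaults: 1
attention head, FC width 256, learning rate 1e-3, batch 128, weight decay
1e-5, at most 30 epochs with early stopping after 3 non-improving
validation epochs, best-validation-loss parameters returned. All defaults
are package choices; each run's seed fixes initialisation and shuffling,
and training is bit-reproducible on a fixed BLAS. The neural layers are
implemented directly in NumPy (float32, explicit backpropagation): dense,
ReLU, dropout, batch normalization, self-attention, Adam — sized for
minute-scale single-CPU training at the cohort sizes used here.

## Tabular baselines

All three consume a fixed-layout numeric feature vector only (never note
text): age, sex/race/arrival-mode one-hots, triage vitals + acuity,
first/last/min/max/mean per periodic-vitals channel, medication and
diagnosis counts, ICD one-hots over the training cohort's vocabulary.
Missing numerics are median-imputed with companion flag columns.

* Logistic regression: L2 penalty 1.0, SAGA solver (scikit-learn).
* Gradient-boosted trees: learning rate 0.05, max depth 6, up to 1000
  trees with early stopping on validation log-loss (xgboost, 1 thread for
  reproducibility).
* MLP: hidden layers 1024/512/256/128/64, each with batch normalization
  and ReLU; dropout 0.3 on the first three hidden layers; weight decay
  everywhere; Adam at 1e-3 halved on validation plateau. Implemented on
  the same NumPy layer stack as the head.

## Evaluation

* **Threshold search**: 1000 evenly spaced thresholds spanning [0, 1]
  inclusive; prediction rule score ≥ t; ties take the lowest threshold.
  The search result is definitionally identical to exhaustive evaluation
  over the same grid. Thresholds are selected on validation scores and
  applied to test scores, avoiding optimistic bias. AUPRC is computed
  threshold-free (it is a property of the ranking, not of a threshold).
* **Metrics**: AUROC as the tie-aware rank statistic; AUPRC as
  step-interpolated area (average precision); F1 defined as 0 when there
  are no positive predictions. All three require both classes present.
* **Bootstrap**: (label, score) pairs resampled with replacement, same
  size, 1000 resamples by default; 2.5/97.5 percentile interval; reported
  parenthetical is the half-width. Single-class resamples are redrawn so
  rank metrics stay defined. Test sets under 10 items set a warning flag.
* **Few-shot**: the head is fine-tuned from the source state on n seeded
  target samples (default schedule 2, 4, …, 1024; 10 low-rate Adam epochs,
  no early stop — the sample may be tiny) and evaluated on the fixed
  target test split. The trend over n is reported, not enforced.
* **Benchmark driver**: one cohort, one split, every model; identical
  partitions for all models, leakage is a hard error.

## Synthetic cohort generator

The generator emulates the six-table dialect with hierarchical labels and
per-stream signal. Observables are drawn first with plausible clinical
marginals; each stream's **signal is a standardized function of its own
recorded data**: an age-plus-ambulance term (arrival), the abnormal-vitals
count at triage, the mean abnormal-vitals fraction over periodic
measurements, and high-risk home-medication / dispensed-medication /
diagnosis-code indicators (prevalence 0.25 each). Triage acuity is derived
from the abnormal count (acuity 1 = sickest), and chief complaints are
drawn from high- vs low-risk vocabularies with probability increasing in
the count — so the risk information genuinely lives in the recorded
tokens and numbers.

The encounter risk score is the weighted sum of the six standardized
signals. Admission is Bernoulli through a logistic link whose intercept is
calibrated by bisection on the drawn scores so the empirical prevalence
matches the configured target (default 39.5%). Decompensation labels are
drawn among admitted encounters with per-label links (discharge-home with
a negative sign — sicker admitted patients are less likely to go straight
home) calibrated to conditional prevalences 0.449/0.197/0.029. Whole
streams are dropped per-encounter at configurable missingness rates
(defaults 0–15%; a rate of 1.0 models a dialect that lacks the stream
entirely). Everything flows from one seeded generator.

Because the signals are functions of the observables, the Bayes ceiling
with respect to the recorded tables equals the label-side ceiling; the
default weights (1.2 arrival, 2.2 triage, 1.4 medrecon, 1.8 vitals, 1.5
pyxis, 2.2 diagnosis) put the risk-score SD near 4.3 and that ceiling
near AUROC 0.96, defining the package's *strong-signal* condition. Zeroed
weights make labels independent of all data (the null condition); a
`concentrated()` helper puts all weight on one stream for ablation
studies.

What the generator does **not** emulate — and hence what green tests do
not establish about real EHR: real marginal and joint distributions of
vitals and codes, free-text chief-complaint variety, temporal dynamics
within a stay, patient-level correlation across visits, coding practice
differences between institutions, and label noise from documentation
error. Results on synthetic cohorts validate the machinery (serialization,
frozen embedding, fusion, evaluation protocol), not clinical performance.

## Problem sizes and numerical choices

Statistical checks run at cohort size 2000 (70/15/15 split, 300-encounter
test sets), five seeds where a median is reported — sizes chosen so the
whole suite trains dozens of heads in minutes on one CPU while leaving
clear margins on the assertions. The few-shot transfer target is a
shifted site: admission prevalence 25.3%, no medrecon stream, different
seed. Bisection tolerance for intercept calibration is 1e-10 within
±30; degenerate inputs (empty streams, single-class resamples, tied
scores, empty-token notes) all have defined, tested behaviour as described
above.

## Known limitations

* The hashed encoder ignores word order and numeric magnitude; it sees
  numbers as tokens. It validates the pipeline offline but is not a
  substitute for a pretrained clinical language model when one is
  available.
* Visit-level splitting can place one (synthetic) patient in two
  partitions by design.
* Bootstrap resampling treats test observations as exchangeable; with
  very rare labels (mortality at 2.9% of admitted) small test sets leave
  wide intervals, which the harness reports rather than hides.
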
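# Methods

This note documents the modeling decisions behind `painrisk`: what each
stage assumes, which parameters matter, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## The outcome: a computable chronic-pain phenotype

A patient is chronic-pain positive if any of three rules fires within
`followup_days` (default 1095 = 3×365 days) after the index date, which is
the earliest breast-cancer diagnosis code (`C50*` in ICD-10-CM; the ICD-9
prefix default is the literal `170`, configurable — in standard ICD-9-CM
breast malignancies are 174/175, so deployments on real ICD-9 data should
override it):

* **code** — any post-index code with ICD-10-CM prefix `G89`, ICD-9-CM
  prefix `338.2`, or SNOMED code exactly `82423001`;
* **medication** — pain-medication exposures (17 configured opioid
  ingredients, matched case-insensitively as substrings, so brand/strength
  text matches) form chains: sorted by start, an exposure joins the current
  chain while the gap from the chain's last covered day is ≤ 90 days. The
  rule fires when one chain covers **more than 90 distinct days**. Distinct
  days, not calendar span: two isolated one-day fills four months apart must
  not count as three months of use. Overlapping and nested intervals are
  union-counted. "Three months" is fixed at 90 days and the duration test is
  strict (> 90) while the gap test is non-strict (≤ 90), reading "exceeding"
  strictly and "within" inclusively. Only exposures starting on or after the
  index date count; exposures begun before the diagnosis are out of scope.
* **exacerbation** — pain-intensity scores (0–10) exist on both sides of the
  index and the post-index maximum strictly exceeds the **latest** pre-index
  score. The latest score is the least ambiguous "baseline" reading; an
  index-day score counts as pre-index (it was known at diagnosis). The
  3-year horizon applies to the post-index evidence, as it does to every
  rule.

Positivity is a pure OR. The reported branch is the first firing rule in
the order code → medication → exacerbation; the order affects reporting
only, never the label. The medication rule has an independently implemented
day-expansion oracle (`oracle_medication_label`) used in tests: it expands
exposures into integer day sets and splits them into maximal runs, with no
interval arithmetic shared with the production path.

## Feature preparation

Codes are made unique as `VOCAB:code` strings and tokenized to integers
≥ 2, assigned in sorted order over the **training split only**; PAD = 0,
UNK = 1. UNK exists although out-of-vocabulary handling is often left
unstated: test-split codes unseen in training need a representation.
Sequences keep pre-index codes in chronological order and are truncated to
the 128 **most recent** events (those nearest the diagnosis are the
clinically relevant tail) or padded with PAD/timestamp-0; a boolean mask
marks real positions. 128 sits slightly above the cohort's mean sequence
length (109).

Age is divided by 100. Race, ethnicity and survey (question, answer) pairs
are one-hot encoded against training-split category lists; unknown
categories at inference encode as zero blocks. Binary columns are filtered
by variance threshold: keep iff population variance ≥ p(1−p), with p = 0.9
for demographics and 0.8 for surveys. The biased (population) variance
estimator is used, matching the conventional threshold formula, and
retention is non-strict — a column exactly at the allowable constancy p is
"allowable". Age is continuous and is never thresholded. Everything is
fitted on the training split and applied unchanged elsewhere, so no
information leaks across splits.

## Model

An encoder-only transformer over the token sequence, fused with static
features:

* Token embeddings (PAD row frozen at zero) are scaled by √d_model — the
  standard convention keeping learned embeddings commensurate with the
  unit-amplitude sinusoids — and summed with two sinusoidal encodings:
  the position index, and the days-until-diagnosis timestamp. Addition
  rather than concatenation keeps the width uniform; sinusoids handle
  unbounded day ranges without a bucket vocabulary. Timestamps are divided
  by `timestamp_scale` (default 7 days) before encoding: with raw day
  values the fastest sinusoid channel has a ~6-day wavelength and acts as
  per-event noise, whereas clinically, events days apart should look
  temporally similar.
* Two post-norm encoder layers, 4 heads each (d_model 32, head width 8),
  feedforward width 32, dropout 0.1 at the three canonical sites:
  embedding sums, attention probabilities, and sublayer outputs. Padded
  keys receive exactly zero attention (enforced in the masked softmax, not
  by large negative constants), and padded positions are excluded from the
  mean pooling; patients with no pre-index codes pool to a zero vector and
  are classified from their static features alone rather than excluded.
* The demographic vector (normalized age + retained one-hots) and the
  survey vector pass through **linear** maps to width 4 each; the pooled
  sequence vector (32) and the two static vectors are concatenated and a
  single linear layer plus sigmoid produces the risk probability.
* d_model = 32 is this package's choice (matching the feedforward width);
  mean pooling is used because no CLS-style token is part of the design.
* Loss: class-weighted binary cross-entropy, positive weight 3.0 by
  default, probabilities clamped to [1e−7, 1−1e−7] inside the loss.
* Initialization is uniform ±1/√fan_in, seeded from `ModelConfig.seed`;
  evaluation mode is fully deterministic.

The model, Adam, and backpropagation are implemented in numpy on a small
tape-based autodiff (`painrisk.autograd`). Gradients are verified in the
test suite against central finite differences with the tape switched to
float64 (float32 is used in production for speed).

## Training and evaluation

Stratified 70/5/25 split (largest-remainder allocation within each label
class — an unstratified 5% validation slice of a small cohort at 17.6%
prevalence can contain no positives at all, making validation AUROC
undefined). Adam, constant learning rate 0.001, 20 epochs. The returned
parameters are those of the epoch with the best validation AUROC; the
validation set exists for tuning, and AUROC is the headline metric.

Batch size is a free parameter of this package; the default is **224**.
The reference recipe implies roughly 13 optimizer steps per epoch at its
own cohort size; at the synthetic default of n = 4000 a batch of 224 keeps
the 20-epoch budget at a comparable point of the fitting curve. With small
batches the same budget takes ~3× more Adam steps and drifts further into
memorization of the training split.

Metrics: accuracy, precision, recall and the confusion matrix at a fixed
decision threshold of 0.5 (config-exposed; 0.5 is the sigmoid-natural
default), plus rank-based (Mann–Whitney) AUROC with ties counted one half.
Empty denominators report 0.0 and are flagged; single-class subsets report
AUROC as undefined rather than a number.

The positive-weight sweep re-runs the full training per weight in {1, 3, 5}
with identical seeds and splits and reports train- and test-split metrics
side by side. The sweep uses the **fixed-epoch protocol** — every weight
trains all 20 epochs and keeps its final parameters, with no
validation-based epoch selection. Under per-weight best-validation
selection each weight would be evaluated at a different epoch, which
confounds the comparison: the weight's precision-for-recall trade appears
cleanly (and monotonically) only when the training budget is held fixed.
The headline pipeline keeps best-validation-AUROC selection.

## Interpretability

Permutation importance shuffles one static feature column across patients
(10 seeded repeats), re-evaluates, and scores the feature by the mean AUROC
drop; constant columns score exactly zero because shuffling them is the
identity. The pooled sequence encoding is computed once and reused —
shuffling static columns cannot affect the encoder. Attention analysis
averages the heads of the final encoder layer (the conventional reporting
layer; config-exposed) and reports the k strongest connections excluding
the diagonal and any pair touching a padded position, with deterministic
(source, target) tie-breaking.

## The synthetic cohort generator

The generator emulates the *statistical shape* of a breast-cancer EHR
cohort: demographics match a reference cohort profile (age
57.8 ± 10.4 clipped to [23.9, 86.8]; race 88.2% White, 7.5% Black or
African American, 2.1% Asian, 1.1% each for two further groups; 98%
non-Hispanic); per-patient pre-index sequences are Poisson with mean 109
over a 600-code synthetic vocabulary whose codes can never collide with
the cohort or phenotype rule prefixes; codes arrive in visit clusters
(~6 codes per visit day); 81 survey questions with four answers each;
opioid exposure intervals; 0–10 pain scores. All dates are emitted as
absolute ISO-8601 strings relative to a per-patient index date, forcing
the reader to recompute day offsets.

The outcome is generated by a logistic model on latent indicators — six
planted diagnosis codes, three planted survey answers, and age — never by
the classifier's own functional form, so signal recovery is a fair test.
The intercept is calibrated by fixed-seed Monte Carlo bisection so the
marginal prevalence hits the 17.6% target under whatever effects are
configured. Positive patients then receive post-index evidence matching
the sampled phenotype branches (pain codes, qualifying opioid chains with
gap ≤ 90 days and union > 90 days, or rising pain scores); at least one
branch is always expressed. Negative patients may receive deliberately
sub-threshold opioid exposures (single chains covering ≤ 90 days, or two
short chains split by a > 90-day gap) as near-boundary stress tests, and
non-rising pain scores. Carried risk codes recur 3–8 times across visits,
as chronic conditions do in billing data.

**Planted effect sizes are deliberately large** (code log-odds 4–5, survey
2–2.5, age 1.2 per decade; Bayes-optimal AUROC ≈ 0.98). The generator's
role is to certify that the pipeline recovers a known signal: at
desk-scale cohort sizes, moderate effects leave recovery dominated by
estimation noise (600 candidate codes against ~2800 training patients cap
even a regularized linear oracle near test AUROC 0.87 with a ~0.13
train–test gap), which would make end-to-end tests flaky rather than
informative. The cost is realism: odds ratios this large do not occur in
clinical risk factors, so absolute metric levels on synthetic runs
overstate what any real cohort would show. Passing tests demonstrate that
the pipeline's plumbing, labeling, features, optimization and evaluation
are correct — not that this architecture would achieve comparable numbers
on real data.

Further simplifications: survey answers are uniform apart from the planted
ones; no code co-occurrence structure, billing semantics, mortality or
censoring; pain scores are generated only where a phenotype branch or its
negative control needs them.

## Numerical and degenerate-input choices

* "3 months" = 90 days, "3 years" = 1095 days — calendar-month arithmetic
  is not reproducible across platforms.
* Same-day events order by (vocabulary, code); ties in top-k attention
  break by position; split remainders distribute deterministically —
  byte-identical reruns are a tested contract (`all` twice produces
  identical metric CSVs).
* The variance-threshold comparison uses a 1e−12 tolerance so the exact
  boundary case Var = p(1−p) is kept despite float rounding.
* Zero-length exposure intervals cover one day; end < start is a
  validation error.
* Empty sequences pool to zero vectors; fully padded attention rows are
  all-zero rather than NaN.

## Known limitations

* Static (demographic/survey) signal is recovered more slowly than code
  signal: with 20 epochs at learning rate 0.001 the linear branches move
  at most ~0.9 per weight, and once the sequence branch fits the training
  set the residual gradient that statics need vanishes. The importance-
  recovery test therefore uses a cohort whose signal is static-only.
* The generator does not model informative missingness, visit frequency
  differences between sick and healthy patients, or coding-practice drift
  over calendar time.
* Attention-connection reports are per-patient; no cross-patient
  aggregation into narrative tables is attempted.
* The whole pipeline is CPU-bound numpy; it is sized for cohorts of
  thousands, not millions.
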
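# painrisk

Chronic pain affects roughly a third of breast-cancer survivors, yet
predicting who is at risk is hard: the drivers span diagnosis history,
demographics and socioeconomic context. `painrisk` is a tested, reusable
implementation of an EHR-based risk pipeline for this problem:

1. **Computable phenotype** — a deterministic chronic-pain outcome over a
   3-year post-diagnosis window, combining three rules: chronic-pain
   diagnosis codes (ICD-10-CM `G89*`, ICD-9-CM `338.2*`, SNOMED `82423001`),
   a pain-medication duration rule (a chain of opioid exposures with gaps
   ≤ 90 days covering > 90 distinct days), and pain-score exacerbation
   (post-diagnosis maximum strictly above the latest pre-diagnosis score).
2. **Multimodal features** — per-patient diagnosis-code time series
   (vocabulary-qualified codes tokenized to integers, truncated/padded to
   length 128, with days-until-diagnosis timestamps), one-hot demographics
   and survey question–answer pairs filtered by variance thresholding
   (binary column kept iff Var ≥ p(1−p); p = 0.9 demographic, 0.8 survey),
   and age normalized by 100.
3. **Model** — an encoder-only transformer (4 heads, 2 layers, d_ff = 32,
   dropout 0.1) over the code sequence with sinusoidal positional and
   days-to-diagnosis embeddings; masked mean pooling; linear width-4
   branches for demographic and survey vectors; concatenation; a final
   linear layer and sigmoid:

   p(chronic pain) = σ( W · [ pool(Encoder(E(codes) + PE(pos) + PE(days))),
                              W_d·x_demo, W_s·x_survey ] + b )

   trained with class-weighted binary cross-entropy
   L = −mean( w·y·log p + (1−y)·log(1−p) ), w = 3.0 by default, Adam at a
   constant learning rate 0.001 for 20 epochs on a stratified 70/5/25
   train/validation/test split, keeping the best-validation-AUROC epoch.
4. **Interpretability** — permutation feature importance (AUROC drop) for the
   static features and extraction of the strongest self-attention
   connections between sequence positions.

Because the cohort data this kind of analysis targets live in a
controlled-access research environment, the package ships a first-class
**synthetic cohort generator** (`painrisk.simulate`) that emits OMOP-style
CSV tables — persons, conditions, drug exposures, surveys, pain-score
measurements — with a *planted, recoverable* risk signal driven by a
logistic model on code/survey/age indicators, calibrated to a 17.6% outcome
prevalence and a mean sequence length of 109 codes. Every downstream stage
is testable end to end without any data access. The model and its training
loop are implemented in pure numpy on a small reverse-mode autodiff core
(`painrisk.autograd`), gradient-checked against finite differences.

## Worked example

```python
from painrisk import SimConfig, ModelConfig, TrainConfig
from painrisk import simulate, cohort, phenotype, features
from painrisk import train as T

sim = SimConfig(n_patients=2000, seed=7)
tables = simulate.generate_cohort(sim)          # five OMOP-style tables
timelines = cohort.extract_cohort(tables)       # index dates + day offsets
labels_df = phenotype.label_cohort(timelines)   # code/medication/exacerbation
print(labels_df["positive"].mean())             # 0.1715
print(labels_df["branch"].value_counts().to_dict())
# {'none': 1657, 'code': 248, 'medication': 72, 'exacerbation': 23}

labels = labels_df["positive"].to_numpy().astype(int)
tr, va, te = T.split_dataset(labels, seed=7)
pipe = features.FeaturePipeline().fit([timelines[i] for i in tr])
batch = pipe.transform(timelines); batch["labels"] = labels
mc = ModelConfig(vocab_size=pipe.vocab.size, demo_dim=pipe.demo_dim,
                 survey_dim=pipe.survey_dim, seed=7)
model, history = T.train(mc, TrainConfig(seed=7),
                         T.take(batch, tr), T.take(batch, va))
print(T.evaluate(model, T.take(batch, te)).as_dict())
# {'split': 'test', 'threshold': 0.5, 'n': 500, 'accuracy': 0.844,
#  'auroc': 0.8948151893045725, 'precision': 0.5338983050847458,
#  'recall': 0.7325581395348837, 'tn': 359, 'fp': 55, 'fn': 23, 'tp': 63}
```

The prevalence is the phenotype-positive fraction of the simulated cohort;
`branch` reports which rule fired first (code → medication → exacerbation).
The evaluation dict gives threshold-0.5 metrics plus the rank-based AUROC —
the model recovers most of the planted signal (test AUROC 0.89 here; the
Bayes-optimal ceiling of the generator's latent risk is about 0.98, with
the shortfall dominated by estimation noise at this cohort size).

A command-line interface runs the same stages against CSV artifacts:

```bash
painrisk --out-dir runs/demo --seed 7 all     # simulate ... interpret
```

## Layout

| module | contents |
| --- | --- |
| `painrisk.simulate` | synthetic OMOP-style cohort generator with planted risk |
| `painrisk.cohort` | CSV reading, cohort definition, per-patient timelines |
| `painrisk.phenotype` | the three chronic-pain rules + day-expansion oracle |
| `painrisk.features` | tokenization, padding, one-hots, variance threshold |
| `painrisk.model` | encoder-only attention classifier (numpy autodiff) |
| `painrisk.train` | splits, training loop, metrics, pos-weight sweep |
| `painrisk.interpret` | permutation importance, top attention connections |
| `painrisk.cli` | `painrisk` command: staged pipeline with manifests |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
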
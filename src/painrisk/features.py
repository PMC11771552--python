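"""Feature preparation: code tokenization, fixed-length sequences, static encodings.

Diagnosis codes are made unique by concatenating vocabulary and code
("ICD9CM:272.4") and tokenized into integers >= 2; token 0 is PAD and token 1
is UNK (out-of-vocabulary at inference).  Sequences are truncated/padded to a
fixed length of 128 — slightly above the cohort's mean code-sequence length —
keeping the 128 events nearest the diagnosis.  Age is normalized by 100; race,
ethnicity and survey (question, answer) pairs are one-hot encoded; binary
columns are then filtered by a variance threshold with a per-block constancy
parameter p (variance kept iff >= p(1-p)).

Everything here is fitted on the training split only and applied unchanged to
validation/test, so no information leaks across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientTimeline

PAD, UNK = 0, 1
SEQ_LEN = 128

__all__ = [
    "PAD",
    "UNK",
    "SEQ_LEN",
    "FeaturePipeline",
    "StaticFeatures",
    "StaticSchema",
    "TokenizedSequence",
    "Vocabulary",
    "build_vocabulary",
    "encode_static",
    "pad_truncate",
    "tokenize",
    "variance_threshold_fit",
]


@dataclass(frozen=True)
class Vocabulary:
    """Injective map from "VOCAB:code" strings to integer tokens >= 2."""

    token_of: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.token_of) + 2  # + PAD + UNK

    def __getitem__(self, key: str) -> int:
        return self.token_of.get(key, UNK)


@dataclass
class TokenizedSequence:
    """Fixed-length token and timestamp series with a validity mask."""

    tokens: np.ndarray  # int32[SEQ_LEN]
    timestamps: np.ndarray  # float32[SEQ_LEN], days until diagnosis, 0 at pads
    mask: np.ndarray  # bool[SEQ_LEN], True at real events


def build_vocabulary(training_timelines: list[PatientTimeline]) -> Vocabulary:
    """Assign tokens 2.. to all distinct pre-index codes, in sorted-string order."""
    if not training_timelines:
        raise ValueError("cannot build a vocabulary from an empty training split")
    keys = sorted(
        {f"{vocab}:{code}" for tl in training_timelines for vocab, code, _ in tl.pre_index_codes}
    )
    return Vocabulary({k: i + 2 for i, k in enumerate(keys)})


def tokenize(timeline: PatientTimeline, vocab: Vocabulary) -> list[tuple[int, int]]:
    """Pre-index codes, chronological order, unseen codes mapped to UNK."""
    return [
        (vocab[f"{v}:{c}"], days) for v, c, days in timeline.pre_index_codes
    ]


def pad_truncate(series: list[tuple[int, int]], length: int = SEQ_LEN) -> TokenizedSequence:
    """Truncate to the ``length`` most recent events or pad with PAD/0.

    The input is chronologically ordered (days-until-diagnosis decreasing), so
    the most recent events — those nearest the diagnosis — are the tail.
    """
    kept = series[-length:]
    n = len(kept)
    tokens = np.zeros(length, dtype=np.int32)
    timestamps = np.zeros(length, dtype=np.float32)
    mask = np.zeros(length, dtype=bool)
    if n:
        tokens[:n] = [t for t, _ in kept]
        timestamps[:n] = [d for _, d in kept]
        mask[:n] = True
    return TokenizedSequence(tokens, timestamps, mask)


@dataclass
class StaticSchema:
    """Training-split category lists for deterministic one-hot encoding."""

    races: list[str]
    ethnicities: list[str]
    survey_pairs: list[tuple[str, str]]
    demo_keep: list[int] = field(default_factory=list)  # post-threshold columns
    survey_keep: list[int] = field(default_factory=list)

    @property
    def demo_names(self) -> list[str]:
        names = [f"race={r}" for r in self.races] + [f"ethnicity={e}" for e in self.ethnicities]
        return [names[i] for i in self.demo_keep]

    @property
    def survey_names(self) -> list[str]:
        names = [f"{q}={a}" for q, a in self.survey_pairs]
        return [names[i] for i in self.survey_keep]


@dataclass
class StaticFeatures:
    age_norm: float
    demo_onehot: np.ndarray  # full one-hot block, pre-selection
    survey_onehot: np.ndarray

    def selected(self, schema: StaticSchema) -> tuple[np.ndarray, np.ndarray]:
        """(demo branch input incl. age, survey branch input) after selection."""
        demo = np.concatenate(
            [[self.age_norm], self.demo_onehot[schema.demo_keep]]
        ).astype(np.float32)
        return demo, self.survey_onehot[schema.survey_keep].astype(np.float32)


def encode_static(timeline: PatientTimeline, schema: StaticSchema) -> StaticFeatures:
    """One-hot race/ethnicity and survey answers; age divided by 100.

    Categories or (question, answer) pairs absent from the training schema
    encode as all-zero blocks.
    """
    if timeline.age_at_diagnosis < 0:
        raise ValueError(f"patient {timeline.patient_id}: negative age")
    demo = np.zeros(len(schema.races) + len(schema.ethnicities), dtype=np.float32)
    if timeline.race in schema.races:
        demo[schema.races.index(timeline.race)] = 1.0
    if timeline.ethnicity in schema.ethnicities:
        demo[len(schema.races) + schema.ethnicities.index(timeline.ethnicity)] = 1.0
    pair_index = {pair: i for i, pair in enumerate(schema.survey_pairs)}
    survey = np.zeros(len(schema.survey_pairs), dtype=np.float32)
    for pair in timeline.survey_answers:
        i = pair_index.get(pair)
        if i is not None:
            survey[i] = 1.0
    return StaticFeatures(timeline.age_at_diagnosis / 100.0, demo, survey)


def variance_threshold_fit(matrix: np.ndarray, p: float) -> list[int]:
    """Columns of a {0,1} matrix whose population variance is >= p(1-p).

    ``p`` is the allowable probability of the constant value: a binary column
    constant at rate >= p (variance < p(1-p)) is dropped.  Retention is
    non-strict — a column exactly at the threshold is kept.
    """
    matrix = np.asarray(matrix)
    if not 0.5 < p < 1.0:
        raise ValueError("p must lie in (0.5, 1)")
    bad = [
        j for j in range(matrix.shape[1]) if not np.isin(matrix[:, j], (0, 1)).all()
    ]
    if bad:
        raise ValueError(f"non-binary column(s): {bad}")
    var = matrix.var(axis=0)  # population (biased) estimator
    threshold = p * (1.0 - p)
    return [int(j) for j in np.nonzero(var >= threshold - 1e-12)[0]]


class FeaturePipeline:
    """Fit tokenization and static schemas on training timelines, then transform.

    Parameters
    ----------
    p_demo, p_survey:
        Constancy parameters for variance thresholding of the demographic and
        survey one-hot blocks (defaults 0.9 and 0.8: demographics vary less).
    """

    def __init__(self, p_demo: float = 0.9, p_survey: float = 0.8, seq_len: int = SEQ_LEN):
        self.p_demo = p_demo
        self.p_survey = p_survey
        self.seq_len = seq_len
        self.vocab: Vocabulary | None = None
        self.schema: StaticSchema | None = None

    def fit(self, training_timelines: list[PatientTimeline]) -> "FeaturePipeline":
        self.vocab = build_vocabulary(training_timelines)
        races = sorted({tl.race for tl in training_timelines})
        ethnicities = sorted({tl.ethnicity for tl in training_timelines})
        pairs = sorted({p for tl in training_timelines for p in tl.survey_answers})
        self.schema = StaticSchema(races, ethnicities, pairs)
        feats = [encode_static(tl, self.schema) for tl in training_timelines]
        demo = np.stack([f.demo_onehot for f in feats])
        survey = np.stack([f.survey_onehot for f in feats])
        self.schema.demo_keep = variance_threshold_fit(demo, self.p_demo)
        self.schema.survey_keep = variance_threshold_fit(survey, self.p_survey)
        return self

    def transform(self, timelines: list[PatientTimeline]) -> dict[str, np.ndarray]:
        """Model-ready arrays: tokens, timestamps, mask, demo, survey."""
        assert self.vocab is not None and self.schema is not None, "fit() first"
        seqs = [pad_truncate(tokenize(tl, self.vocab), self.seq_len) for tl in timelines]
        feats = [encode_static(tl, self.schema) for tl in timelines]
        selected = [f.selected(self.schema) for f in feats]
        return {
            "tokens": np.stack([s.tokens for s in seqs]),
            "timestamps": np.stack([s.timestamps for s in seqs]),
            "mask": np.stack([s.mask for s in seqs]),
            "demo": np.stack([d for d, _ in selected]),
            "survey": np.stack([s for _, s in selected]),
        }

    @property
    def demo_dim(self) -> int:
        return 1 + len(self.schema.demo_keep)  # age + retained one-hots

    @property
    def survey_dim(self) -> int:
        return len(self.schema.survey_keep)

    @property
    def static_feature_names(self) -> list[str]:
        return ["age_at_diagnosis"] + self.schema.demo_names + self.schema.survey_names
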
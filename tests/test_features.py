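"""Tokenization, padding, static encodings and variance-threshold selection."""

import numpy as np
import pytest

from conftest import build_timeline
from painrisk.features import (
    PAD,
    UNK,
    FeaturePipeline,
    StaticSchema,
    build_vocabulary,
    encode_static,
    pad_truncate,
    tokenize,
    variance_threshold_fit,
)


def timeline_with_codes(codes, **kw):
    pre = [(v, c, d) for (v, c), d in zip(codes, range(len(codes), 0, -1))]
    return build_timeline(pre=pre, **kw)


class TestVocabulary:
    def test_tokens_assigned_in_sorted_order_from_two(self):
        tl = timeline_with_codes([("ICD9CM", "272.4"), ("ICD10CM", "I10")])
        vocab = build_vocabulary([tl])
        assert vocab.token_of == {"ICD10CM:I10": 2, "ICD9CM:272.4": 3}
        assert vocab.size == 4

    def test_rebuild_is_deterministic_and_size_arithmetic_holds(self):
        codes = [("ICD10CM", f"Z{i:04d}") for i in range(5740)]
        tl = timeline_with_codes(codes)
        v1, v2 = build_vocabulary([tl]), build_vocabulary([tl])
        assert v1.token_of == v2.token_of
        assert v1.size == 5742  # distinct codes plus PAD and UNK

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


def test_tokenize_preserves_order_and_maps_unseen_to_unk():
    train = timeline_with_codes([("ICD9CM", "272.4")])
    vocab = build_vocabulary([train])
    series = tokenize(build_timeline(pre=[("ICD9CM", "272.4", 365)]), vocab)
    assert series == [(2, 365)]
    unseen = tokenize(build_timeline(pre=[("ICD10CM", "NEW", 10)]), vocab)
    assert unseen == [(UNK, 10)]
    assert tokenize(build_timeline(), vocab) == []


@pytest.mark.parametrize(
    "n_events, kept, n_pads",
    [(130, 128, 0), (100, 100, 28), (128, 128, 0), (0, 0, 128)],
)
def test_pad_truncate_lengths_and_mask(n_events, kept, n_pads):
    series = [(i + 2, n_events - i) for i in range(n_events)]  # newest last
    seq = pad_truncate(series)
    assert len(seq.tokens) == 128
    assert seq.mask.sum() == kept
    assert (seq.tokens[kept:] == PAD).all()
    assert (seq.timestamps[kept:] == 0).all()
    if n_events > 128:
        # the two oldest (largest days-until-diagnosis) events are dropped
        assert seq.timestamps[0] == n_events - 2
    if kept:
        retained = [t for t, _ in series[-128:]]
        assert list(seq.tokens[:kept]) == retained  # relative order preserved


SCHEMA = StaticSchema(
    races=["Asian", "Black or African American", "White"],
    ethnicities=["Not Hispanic or Latino"],
    survey_pairs=[("SQ001", "A1"), ("SQ001", "A2")],
    demo_keep=[0, 1, 2, 3],
    survey_keep=[0, 1],
)


def test_encode_static_age_normalization_and_onehots():
    tl = build_timeline(age=57.8, race="Asian", surveys=[("SQ001", "A1")])
    feats = encode_static(tl, SCHEMA)
    assert feats.age_norm == pytest.approx(0.578)
    assert feats.demo_onehot.tolist() == [1, 0, 0, 1]
    assert feats.survey_onehot.tolist() == [1, 0]


def test_encode_static_unknown_category_gives_zero_block():
    tl = build_timeline(race="Unreported", ethnicity="Unreported", surveys=[("SQ099", "A9")])
    feats = encode_static(tl, SCHEMA)
    assert feats.demo_onehot.sum() == 0
    assert feats.survey_onehot.sum() == 0


def test_encode_static_rejects_negative_age():
    with pytest.raises(ValueError, match="negative age"):
        encode_static(build_timeline(age=-1.0), SCHEMA)


class TestVarianceThreshold:
    def test_worked_examples(self):
        col_95_zeros = np.r_[np.ones(5), np.zeros(95)].reshape(-1, 1)
        assert variance_threshold_fit(col_95_zeros, 0.9) == []  # var 0.0475 < 0.09
        col_half = np.r_[np.ones(50), np.zeros(50)].reshape(-1, 1)
        assert variance_threshold_fit(col_half, 0.9) == [0]  # var 0.25 >= 0.09
        col_80_zeros = np.r_[np.ones(20), np.zeros(80)].reshape(-1, 1)
        # variance exactly p(1-p) = 0.16: retention is non-strict
        assert variance_threshold_fit(col_80_zeros, 0.8) == [0]

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = float(rng.uniform(0.6, 0.95))
            X = (rng.random((60, 12)) < rng.uniform(0.02, 0.98, 12)).astype(float)
            expected = [
                j
                for j in range(X.shape[1])
                if np.mean((X[:, j] - X[:, j].mean()) ** 2) >= p * (1 - p) - 1e-12
            ]
            assert variance_threshold_fit(X, p) == expected

    def test_non_binary_column_named_in_error(self):
        X = np.zeros((10, 3))
        X[0, 1] = 0.5
        with pytest.raises(ValueError, match=r"\[1\]"):
            variance_threshold_fit(X, 0.8)


def test_pipeline_is_leakage_free():
    """Vocabulary and schemas come from training only; unseen codes map to UNK."""
    train = [
        timeline_with_codes([("ICD9CM", "272.4"), ("ICD10CM", "I10")], surveys=[("SQ001", "A1")]),
        timeline_with_codes([("ICD9CM", "272.4")], race="Asian", surveys=[("SQ001", "A2")]),
    ]
    pipe = FeaturePipeline(p_demo=0.6, p_survey=0.6).fit(train)
    test_tl = timeline_with_codes([("ICD10CM", "TESTONLY")], surveys=[("SQ002", "B7")])
    out = pipe.transform([test_tl])
    real = out["tokens"][0][out["mask"][0]]
    assert (real == UNK).all()
    assert out["survey"][0].sum() == 0  # unseen pair encodes as zeros
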
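"""Classifier contracts: masking, determinism, loss closed forms, gradients."""

import math

import numpy as np
import pytest

from painrisk import autograd as ag
from painrisk.autograd import Tensor
from painrisk.config import ModelConfig
from painrisk.model import Adam, TransformerClassifier, sinusoid_encoding, weighted_bce

TINY = ModelConfig(
    vocab_size=20,
    demo_dim=3,
    survey_dim=5,
    d_model=8,
    n_heads=2,
    n_layers=2,
    d_ff=6,
    dropout=0.1,
    seq_len=10,
    seed=3,
)


def tiny_batch(seed=0, B=4, cfg=TINY):
    rng = np.random.default_rng(seed)
    L = cfg.seq_len
    mask = np.ones((B, L), dtype=bool)
    mask[0, L // 2 :] = False
    tokens = rng.integers(2, cfg.vocab_size, (B, L))
    tokens[~mask] = 0
    ts = rng.integers(0, 1500, (B, L)).astype(np.float32)
    ts[~mask] = 0
    demo = rng.random((B, cfg.demo_dim)).astype(np.float32)
    survey = (rng.random((B, cfg.survey_dim)) < 0.3).astype(np.float32)
    return tokens, ts, mask, demo, survey


def test_outputs_are_probabilities_and_deterministic_in_eval_mode():
    model = TransformerClassifier(TINY)
    batch = tiny_batch()
    p1, _ = model.forward(*batch)
    p2, _ = model.forward(*batch)
    assert ((p1.data > 0) & (p1.data < 1)).all()
    np.testing.assert_array_equal(p1.data, p2.data)


def test_padded_positions_cannot_influence_the_output():
    model = TransformerClassifier(TINY)
    tokens, ts, mask, demo, survey = tiny_batch()
    base, _ = model.forward(tokens, ts, mask, demo, survey)
    perturbed = tokens.copy()
    perturbed[~mask] = 17  # arbitrary garbage at padded positions
    ts2 = ts.copy()
    ts2[~mask] = 999.0
    out, _ = model.forward(perturbed, ts2, mask, demo, survey)
    np.testing.assert_allclose(out.data, base.data, atol=1e-6)


def test_attention_rows_normalize_and_padded_keys_get_exact_zero():
    model = TransformerClassifier(TINY)
    tokens, ts, mask, demo, survey = tiny_batch()
    _, attn = model.forward(tokens, ts, mask, demo, survey, collect_attention=True)
    assert len(attn) == TINY.n_layers
    for layer in attn:
        assert (layer[0][:, :, ~mask[0]] == 0.0).all()
        np.testing.assert_allclose(layer.sum(axis=-1), 1.0, atol=1e-5)


def test_batch_permutation_equivariance():
    model = TransformerClassifier(TINY)
    tokens, ts, mask, demo, survey = tiny_batch(B=6)
    base, _ = model.forward(tokens, ts, mask, demo, survey)
    perm = np.array([3, 1, 5, 0, 2, 4])
    out, _ = model.forward(tokens[perm], ts[perm], mask[perm], demo[perm], survey[perm])
    np.testing.assert_allclose(out.data, base.data[perm], atol=1e-6)


def test_pad_embedding_row_stays_zero_through_training_steps():
    model = TransformerClassifier(TINY)
    assert (model.params["tok_emb"].data[0] == 0).all()
    opt = Adam(model.params, lr=0.01)
    tokens, ts, mask, demo, survey = tiny_batch()
    y = np.array([1, 0, 1, 0])
    rng = np.random.default_rng(0)
    for _ in range(3):
        probs, _ = model.forward(tokens, ts, mask, demo, survey, rng=rng)
        loss = weighted_bce(probs, y, 3.0)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert (model.params["tok_emb"].data[0] == 0).all()


def test_parameter_count_is_a_pure_function_of_config():
    a, b = TransformerClassifier(TINY), TransformerClassifier(TINY)
    assert a.n_parameters() == b.n_parameters()
    bigger = ModelConfig(vocab_size=21, demo_dim=3, survey_dim=5, d_model=8, n_heads=2,
                         n_layers=2, d_ff=6, seq_len=10, seed=3)
    assert TransformerClassifier(bigger).n_parameters() == a.n_parameters() + 8


def test_timestamp_zero_gives_alternating_sin_cos_pattern():
    enc = sinusoid_encoding(np.array([0.0]), 8)[0]
    np.testing.assert_allclose(enc[0::2], 0.0)
    np.testing.assert_allclose(enc[1::2], 1.0)


def test_equal_codes_at_different_timestamps_embed_differently():
    model = TransformerClassifier(TINY)
    x = model.embed_sequence(np.array([[5, 5]]), np.array([[10.0, 400.0]]))
    assert not np.allclose(x.data[0, 0], x.data[0, 1])


def test_all_pad_sequence_has_zero_token_component_and_pools_to_statics_only():
    model = TransformerClassifier(TINY)
    tokens = np.zeros((1, TINY.seq_len), dtype=int)
    ts = np.zeros((1, TINY.seq_len), dtype=np.float32)
    x = model.embed_sequence(tokens, ts)
    expected = model._posenc[: TINY.seq_len] + sinusoid_encoding(
        ts[0] / TINY.timestamp_scale, TINY.d_model
    )
    np.testing.assert_allclose(x.data[0], expected, atol=1e-6)
    # forward still yields a valid probability via the static branches
    mask = np.zeros((1, TINY.seq_len), dtype=bool)
    demo = np.ones((1, TINY.demo_dim), dtype=np.float32)
    survey = np.zeros((1, TINY.survey_dim), dtype=np.float32)
    p, _ = model.forward(tokens, ts, mask, demo, survey)
    assert 0 < float(p.data[0]) < 1


def test_token_out_of_vocabulary_raises():
    model = TransformerClassifier(TINY)
    tokens, ts, mask, demo, survey = tiny_batch()
    tokens[0, 0] = TINY.vocab_size
    with pytest.raises(IndexError):
        model.forward(tokens, ts, mask, demo, survey)


class TestWeightedBCE:
    @pytest.fixture(autouse=True)
    def _float64(self):
        ag.set_default_dtype(np.float64)
        yield
        ag.set_default_dtype(np.float32)

    def test_closed_forms(self):
        assert float(weighted_bce(Tensor([0.5]), np.array([1.0]), 3.0).data) == pytest.approx(
            3 * math.log(2), abs=1e-9
        )
        # the weight touches only the positive term
        assert float(weighted_bce(Tensor([0.5]), np.array([0.0]), 7.0).data) == pytest.approx(
            math.log(2), abs=1e-9
        )

    def test_weight_one_equals_unweighted_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, 64)
        y = rng.integers(0, 2, 64).astype(float)
        ours = float(weighted_bce(Tensor(p), y, 1.0).data)
        ref = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_gradient_scales_linearly_with_pos_weight(self):
        logit = Tensor(np.array([0.3]), requires_grad=True)
        grads = []
        for w in (1.0, 2.0, 4.0):
            logit.grad = None
            weighted_bce(logit.sigmoid(), np.array([1.0]), w).backward()
            grads.append(float(logit.grad[0]))
        assert grads[1] == pytest.approx(2 * grads[0], rel=1e-6)
        assert grads[2] == pytest.approx(4 * grads[0], rel=1e-6)

    def test_extreme_probabilities_are_clamped(self):
        loss = weighted_bce(Tensor([1.0, 0.0]), np.array([0.0, 1.0]), 1.0)
        assert np.isfinite(loss.data)


def test_model_gradients_match_finite_differences():
    """End-to-end gradient check of the full forward pass in float64."""
    ag.set_default_dtype(np.float64)
    try:
        model = TransformerClassifier(TINY)
        for t in model.params.values():
            t.data = t.data.astype(np.float64)
        tokens, ts, mask, demo, survey = tiny_batch(B=3)
        y = np.array([1.0, 0.0, 1.0])

        def loss_value():
            p, _ = model.forward(tokens, ts, mask, demo, survey)
            return float(weighted_bce(p, y, 3.0).data)

        probs, _ = model.forward(tokens, ts, mask, demo, survey)
        loss = weighted_bce(probs, y, 3.0)
        for t in model.params.values():
            t.grad = None
        loss.backward()
        rng = np.random.default_rng(1)
        for name, t in model.params.items():
            grad = t.grad if t.grad is not None else np.zeros_like(t.data)
            flat = t.data.reshape(-1)
            for _ in range(min(3, flat.size)):
                i = int(rng.integers(0, flat.size))
                if name == "tok_emb" and i < TINY.d_model:
                    continue  # PAD row is frozen
                eps = 1e-6
                old = flat[i]
                flat[i] = old + eps
                fp = loss_value()
                flat[i] = old - eps
                fm = loss_value()
                flat[i] = old
                num = (fp - fm) / (2 * eps)
                ana = float(grad.reshape(-1)[i])
                assert num == pytest.approx(ana, rel=1e-3, abs=1e-7), name
    finally:
        ag.set_default_dtype(np.float32)


def test_save_load_roundtrip(tmp_path):
    model = TransformerClassifier(TINY)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = TransformerClassifier.load(path)
    assert loaded.config == TINY
    batch = tiny_batch()
    np.testing.assert_array_equal(model.forward(*batch)[0].data, loaded.forward(*batch)[0].data)


def test_load_rejects_incompatible_state(tmp_path):
    model = TransformerClassifier(TINY)
    state = model.state_dict()
    del state["head.W"]
    with pytest.raises(KeyError):
        model.load_state_dict(state)
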
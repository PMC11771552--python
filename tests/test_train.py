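"""Splitting, metrics, AUROC oracle and training-loop contracts."""

import numpy as np
import pytest

from painrisk.config import ModelConfig, TrainConfig
from painrisk.model import TransformerClassifier
from painrisk.train import (
    auroc,
    evaluate,
    pos_weight_sweep,
    report_from_scores,
    split_dataset,
    take,
    train,
)


class TestSplitDataset:
    def test_sizes_follow_fractions(self):
        labels = np.r_[np.ones(500), np.zeros(500)]
        tr, va, te = split_dataset(labels, seed=0)
        assert (len(tr), len(va), len(te)) == (700, 50, 250)
        assert len(set(tr) | set(va) | set(te)) == 1000  # disjoint and exhaustive

    def test_stratification_preserves_prevalence(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(1000) < 0.176).astype(int)
        overall = labels.mean()
        for idx in split_dataset(labels, seed=1):
            assert abs(labels[idx].mean() - overall) <= 0.02

    def test_same_seed_gives_identical_membership(self):
        labels = np.tile([0, 0, 0, 0, 1], 40)
        a = split_dataset(labels, seed=9)
        b = split_dataset(labels, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_all_negative_split_warns(self):
        labels = np.r_[np.ones(2), np.zeros(98)]
        with pytest.warns(UserWarning, match="zero positive"):
            split_dataset(labels, seed=0)


class TestAuroc:
    def test_three_of_four_pairs_ordered(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auroc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_random_scores_hover_near_half(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.ones(1000), np.zeros(1000)]
        assert 0.45 <= auroc(labels, rng.random(2000)) <= 0.55

    def test_matches_pairwise_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [(0.5 if a == b else float(a > b)) for a in pos for b in neg]
            assert auroc(labels, scores) == pytest.approx(np.mean(pairs))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert auroc(labels, scores) == pytest.approx(auroc(labels, np.exp(3 * scores)))

    def test_single_class_is_undefined(self):
        with pytest.raises(ValueError, match="one class"):
            auroc([1, 1], [0.2, 0.4])


class TestEvaluate:
    def test_perfect_separation(self):
        rep = report_from_scores([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 0.5)
        assert rep.accuracy == 1.0 and rep.auroc == 1.0
        assert rep.confusion == (2, 0, 0, 2)

    def test_mixed_case_and_confusion_consistency(self):
        rep = report_from_scores([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1], 0.5)
        tn, fp, fn, tp = rep.confusion
        assert tn + fp + fn + tp == rep.n
        assert rep.accuracy == pytest.approx((tp + tn) / rep.n)
        assert rep.precision == pytest.approx(tp / (tp + fp))
        assert rep.recall == pytest.approx(tp / (tp + fn))
        assert rep.auroc == pytest.approx(0.75)

    def test_degenerate_denominators_reported_as_zero_with_flag(self):
        rep = report_from_scores([1, 1, 0], [0.1, 0.2, 0.3], 0.5)
        assert rep.precision == 0.0 and rep.recall == 0.0
        assert "precision" in rep.undefined

    def test_single_class_auroc_reported_as_none(self):
        rep = report_from_scores([1, 1], [0.9, 0.8], 0.5)
        assert rep.auroc is None and "auroc" in rep.undefined


def toy_separable_data(cfg: ModelConfig, n=12):
    """Half the patients carry a single signal token; labels follow it exactly."""
    L = cfg.seq_len
    tokens = np.full((n, L), 3, dtype=int)
    labels = np.arange(n) % 2
    tokens[labels == 1, 0] = 2  # the signal code
    ts = np.tile(np.arange(L, 0, -1, dtype=np.float32), (n, 1))
    mask = np.ones((n, L), dtype=bool)
    demo = np.zeros((n, cfg.demo_dim), dtype=np.float32)
    survey = np.zeros((n, cfg.survey_dim), dtype=np.float32)
    return {
        "tokens": tokens,
        "timestamps": ts,
        "mask": mask,
        "demo": demo,
        "survey": survey,
        "labels": labels,
    }


TOY = ModelConfig(
    vocab_size=6, demo_dim=2, survey_dim=2, d_model=8, n_heads=2, n_layers=2,
    d_ff=6, dropout=0.0, seq_len=8, seed=0,
)


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        batch = toy_separable_data(TOY)
        tc = TrainConfig(seed=1, learning_rate=0.0, epochs=2, batch_size=4)
        model, _ = train(TOY, tc, batch)
        np.testing.assert_array_equal(
            model.params["head.W"].data, TransformerClassifier(TOY).params["head.W"].data
        )

    def test_loss_decreases_on_separable_toy_problem(self):
        batch = toy_separable_data(TOY)
        tc = TrainConfig(seed=1, epochs=6, batch_size=4, pos_weight=1.0)
        _, history = train(TOY, tc, batch)
        losses = history["train_loss"].tolist()
        assert all(b < a for a, b in zip(losses[:5], losses[1:6]))

    def test_identical_seeds_reproduce_identical_history(self):
        batch = toy_separable_data(TOY)
        tc = TrainConfig(seed=4, epochs=3, batch_size=4)
        _, h1 = train(TOY, tc, batch, batch)
        _, h2 = train(TOY, tc, batch, batch)
        assert h1.equals(h2)

    def test_best_validation_epoch_parameters_are_returned(self):
        batch = toy_separable_data(TOY, n=16)
        tc = TrainConfig(seed=2, epochs=5, batch_size=4)
        model, history = train(TOY, tc, batch, batch)
        best = history["val_auroc"].max()
        rep = evaluate(model, batch, split="validation")
        assert rep.auroc == pytest.approx(best, abs=1e-9)

    def test_sweep_single_weight_matches_independent_run(self):
        batch = toy_separable_data(TOY, n=16)
        tc = TrainConfig(seed=3, epochs=3, batch_size=4, pos_weight=1.0)
        table = pos_weight_sweep(TOY, tc, batch, batch, batch, weights=(1.0,))
        assert len(table) == 1
        model, _ = train(TOY, tc, batch, batch)
        rep = evaluate(model, batch, tc.decision_threshold, "test")
        assert table.loc[0, "test_auroc"] == pytest.approx(rep.auroc)
        assert table.loc[0, "test_recall"] == pytest.approx(rep.recall)


def test_take_subsets_every_array():
    batch = {"a": np.arange(10), "b": np.arange(20).reshape(10, 2)}
    sub = take(batch, np.array([1, 3]))
    np.testing.assert_array_equal(sub["a"], [1, 3])
    assert sub["b"].shape == (2, 2)
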
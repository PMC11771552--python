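"""Dataset splitting, training loop, evaluation metrics and the pos-weight sweep.

The dataset is split 70/5/25 (train/validation/test) with label
stratification; the classifier is optimized with Adam at a constant learning
rate of 0.001 for 20 epochs of minibatch class-weighted cross-entropy
(positive weight 3.0 by default, sweep set {1, 3, 5}); the parameters kept
are those of the epoch with the best validation AUROC.  Metrics: accuracy,
AUROC (rank-based, ties counted one half), precision, recall and the
confusion matrix at a fixed decision threshold of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ModelConfig, TrainConfig
from .model import Adam, TransformerClassifier, weighted_bce

__all__ = [
    "EvalReport",
    "auroc",
    "evaluate",
    "pos_weight_sweep",
    "split_dataset",
    "take",
    "train",
]


def take(batch: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    """Row-subset every array in a prepared batch."""
    return {k: v[idx] for k, v in batch.items()}


def split_dataset(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.05, 0.25),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, disjoint, exhaustive train/validation/test indices.

    Within each label class the shuffled members are allocated by largest
    remainder, so split sizes match the fractions to within rounding and each
    split's prevalence tracks the overall prevalence.
    """
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        n = len(members)
        ideal = np.array([f * n for f in fractions])
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        # hand out the leftover slots by largest fractional part
        for j in np.argsort(-remainder)[: n - counts.sum()]:
            counts[j] += 1
        edges = np.concatenate([[0], np.cumsum(counts)])
        for s in range(3):
            parts[s].append(members[edges[s] : edges[s + 1]])
    out = tuple(np.sort(np.concatenate(p)) for p in parts)
    for name, idx in zip(("train", "validation", "test"), out):
        if len(idx) and labels[idx].sum() == 0 and labels.sum() > 0:
            import warnings

            warnings.warn(f"split '{name}' received zero positive cases", stacklevel=2)
    return out


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(random positive outscores random negative), ties half.

    Raises ``ValueError`` if only one class is present.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Threshold metrics plus AUROC for one split.

    ``auroc`` is None when the split contains a single class.  When a
    denominator is empty (no predicted positives / no true positives) the
    corresponding metric is reported as 0.0 and listed in ``undefined``.
    """

    split: str
    threshold: float
    n: int
    accuracy: float
    auroc: float | None
    precision: float
    recall: float
    confusion: tuple[int, int, int, int]  # (TN, FP, FN, TP)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {
            "split": self.split,
            "threshold": self.threshold,
            "n": self.n,
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "precision": self.precision,
            "recall": self.recall,
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "tp": tp,
        }


def evaluate(
    model: TransformerClassifier,
    batch: dict[str, np.ndarray],
    threshold: float = 0.5,
    split: str = "test",
) -> EvalReport:
    """Score a prepared split at the given decision threshold."""
    labels = np.asarray(batch["labels"]).astype(bool)
    scores = model.predict_proba(batch)
    return report_from_scores(labels, scores, threshold, split)


def report_from_scores(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5, split: str = "test"
) -> EvalReport:
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    undefined = []
    precision = tp / (tp + fp) if tp + fp else 0.0
    if tp + fp == 0:
        undefined.append("precision")
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fn == 0:
        undefined.append("recall")
    try:
        auc = auroc(labels, scores)
    except ValueError:
        auc = None
        undefined.append("auroc")
    return EvalReport(
        split=split,
        threshold=threshold,
        n=len(labels),
        accuracy=(tp + tn) / len(labels),
        auroc=auc,
        precision=precision,
        recall=recall,
        confusion=(tn, fp, fn, tp),
        undefined=tuple(undefined),
    )


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_batch: dict[str, np.ndarray],
    val_batch: dict[str, np.ndarray] | None = None,
) -> tuple[TransformerClassifier, pd.DataFrame]:
    """Minibatch training; returns the best-validation-AUROC model and history.

    History records per-epoch mean training loss and validation AUROC.  When
    no validation batch is given (or its AUROC is undefined) the final-epoch
    parameters are kept.  A non-finite loss aborts with a diagnostic.
    """
    model = TransformerClassifier(model_config)
    opt = Adam(model.params, lr=train_config.learning_rate)
    seq = np.random.SeedSequence(train_config.seed)
    shuffle_seq, dropout_seq = seq.spawn(2)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    # SFC64: dropout burns through large uniform blocks every step
    dropout_rng = np.random.Generator(np.random.SFC64(dropout_seq))

    n = len(train_batch["labels"])
    labels = np.asarray(train_batch["labels"], dtype=np.float32)
    history = []
    best = (-np.inf, None)
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        micro = min(train_config.batch_size, 64)  # cache-friendly micro-batches
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            # gradient accumulation: identical update to one big batch, since
            # chunk losses are weighted by chunk size before summing
            for mstart in range(0, len(idx), micro):
                sub = idx[mstart : mstart + micro]
                mb = take(train_batch, sub)
                probs, _ = model.forward(
                    mb["tokens"],
                    mb["timestamps"],
                    mb["mask"],
                    mb["demo"],
                    mb["survey"],
                    rng=dropout_rng if model_config.dropout > 0 else None,
                )
                loss = weighted_bce(probs, labels[sub], train_config.pos_weight) * (
                    len(sub) / len(idx)
                )
                loss.backward()
                batch_loss += float(loss.data)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {start}"
                )
            opt.step()
            losses.append(batch_loss)
        val_auc = np.nan
        if val_batch is not None:
            rep = evaluate(model, val_batch, train_config.decision_threshold, "validation")
            if rep.auroc is not None:
                val_auc = rep.auroc
                if val_auc > best[0]:
                    best = (val_auc, model.state_dict())
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auroc": val_auc}
        )
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, pd.DataFrame(history)


def pos_weight_sweep(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_batch: dict[str, np.ndarray],
    val_batch: dict[str, np.ndarray],
    test_batch: dict[str, np.ndarray],
    weights: tuple[float, ...] = (1.0, 3.0, 5.0),
) -> pd.DataFrame:
    """Full train+evaluate per positive weight, all else (seeds, splits) fixed.

    Reports training-set and test-set metrics side by side.  The positive
    weight trades precision for recall most visibly on the training split,
    where the weighted loss acts directly; this weight exploration is
    conventionally read off the training set.  Pass ``val_batch=None`` (the
    fixed-epoch protocol) to keep each weight's final-epoch parameters, so
    the comparison is not confounded by per-weight epoch selection.
    """
    from dataclasses import replace

    rows = []
    for w in weights:
        cfg = replace(train_config, pos_weight=w)
        model, _ = train(model_config, cfg, train_batch, val_batch)
        row = {"pos_weight": w}
        for split, batch in (("train", train_batch), ("test", test_batch)):
            rep = evaluate(model, batch, cfg.decision_threshold, split)
            row.update(
                {
                    f"{split}_accuracy": rep.accuracy,
                    f"{split}_auroc": rep.auroc,
                    f"{split}_precision": rep.precision,
                    f"{split}_recall": rep.recall,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
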
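"""Interpretability: permutation importance and strongest attention connections.

Permutation importance scores each static feature (age, retained demographic
one-hots, retained survey question-answer pairs) by the drop in AUROC when
that feature's column is shuffled across patients, repeated several times
with a seeded generator.  Attention analysis averages the final encoder
layer's heads and reports the k strongest connections between real (unpadded,
non-diagonal) sequence positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import Vocabulary
from .model import TransformerClassifier
from .train import auroc

__all__ = [
    "AttentionReport",
    "attention_weights",
    "permutation_importance",
    "top_connections",
]


def permutation_importance(
    model: TransformerClassifier,
    batch: dict[str, np.ndarray],
    feature_names: list[str] | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC-drop importance for every static feature column.

    Returns a frame (feature, importance, std, rank) sorted by decreasing
    importance; importance = base AUROC - mean permuted AUROC over
    ``repeats`` shuffles.  Constant columns score exactly 0 because shuffling
    them is the identity.  The pooled sequence encoding is computed once and
    reused, since shuffling static columns does not touch the encoder.
    """
    labels = np.asarray(batch["labels"]).astype(bool)
    pooled = model.encode_pooled(batch)
    demo, survey = batch["demo"], batch["survey"]
    base = auroc(labels, model.head_proba(pooled, demo, survey))
    n_demo = demo.shape[1]
    n_total = n_demo + survey.shape[1]
    if feature_names is None:
        feature_names = [f"static_{j}" for j in range(n_total)]
    if len(feature_names) != n_total:
        raise ValueError(f"expected {n_total} feature names, got {len(feature_names)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for j in range(n_total):
        drops = []
        for _ in range(repeats):
            perm = rng.permutation(len(labels))
            d, s = demo, survey
            if j < n_demo:
                d = demo.copy()
                d[:, j] = demo[perm, j]
            else:
                s = survey.copy()
                s[:, j - n_demo] = survey[perm, j - n_demo]
            drops.append(base - auroc(labels, model.head_proba(pooled, d, s)))
        rows.append(
            {
                "feature": feature_names[j],
                "importance": float(np.mean(drops)),
                "std": float(np.std(drops)),
            }
        )
    report = pd.DataFrame(rows).sort_values(
        ["importance", "feature"], ascending=[False, True], kind="mergesort"
    )
    report["rank"] = np.arange(1, len(report) + 1)
    return report.reset_index(drop=True)


def attention_weights(
    model: TransformerClassifier,
    tokens: np.ndarray,
    timestamps: np.ndarray,
    mask: np.ndarray,
) -> list[np.ndarray]:
    """Per-layer (heads, L, L) attention matrices for one sequence, eval mode.

    Each unmasked row sums to 1; columns at padded key positions are exactly 0.
    """
    _, attn = model._pool(
        tokens[None] if tokens.ndim == 1 else tokens,
        timestamps[None] if timestamps.ndim == 1 else timestamps,
        mask[None] if mask.ndim == 1 else mask,
        collect_attention=True,
    )
    return [a[0] for a in attn]


@dataclass
class AttentionReport:
    """Top attention connections: (source, target, source_code, target_code, weight)."""

    entries: list[tuple[int, int, str, str, float]]
    truncated: bool = False  # fewer eligible pairs than requested


def top_connections(
    attn,
    mask: np.ndarray,
    k: int = 5,
    tokens: np.ndarray | None = None,
    vocab: Vocabulary | None = None,
) -> AttentionReport:
    """The k strongest connections between real sequence positions.

    ``attn`` is either the per-layer list from :func:`attention_weights`
    (heads of the final layer are averaged) or an already-averaged (L, L)
    matrix.  The diagonal and any pair touching a padded position are
    excluded; ties break by (source, target) position order.  Code names are
    attached when ``tokens`` and ``vocab`` are given.
    """
    if isinstance(attn, list):
        avg = np.asarray(attn[-1]).mean(axis=0)
    else:
        avg = np.asarray(attn)
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    L = avg.shape[0]
    names = [""] * L
    if tokens is not None and vocab is not None:
        inverse = {t: key for key, t in vocab.token_of.items()}
        inverse.update({0: "PAD", 1: "UNK"})
        names = [inverse.get(int(t), "UNK") for t in np.asarray(tokens).reshape(-1)]
    pairs = [
        (float(avg[i, j]), i, j)
        for i in range(L)
        for j in range(L)
        if i != j and mask[i] and mask[j]
    ]
    pairs.sort(key=lambda e: (-e[0], e[1], e[2]))
    entries = [(i, j, names[i], names[j], w) for w, i, j in pairs[: max(k, 0)]]
    return AttentionReport(entries=entries, truncated=len(pairs) < k)
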
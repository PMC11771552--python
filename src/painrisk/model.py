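"""Encoder-only attention classifier over diagnosis-code sequences.

Architecture: token embeddings (PAD row fixed at zero) summed with a
sinusoidal positional encoding of the sequence position and a sinusoidal
encoding of the days-until-diagnosis timestamp; a stack of post-norm
transformer encoder layers (multi-head self-attention with padded keys
masked out, then a two-layer feedforward, residual connections and layer
norm); masked mean pooling over real positions; two small feedforward
branches for the demographic and survey vectors; concatenation of the three
representations; a final linear layer and a sigmoid.

Defaults (4 heads, 2 layers, feedforward width 32, dropout 0.1, static hidden
width 4) live in :class:`painrisk.config.ModelConfig`.  The model runs on the
package's own numpy autodiff (:mod:`painrisk.autograd`); all randomness —
initialization and dropout — is explicitly seeded.
"""

from __future__ import annotations

import io
import json
import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import ModelConfig

__all__ = ["Adam", "TransformerClassifier", "sinusoid_encoding", "weighted_bce"]



def sinusoid_encoding(values: np.ndarray, d_model: int) -> np.ndarray:
    """Sinusoidal encoding of arbitrary non-negative values (positions or days).

    Channel 2i holds sin(v / 10000^(2i/d)), channel 2i+1 the matching cosine,
    so unbounded day counts need no bucket vocabulary.
    """
    values = np.asarray(values, dtype=np.float64)
    half = d_model // 2
    freqs = np.exp(-math.log(10000.0) * (2 * np.arange(half) / d_model))
    angles = values[..., None] * freqs
    enc = np.empty(values.shape + (d_model,), dtype=np.float32)
    enc[..., 0::2] = np.sin(angles)
    enc[..., 1::2] = np.cos(angles[..., : d_model - half])
    return enc


class TransformerClassifier:
    """The chronic-pain risk classifier; parameters seeded from the config."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        d, dff = config.d_model, config.d_ff
        self.params: dict[str, Tensor] = {}

        def add(name, shape, fan_in):
            bound = 1.0 / math.sqrt(fan_in)
            self.params[name] = Tensor(
                rng.uniform(-bound, bound, shape).astype(np.float32), requires_grad=True
            )

        add("tok_emb", (config.vocab_size, d), d)
        self.params["tok_emb"].data[0] = 0.0  # PAD row stays zero
        for layer in range(config.n_layers):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                add(f"l{layer}.{w}", (d, d), d)
                add(f"l{layer}.{w}_b", (d,), d)
            add(f"l{layer}.ff1", (d, dff), d)
            add(f"l{layer}.ff1_b", (dff,), d)
            add(f"l{layer}.ff2", (dff, d), dff)
            add(f"l{layer}.ff2_b", (d,), dff)
            for ln in ("ln1", "ln2"):
                self.params[f"l{layer}.{ln}_g"] = Tensor(np.ones(d, np.float32), requires_grad=True)
                self.params[f"l{layer}.{ln}_b"] = Tensor(np.zeros(d, np.float32), requires_grad=True)
        add("demo.W", (config.demo_dim, config.demo_hidden), max(config.demo_dim, 1))
        add("demo.b", (config.demo_hidden,), max(config.demo_dim, 1))
        add("survey.W", (config.survey_dim, config.survey_hidden), max(config.survey_dim, 1))
        add("survey.b", (config.survey_hidden,), max(config.survey_dim, 1))
        head_in = d + config.demo_hidden + config.survey_hidden
        add("head.W", (head_in, 1), head_in)
        add("head.b", (1,), head_in)
        # positional encoding is a fixed buffer
        self._posenc = sinusoid_encoding(np.arange(config.seq_len), d)

    # ------------------------------------------------------------------ utils
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].astype(np.float32).copy()

    def save(self, path) -> None:
        """Single-file checkpoint with the config embedded."""
        with open(path, "wb") as fh:
            meta = json.dumps(self.config.__dict__).encode()
            np.savez(fh, __config__=np.frombuffer(meta, dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> "TransformerClassifier":
        with np.load(path) as data:
            meta = json.loads(io.BytesIO(data["__config__"].tobytes()).read().decode())
            config = ModelConfig(**meta)
            model = cls(config)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model

    # ---------------------------------------------------------------- forward
    def embed_sequence(self, tokens: np.ndarray, timestamps: np.ndarray) -> Tensor:
        """Token embedding + positional encoding + timestamp encoding.

        Token embeddings are scaled by sqrt(d_model), the usual convention
        that keeps them commensurate with the unit-amplitude sinusoids.
        Timestamps are divided by ``timestamp_scale`` (days) before encoding
        so the finest sinusoid wavelength stays above day-to-day noise:
        events a few days apart should look temporally similar.
        """
        if tokens.max(initial=0) >= self.config.vocab_size:
            raise IndexError("token id outside the vocabulary")
        x = ag.embedding(self.params["tok_emb"], tokens) * np.float32(
            math.sqrt(self.config.d_model)
        )
        x = x + Tensor(self._posenc[None, : tokens.shape[1]])
        x = x + Tensor(
            sinusoid_encoding(timestamps / self.config.timestamp_scale, self.config.d_model)
        )
        return x

    def _attention(self, x: Tensor, layer: int, key_mask: np.ndarray, rng, attn_out):
        cfg = self.config
        B, L, d = x.shape
        H, dk = cfg.n_heads, cfg.d_model // cfg.n_heads
        p = self.params

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dk).transpose(0, 2, 1, 3)  # (B,H,L,dk)

        # fold the 1/sqrt(dk) scale into q while it is still small
        q = heads((x @ p[f"l{layer}.Wq"] + p[f"l{layer}.Wq_b"]) * np.float32(1.0 / math.sqrt(dk)))
        k = heads(x @ p[f"l{layer}.Wk"] + p[f"l{layer}.Wk_b"])
        v = heads(x @ p[f"l{layer}.Wv"] + p[f"l{layer}.Wv_b"])
        scores = q @ k.transpose(0, 1, 3, 2)
        # padded keys get exactly 0 attention; all-padded rows are all zeros
        probs = ag.masked_softmax_lastaxis(scores, key_mask[:, None, None, :])
        if attn_out is not None:
            attn_out.append(probs.data.copy())
        # one dropout mask shared across heads keeps mask generation cheap
        dropped = ag.dropout(probs, cfg.dropout, rng, mask_shape=(B, 1, L, L))
        ctx = (dropped @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        out = ctx @ p[f"l{layer}.Wo"] + p[f"l{layer}.Wo_b"]
        return ag.dropout(out, cfg.dropout, rng)

    def forward(
        self,
        tokens: np.ndarray,
        timestamps: np.ndarray,
        mask: np.ndarray,
        demo: np.ndarray,
        survey: np.ndarray,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> tuple[Tensor, list[np.ndarray] | None]:
        """Predicted chronic-pain probability per patient, strictly in (0, 1).

        ``rng`` enables dropout (training mode); evaluation passes None.
        Returns (probabilities, attention) where attention is a list of
        (batch, heads, L, L) arrays per layer when requested.
        """
        pooled, attn = self._pool(tokens, timestamps, mask, rng, collect_attention)
        return self._head(pooled, demo, survey), attn

    def _pool(self, tokens, timestamps, mask, rng=None, collect_attention=False):
        """Run the encoder and mean-pool over unmasked positions."""
        cfg = self.config
        p = self.params
        key_mask = np.asarray(mask, dtype=bool)
        x = self.embed_sequence(np.asarray(tokens), np.asarray(timestamps, dtype=np.float32))
        x = ag.dropout(x, cfg.dropout, rng)  # on the embedding/encoding sums
        attn: list[np.ndarray] | None = [] if collect_attention else None
        for layer in range(cfg.n_layers):
            a = self._attention(x, layer, key_mask, rng, attn)
            x = ag.layer_norm(x + a, p[f"l{layer}.ln1_g"], p[f"l{layer}.ln1_b"])
            f = (x @ p[f"l{layer}.ff1"] + p[f"l{layer}.ff1_b"]).relu()
            f = f @ p[f"l{layer}.ff2"] + p[f"l{layer}.ff2_b"]
            x = ag.layer_norm(x + ag.dropout(f, cfg.dropout, rng), p[f"l{layer}.ln2_g"], p[f"l{layer}.ln2_b"])
        # mean over unmasked positions; empty sequences pool to a zero vector
        maskf = Tensor(key_mask[..., None].astype(np.float32))
        counts = Tensor(np.maximum(key_mask.sum(axis=1, keepdims=True), 1).astype(np.float32))
        return (x * maskf).sum(axis=1) / counts, attn

    def _head(self, pooled: Tensor, demo: np.ndarray, survey: np.ndarray) -> Tensor:
        # the static branches are linear feature maps into width-4 vectors
        p = self.params
        demo_h = Tensor(demo) @ p["demo.W"] + p["demo.b"]
        survey_h = Tensor(survey) @ p["survey.W"] + p["survey.b"]
        z = ag.concat([pooled, demo_h, survey_h], axis=-1)
        logit = (z @ p["head.W"] + p["head.b"]).reshape(-1)
        return logit.sigmoid()

    def encode_pooled(self, batch: dict[str, np.ndarray], batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode pooled sequence representations (n, d_model).

        The pooled encoding depends only on the code sequence, so callers that
        vary the static inputs (e.g. permutation importance) can compute it
        once and reuse it via :meth:`head_proba`.
        """
        out = []
        n = len(batch["tokens"])
        for i in range(0, n, batch_size):
            sl = slice(i, i + batch_size)
            pooled, _ = self._pool(batch["tokens"][sl], batch["timestamps"][sl], batch["mask"][sl])
            out.append(pooled.data)
        return np.concatenate(out)

    def head_proba(self, pooled: np.ndarray, demo: np.ndarray, survey: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities from precomputed pooled encodings."""
        return self._head(Tensor(pooled), demo, survey).data

    def predict_proba(self, batch: dict[str, np.ndarray], batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode probabilities for a whole prepared dataset."""
        out = []
        n = len(batch["tokens"])
        for i in range(0, n, batch_size):
            sl = slice(i, i + batch_size)
            probs, _ = self.forward(
                batch["tokens"][sl],
                batch["timestamps"][sl],
                batch["mask"][sl],
                batch["demo"][sl],
                batch["survey"][sl],
            )
            out.append(probs.data)
        return np.concatenate(out)


def weighted_bce(probs: Tensor, labels: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Class-weighted binary cross-entropy, mean over the batch.

    loss = -mean( w * y * log p + (1 - y) * log(1 - p) ); probabilities are
    clamped to [1e-7, 1 - 1e-7] for numerical safety.
    """
    y = Tensor(np.asarray(labels, dtype=np.float32))
    p = probs.clip(1e-7, 1.0 - 1e-7)
    loss = -(y * p.log() * np.float32(pos_weight) + (1.0 - y) * (1.0 - p).log())
    return loss.mean()


class Adam:
    """Adam with the standard moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if k == "tok_emb":
                g = g.copy()
                g[0] = 0.0  # PAD embedding is frozen at zero
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
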
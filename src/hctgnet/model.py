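"""The beat classifier: residual CNN branch, Transformer branch, gated fusion.

The network ingests one z-scored 188-sample heartbeat (a single channel) and
produces probabilities over the five AAMI classes.  Two branches run in
parallel:

* **CNN branch** — a stem convolution (1→64 channels, kernel 7) followed by
  three residual blocks (64→64 stride 1, 64→128 stride 2, 128→256 stride 1),
  each two kernel-3 convolutions with batch normalisation and ReLU plus a
  skip connection (identity, or a strided 1x1 convolution when the shape
  changes).  Global average pooling yields ``c`` in R^256.
* **Transformer branch** — each scalar sample is embedded into d_model = 128,
  sinusoidal positional encoding is added, and two post-norm encoder layers
  (4-head self-attention, feed-forward width 256, dropout 0.1) are applied;
  average pooling over the 188 positions yields ``t`` in R^128.

A gated fusion module projects both vectors into a shared 256-dimensional
space (``c_tilde = W_c c``, ``t_tilde = W_t t``), computes a per-dimension
gate ``g = sigmoid(MLP([c_tilde; t_tilde]))`` with an MLP of shape
512→256→256, and fuses ``f = g * c_tilde + (1 - g) * t_tilde``.  A classifier
head (256→128, ReLU, dropout 0.3, 128→5) ends in a softmax.

Ablation variants re-wire the same components: ``cnn_only`` classifies ``c``
directly, ``transformer_only`` classifies ``t``, and ``concat_no_gate``
classifies the plain concatenation ``[c_tilde; t_tilde]``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import (Dropout, LayerNorm, Linear, Module, Tensor,
                        global_avg_pool)
from .wfdb_io import CLASSES

VARIANTS = ("full", "cnn_only", "transformer_only", "concat_no_gate")


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter, with the published defaults."""

    input_length: int = 188
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 1
    stem_padding: int = 3
    res_blocks: tuple[tuple[int, int, int], ...] = (
        (64, 64, 1), (64, 128, 2), (128, 256, 1))   # (C_in, C_out, stride)
    d_model: int = 128
    n_transformer_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 256
    transformer_dropout: float = 0.1
    fusion_dim: int = 256
    classifier_hidden: int = 128
    classifier_dropout: float = 0.3
    n_classes: int = 5
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("input_length", "stem_channels", "d_model", "n_heads",
                     "ffn_dim", "fusion_dim", "classifier_hidden", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def cnn_feature_dim(self) -> int:
        return self.res_blocks[-1][1]

    @property
    def classifier_input_dim(self) -> int:
        return {"full": self.fusion_dim,
                "cnn_only": self.cnn_feature_dim,
                "transformer_only": self.d_model,
                "concat_no_gate": 2 * self.fusion_dim}[self.variant]


@dataclass
class FusionState:
    """All intermediates of the gated fusion, for inspection."""

    c: np.ndarray
    t: np.ndarray
    c_tilde: np.ndarray
    t_tilde: np.ndarray
    g: np.ndarray
    f: np.ndarray


# ---------------------------------------------------------------------------
# Deterministic pieces
# ---------------------------------------------------------------------------

def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding matrix of shape [length, d_model].

    Entry (pos, 2i) = sin(pos / 10000^(2i/d_model)) and entry (pos, 2i+1) the
    matching cosine.
    """
    if d_model % 2:
        raise ValueError("d_model must be even for sinusoidal encoding")
    if length < 1:
        raise ValueError("length must be >= 1")
    pos = np.arange(length)[:, None].astype(float)
    i2 = np.arange(0, d_model, 2).astype(float)
    angles = pos / np.power(10000.0, i2 / d_model)
    pe = np.empty((length, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention on plain arrays.

    ``softmax(Q K^T / sqrt(d_k)) V`` with the softmax over the key axis.
    Shapes: q [..., T, d_k], k [..., S, d_k], v [..., S, d_v].
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    for name, a in (("Q", q), ("K", k), ("V", v)):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite values in {name}")
    return ad.attention_core(Tensor(q), Tensor(k), Tensor(v)).data


def attention_weights(q: np.ndarray, k: np.ndarray) -> np.ndarray:
    """The softmax attention matrix alone (each row sums to 1)."""
    q, k = np.asarray(q, dtype=float), np.asarray(k, dtype=float)
    d_k = q.shape[-1]
    scores = np.matmul(q, np.swapaxes(k, -1, -2)) / np.sqrt(d_k)
    return ad.softmax(Tensor(scores), axis=-1).data


# ---------------------------------------------------------------------------
# Branch modules
# ---------------------------------------------------------------------------

class ResidualBlock(Module):
    """Two kernel-3 convolutions with BN/ReLU and a skip connection.

    ``y = ReLU(F(x) + W_down x)``; the skip is the identity when the channel
    count and temporal length are unchanged, otherwise a 1x1 convolution with
    the block's stride.
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = ad.Conv1d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.bn1 = ad.BatchNorm1d(c_out)
        self.conv2 = ad.Conv1d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.bn2 = ad.BatchNorm1d(c_out)
        if c_in == c_out and stride == 1:
            self.downsample = None
        else:
            self.downsample = ad.Conv1d(c_in, c_out, 1, rng, stride=stride,
                                        bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        fx = self.bn2(self.conv2(ad.relu(self.bn1(self.conv1(x)))))
        skip = x if self.downsample is None else self.downsample(x)
        return ad.relu(ad.add(fx, skip))


class CnnBranch(Module):
    """Stem convolution + three residual blocks + global average pooling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.stem = ad.Conv1d(1, config.stem_channels, config.stem_kernel, rng,
                              stride=config.stem_stride,
                              padding=config.stem_padding)
        self.stem_bn = ad.BatchNorm1d(config.stem_channels)
        self.blocks = [ResidualBlock(ci, co, s, rng)
                       for ci, co, s in config.res_blocks]

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.stem_bn(self.stem(x)))
        for block in self.blocks:
            h = block(h)
        return global_avg_pool(h)          # [B, 256]


class MultiheadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, dropout_p: float,
                 rng: np.random.Generator, drop_rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_model = d_model
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)
        self.dropout_p = dropout_p
        self.drop_rng = drop_rng

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        h, dk = self.n_heads, self.d_model // self.n_heads

        def split_heads(t: Tensor) -> Tensor:
            t = ad.reshape(t, (B, T, h, dk))
            t = ad.transpose(t, (0, 2, 1, 3))
            return ad.reshape(t, (B * h, T, dk))

        q, k, v = (split_heads(p(x))
                   for p in (self.q_proj, self.k_proj, self.v_proj))
        out = ad.attention_core(q, k, v, drop_p=self.dropout_p,
                                rng=self.drop_rng, training=self.training)
        out = ad.reshape(out, (B, h, T, dk))
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (B, T, d))
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHSA and FFN, each with residual + LayerNorm.

    ``attention_identity`` is a test hook that bypasses self-attention (the
    sub-layer acts as the identity), isolating the FFN path.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        p = config.transformer_dropout
        self.self_attn = MultiheadAttention(config.d_model, config.n_heads,
                                            p, rng, drop_rng)
        self.norm1 = LayerNorm(config.d_model)
        self.norm2 = LayerNorm(config.d_model)
        self.linear1 = Linear(config.d_model, config.ffn_dim, rng)
        self.linear2 = Linear(config.ffn_dim, config.d_model, rng)
        self.drop1 = Dropout(p, drop_rng)
        self.drop2 = Dropout(p, drop_rng)
        self.drop_ffn = Dropout(p, drop_rng)
        self.attention_identity = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.attention_identity:
            attn_out = x
        else:
            attn_out = self.self_attn(x)
        x = self.norm1(ad.add(x, self.drop1(attn_out)))
        ffn = self.linear2(self.drop_ffn(ad.relu(self.linear1(x))))
        return self.norm2(ad.add(x, self.drop2(ffn)))


class TransformerBranch(Module):
    """Scalar embedding + positional encoding + 2 encoder layers + pooling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        self.embed = Linear(1, config.d_model, rng)
        self.pe = positional_encoding(config.input_length,
                                      config.d_model).astype(ad.DEFAULT_DTYPE)
        self.layers = [TransformerEncoderLayer(config, rng, drop_rng)
                       for _ in range(config.n_transformer_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        # [B, 1, L] -> [B, L, 1] -> [B, L, d_model]
        seq = ad.transpose(x, (0, 2, 1))
        h = ad.add(self.embed(seq), Tensor(self.pe))
        for layer in self.layers:
            h = layer(h)
        return ad.tmean(h, axis=1)         # [B, 128]


class GatedFusion(Module):
    """Project both branches to a shared space and gate per dimension."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        H = config.fusion_dim
        self.proj_c = Linear(config.cnn_feature_dim, H, rng, bias=False)
        self.proj_t = Linear(config.d_model, H, rng, bias=False)
        self.gate_fc1 = Linear(2 * H, H, rng)
        self.gate_fc2 = Linear(H, H, rng)

    def project(self, c: Tensor, t: Tensor) -> tuple[Tensor, Tensor]:
        return self.proj_c(c), self.proj_t(t)

    def __call__(self, c: Tensor, t: Tensor,
                 g_override: np.ndarray | float | None = None
                 ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        c_tilde, t_tilde = self.project(c, t)
        if g_override is None:
            hidden = ad.relu(self.gate_fc1(ad.concat([c_tilde, t_tilde],
                                                     axis=-1)))
            g = ad.sigmoid(self.gate_fc2(hidden))
        else:
            g_data = np.broadcast_to(
                np.asarray(g_override, dtype=c_tilde.dtype),
                c_tilde.shape).copy()
            g = Tensor(g_data)
        one_minus_g = ad.add(ad.mul(g, -1.0), 1.0)
        f = ad.add(ad.mul(g, c_tilde), ad.mul(one_minus_g, t_tilde))
        return f, g, c_tilde, t_tilde


class ClassifierHead(Module):
    """in -> 128 -> ReLU -> dropout -> 5 logits."""

    def __init__(self, in_dim: int, config: ModelConfig,
                 rng: np.random.Generator, drop_rng: np.random.Generator):
        self.fc1 = Linear(in_dim, config.classifier_hidden, rng)
        self.drop = Dropout(config.classifier_dropout, drop_rng)
        self.fc2 = Linear(config.classifier_hidden, config.n_classes, rng)

    def __call__(self, f: Tensor) -> Tensor:
        return self.fc2(self.drop(ad.relu(self.fc1(f))))


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class HctgNet(Module):
    """Dual-branch gated-fusion beat classifier (and its ablation variants).

    Both branches are constructed for every variant (so ablation variants
    provably ignore the unwired branch); the classifier head is sized to the
    variant's feature dimension.  All initialisation and dropout randomness
    flows from ``seed``.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        init_rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.drop_rng = np.random.default_rng(
            np.random.SeedSequence((seed, 1)))
        self.cnn = CnnBranch(config, init_rng)
        self.transformer = TransformerBranch(config, init_rng, self.drop_rng)
        self.fusion = GatedFusion(config, init_rng)
        self.head = ClassifierHead(config.classifier_input_dim, config,
                                   init_rng, self.drop_rng)

    # -- forward passes -----------------------------------------------------
    def _check_input(self, x) -> Tensor:
        x = ad.as_tensor(x, dtype=ad.DEFAULT_DTYPE)
        L = self.config.input_length
        if x.ndim != 3 or x.shape[1] != 1 or x.shape[2] != L:
            raise ValueError(
                f"expected input of shape [batch, 1, {L}], got {x.shape}")
        return x

    def cnn_branch_forward(self, x) -> Tensor:
        """CNN branch feature ``c`` [B, 256]."""
        return self.cnn(self._check_input(x))

    def transformer_branch_forward(self, x) -> Tensor:
        """Transformer branch feature ``t`` [B, 128]."""
        return self.transformer(self._check_input(x))

    def forward_logits(self, x) -> Tensor:
        x = self._check_input(x)
        v = self.config.variant
        if v == "cnn_only":
            return self.head(self.cnn(x))
        if v == "transformer_only":
            return self.head(self.transformer(x))
        c = self.cnn(x)
        t = self.transformer(x)
        if v == "concat_no_gate":
            c_tilde, t_tilde = self.fusion.project(c, t)
            return self.head(ad.concat([c_tilde, t_tilde], axis=-1))
        f, _g, _c, _t = self.fusion(c, t)
        return self.head(f)

    def forward(self, x) -> Tensor:
        """Class probabilities [B, 5]; rows sum to 1."""
        return ad.softmax(self.forward_logits(x), axis=-1)

    __call__ = forward

    def predict(self, x, batch_size: int = 512) -> np.ndarray:
        """Eval-mode class labels for a beat matrix [n, 188] or [n, 1, 188]."""
        x = np.asarray(x, dtype=ad.DEFAULT_DTYPE)
        if x.ndim == 2:
            x = x[:, None, :]
        was_training = self.training
        self.eval()
        try:
            preds = []
            with ad.no_grad():
                for lo in range(0, len(x), batch_size):
                    probs = self.forward(x[lo:lo + batch_size]).data
                    preds.append(np.argmax(probs, axis=1))
        finally:
            if was_training:
                self.train()
        codes = np.concatenate(preds) if preds else np.empty(0, dtype=int)
        return np.array([CLASSES[k] for k in codes], dtype="U1")

    # -- inspection hooks ---------------------------------------------------
    def fusion_state(self, x,
                     g_override: np.ndarray | float | None = None
                     ) -> FusionState:
        """Run both branches and the fusion, returning every intermediate."""
        x = self._check_input(x)
        c = self.cnn(x)
        t = self.transformer(x)
        f, g, c_tilde, t_tilde = self.fusion(c, t, g_override=g_override)
        return FusionState(c=c.data, t=t.data, c_tilde=c_tilde.data,
                           t_tilde=t_tilde.data, g=g.data, f=f.data)

    def classify(self, f: np.ndarray) -> tuple[np.ndarray, str]:
        """Head + softmax on one fused feature vector.

        Returns the probability 5-vector and the predicted class label
        (argmax; ties broken towards the lowest class index).
        """
        f = np.asarray(f, dtype=float)
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite fused feature")
        if f.shape != (self.config.classifier_input_dim,):
            raise ValueError(
                f"expected feature of length {self.config.classifier_input_dim}, "
                f"got shape {f.shape}")
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                logits = self.head(
                    Tensor(f[None, :].astype(ad.DEFAULT_DTYPE))).data[0]
        finally:
            if was_training:
                self.train()
        z = logits.astype(np.float64)
        z -= z.max()
        probs = np.exp(z) / np.exp(z).sum()
        return probs, CLASSES[int(np.argmax(probs))]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz") if path.suffix \
                else path.with_suffix(".npz")
        np.savez(path, **self.state_dict())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"config": asdict(self.config), "seed": self.seed}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "HctgNet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        cfg = meta["config"]
        cfg["res_blocks"] = tuple(tuple(b) for b in cfg["res_blocks"])
        model = cls(ModelConfig(**cfg), seed=meta.get("seed", 0))
        with np.load(path) as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model
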
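"""Dataset splitting and the optimisation loop.

Training follows the published protocol: Adam (initial learning rate 1e-3,
weight decay 1e-4), a cosine-annealing schedule from 1e-3 down to 1e-6 over
T_max = 100 epochs, batch size 256, gradient clipping at global L2 norm 1.0,
cross-entropy loss, and early stopping on validation loss with the
best-validation checkpoint restored.

Splitting is stratified and beat-level: the test fraction is held out first,
then the remainder is divided 80/20 into train and validation.  One master
seed drives the split, SMOTE, weight initialisation and batch shuffling.
Class balancing is applied to the training split only — the validation and
test datasets carry split-role tags and refuse balancing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor, cross_entropy, no_grad
from .balance import SmoteConfig, smote_oversample
from .evaluate import macro_f1
from .model import HctgNet, ModelConfig
from .preprocess import BeatDataset
from .wfdb_io import CLASSES


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters, defaulting to the published protocol."""

    lr0: float = 1e-3
    weight_decay: float = 1e-4
    t_max: int = 100                 # cosine annealing period, epochs
    eta_min: float = 1e-6
    batch_size: int = 256
    micro_batch: int = 64            # gradient-accumulation chunk size
    clip_max_norm: float = 1.0
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    test_frac: float = 0.2
    val_frac: float = 0.2            # of the non-test remainder
    balance: str = "smote"           # "smote" | "none"
    smote_k: int = 5

    def __post_init__(self):
        if not (0 < self.test_frac < 1 and 0 < self.val_frac < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        for name in ("lr0", "batch_size", "clip_max_norm", "max_epochs",
                     "t_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.balance not in ("smote", "none"):
            raise ValueError("balance must be 'smote' or 'none'")


@dataclass
class TrainHistory:
    """Per-epoch training trajectory."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "epoch": np.arange(self.n_epochs),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "lr": self.lr,
            "val_macro_f1": self.val_macro_f1,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(dataset: BeatDataset, config: TrainConfig = TrainConfig()
                  ) -> tuple[BeatDataset, BeatDataset, BeatDataset]:
    """Stratified seeded split into (train, val, test).

    The test fraction is held out first per class, then the remainder is
    split ``(1 - val_frac)/val_frac`` into train/val.  Per-class proportions
    are preserved to within one sample; the three parts are disjoint and
    exhaustive.  Each part is tagged with its role in provenance.
    """
    counts = dataset.class_counts
    for cls, n in zip(CLASSES, counts):
        if 0 < n < 5:
            raise ValueError(
                f"class {cls} has only {n} beats; at least 5 per present "
                "class are required to stratify — generate or load more data")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5B11)))
    train_idx, val_idx, test_idx = [], [], []
    for cls in CLASSES:
        idx = np.flatnonzero(dataset.labels == cls)
        if len(idx) == 0:
            continue
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * config.test_frac))
        n_val = int(round((len(idx) - n_test) * config.val_frac))
        test_idx.append(idx[:n_test])
        val_idx.append(idx[n_test:n_test + n_val])
        train_idx.append(idx[n_test + n_val:])
    parts = []
    for name, chunks in (("train", train_idx), ("val", val_idx),
                         ("test", test_idx)):
        idx = np.sort(np.concatenate(chunks)) if chunks else np.empty(0, int)
        parts.append(dataset.subset(
            idx, {"step": "split", "role": name, "seed": config.seed,
                  "test_frac": config.test_frac, "val_frac": config.val_frac}))
    return tuple(parts)


# ---------------------------------------------------------------------------
# Schedule, clipping, optimiser
# ---------------------------------------------------------------------------

def cosine_lr(epoch: int, config: TrainConfig = TrainConfig()) -> float:
    """Cosine-annealed learning rate at an epoch (clamped beyond t_max)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if epoch >= config.t_max:
        return config.eta_min
    return config.eta_min + 0.5 * (config.lr0 - config.eta_min) * (
        1.0 + math.cos(math.pi * epoch / config.t_max))


def clip_gradients(grads: list[np.ndarray], max_norm: float
                   ) -> tuple[list[np.ndarray], float]:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the (possibly scaled) gradients and the pre-clip global norm.
    """
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    total = math.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                          for g in grads))
    if total > max_norm:
        scale = max_norm / total
        grads = [g * scale for g in grads]
    return grads, total


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in params]
        self.t = 0

    def step(self, lr: float, clip_max_norm: float | None = None) -> float:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.weight_decay:
            grads = [g + self.weight_decay * p.data
                     for g, p in zip(grads, self.params)]
        norm = 0.0
        if clip_max_norm is not None:
            grads, norm = clip_gradients(grads, clip_max_norm)
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data = p.data - lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
        return norm


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _labels_to_codes(labels: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASSES)}
    return np.array([lut[l] for l in labels], dtype=np.int64)


def _validate(model: HctgNet, beats: np.ndarray, codes: np.ndarray,
              labels: np.ndarray, batch_size: int) -> tuple[float, float]:
    """One eval-mode pass over the validation split: (loss, macro-F1)."""
    model.eval()
    losses, weights, preds = [], [], []
    with no_grad():
        for lo in range(0, len(beats), batch_size):
            xb = beats[lo:lo + batch_size][:, None, :]
            logits = model.forward_logits(xb)
            losses.append(float(
                cross_entropy(logits, codes[lo:lo + batch_size]).data))
            weights.append(len(xb))
            preds.append(np.argmax(logits.data, axis=1))
    model.train()
    y_pred = np.array([CLASSES[k] for k in np.concatenate(preds)], dtype="U1")
    return float(np.average(losses, weights=weights)), macro_f1(labels, y_pred)


def train_model(train: BeatDataset, val: BeatDataset,
                mcfg: ModelConfig = ModelConfig(),
                tcfg: TrainConfig = TrainConfig(),
                apply_balance: bool = True,
                verbose: bool = False) -> tuple[HctgNet, TrainHistory]:
    """Fit the model on the training split; early-stop on validation loss.

    If ``apply_balance`` and ``tcfg.balance == "smote"``, the training split
    is SMOTE-equalised first (validation data are never balanced).  The
    best-validation-loss checkpoint is restored before returning.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if val.is_balanced():
        raise ValueError("validation split must not be balanced")
    if apply_balance and tcfg.balance == "smote":
        train = smote_oversample(train, SmoteConfig(k_neighbors=tcfg.smote_k,
                                                    seed=tcfg.seed))
    x_train = train.beats.astype(np.float32)
    y_train = _labels_to_codes(train.labels)
    x_val = val.beats.astype(np.float32)
    y_val = _labels_to_codes(val.labels)

    model = HctgNet(mcfg, seed=tcfg.seed)
    optimizer = Adam(model.parameters(), weight_decay=tcfg.weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence((tcfg.seed, 0xBA7C)))
    history = TrainHistory()
    best_val = math.inf
    best_state: dict | None = None
    since_best = 0

    for epoch in range(tcfg.max_epochs):
        lr = cosine_lr(epoch, tcfg)
        order = shuffle_rng.permutation(len(x_train))
        model.train()
        epoch_losses, epoch_sizes = [], []
        micro = min(tcfg.micro_batch, tcfg.batch_size)
        for bi, lo in enumerate(range(0, len(order), tcfg.batch_size)):
            idx = order[lo:lo + tcfg.batch_size]
            model.zero_grad()
            batch_loss = 0.0
            # gradient accumulation: each optimiser step sees the full batch,
            # processed in micro-batches to bound peak memory
            for mlo in range(0, len(idx), micro):
                midx = idx[mlo:mlo + micro]
                xb = x_train[midx][:, None, :]
                logits = model.forward_logits(xb)
                loss = cross_entropy(logits, y_train[midx])
                loss_val = float(loss.data)
                if not math.isfinite(loss_val):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch {bi}")
                weight = len(midx) / len(idx)
                loss.backward(np.asarray(weight, dtype=loss.data.dtype))
                batch_loss += loss_val * weight
            optimizer.step(lr, clip_max_norm=tcfg.clip_max_norm)
            epoch_losses.append(batch_loss)
            epoch_sizes.append(len(idx))
        train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
        val_loss, vf1 = _validate(model, x_val, y_val, val.labels,
                                  tcfg.micro_batch)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(lr)
        history.val_macro_f1.append(vf1)
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.2e}  train {train_loss:.4f}  "
                  f"val {val_loss:.4f}  val macro-F1 {vf1:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.early_stop_patience:
                break
    history.stopped_epoch = history.n_epochs - 1
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history
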
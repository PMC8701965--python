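"""Training loop (BCE + Adam) and the evaluation metric suite.

The classifier is trained per-bag with binary cross-entropy and Adam
(learning rate 2e-4, betas (0.9, 0.999), weight decay 1e-5 by default).
Several bags are packed into one forward pass by concatenating their
instances and carrying a segment-id vector, which is mathematically
identical to summing per-bag losses.

Metrics: accuracy, sensitivity, specificity, precision, MCC

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

(defined as 0 when any denominator factor is zero), F1 as the harmonic
mean of precision and recall, and ROC AUC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .instancing import Bag
from .model import BagNet, ModelConfig, save_checkpoint
from .nn import Adam
from .seqio import encode_sequence

__all__ = [
    "TrainConfig",
    "EvalReport",
    "EncodedBag",
    "encode_bags",
    "train",
    "TrainResult",
    "predict_probs",
    "confusion",
    "mcc",
    "f1",
    "roc_auc",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe for the bag classifier."""

    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-5
    epochs: int = 70
    batch_bags: int = 16
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    selection: str = "best_val"    # or "last"
    early_stop_val_acc: float | None = None
    warmup_epochs: int = 0         # initial epochs with max-pooling MIL

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class EvalReport:
    """Confusion counts plus the derived classification metrics."""

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    f1: float
    auc: float

    def to_dict(self) -> dict:
        return {k: (int(v) if k in ("TP", "TN", "FP", "FN") else float(v))
                for k, v in vars(self).items()}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class EncodedBag:
    """A bag ready for the network: encoded instances plus its label."""

    x: np.ndarray          # (k, T) int codes or (k, T, D) float rows
    label: int
    record_id: str = ""

    @property
    def k(self) -> int:
        return self.x.shape[0]


def encode_bags(bags: list[Bag]) -> list[EncodedBag]:
    out = []
    for bag in bags:
        if bag.label is None:
            raise ValueError(f"bag {bag.record_id} has no label")
        x = np.stack([encode_sequence(s) for s in bag.instances])
        out.append(EncodedBag(x=x, label=int(bag.label), record_id=bag.record_id))
    return out


# -- metrics ---------------------------------------------------------------


def confusion(labels, probs, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with prediction = 1 iff prob >= threshold."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {probs.shape}")
    pred = probs >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, tn, fp, fn


def mcc(TP: int, TN: int, FP: int, FN: int) -> float:
    """Matthews correlation coefficient; 0.0 when a denominator factor is 0."""
    d = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if d == 0:
        return 0.0
    return (TP * TN - FP * FN) / math.sqrt(d)


def f1(TP: int, FP: int, FN: int) -> float:
    """Harmonic mean of precision and recall; 0.0 in the degenerate cases."""
    if TP + FP == 0 or TP + FN == 0:
        return 0.0
    precision = TP / (TP + FP)
    recall = TP / (TP + FN)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(labels, probs) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC AUC by the trapezoid rule; returns (auc, fpr, tpr)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(probs, dtype=float))
    return float(_sk_auc(fpr, tpr)), fpr, tpr


def evaluate(labels, probs, threshold: float = 0.5) -> EvalReport:
    tp, tn, fp, fn = confusion(labels, probs, threshold)
    n_pos, n_neg = tp + fn, tn + fp
    try:
        auc_val = roc_auc(labels, probs)[0]
    except ValueError:
        auc_val = float("nan")
    return EvalReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        accuracy=(tp + tn) / max(1, tp + tn + fp + fn),
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        mcc=mcc(tp, tn, fp, fn),
        f1=f1(tp, fp, fn),
        auc=auc_val,
    )


# -- batching --------------------------------------------------------------


def _pack(bags: list[EncodedBag]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate several bags' instances; returns (x, segment_ids, labels)."""
    x = np.concatenate([b.x for b in bags], axis=0)
    seg = np.concatenate([np.full(b.k, i, dtype=np.int64)
                          for i, b in enumerate(bags)])
    labels = np.array([b.label for b in bags], dtype=np.float64)
    return x, seg, labels


def predict_probs(net: BagNet, bags: list[EncodedBag],
                  max_instances: int = 4096) -> np.ndarray:
    """Bag probabilities, batching bags to bound the forward-pass size."""
    from ._tensor import no_grad

    probs = np.empty(len(bags))
    i = 0
    while i < len(bags):
        j = i
        count = 0
        while j < len(bags) and (j == i or count + bags[j].k <= max_instances):
            count += bags[j].k
            j += 1
        chunk = bags[i:j]
        x, seg, _ = _pack(chunk)
        with no_grad():
            _, _, _, logits = net.forward(x, seg, len(chunk))
        probs[i:j] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        i = j
    return probs


def pretrain_masked_lm(net: BagNet, bags: list[EncodedBag], epochs: int = 3,
                       lr: float = 3e-3, mask_rate: float = 0.15,
                       batch_rows: int = 512, seed: int = 0) -> list[float]:
    """Self-supervised encoder pretraining by masked-base prediction.

    All instances are pooled into one (N, T) matrix; each epoch masks
    ``mask_rate`` of the positions (replaced by N) and trains the encoder
    to recover the original base from the bidirectional context.  Returns
    the per-epoch mean losses.  Useful at small data scales, where the
    bag-level signal alone is too dilute to lift the encoder off its
    random start.
    """
    from .seqio import SYMBOL_INDEX

    x_all = np.concatenate([b.x for b in bags], axis=0)
    rng = np.random.default_rng(seed)
    n_code = SYMBOL_INDEX["N"]
    opt = Adam(net.parameters(), lr=lr, weight_decay=0.0)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(x_all.shape[0])
        total, count = 0.0, 0
        for lo in range(0, len(order), batch_rows):
            rows = x_all[order[lo:lo + batch_rows]]
            mask = rng.random(rows.shape) < mask_rate
            masked = rows.copy()
            masked[mask] = n_code
            opt.zero_grad()
            loss = net.masked_lm_loss(masked, rows, mask)
            loss.backward()
            opt.step()
            total += loss.item() * rows.shape[0]
            count += rows.shape[0]
        losses.append(total / count)
    return losses


@dataclass
class TrainResult:
    net: BagNet
    history: pd.DataFrame
    best_epoch: int
    best_state: dict | None = None

    def write_history(self, path: str | Path) -> None:
        self.history.to_csv(path, sep="\t", index=False)


def train(net: BagNet, train_bags: list[EncodedBag],
          val_bags: list[EncodedBag] | None,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Train the bag classifier; returns the model and per-epoch history.

    Deterministic for a fixed seed (pure-numpy forward/backward).  The
    returned net carries the final-epoch parameters; with
    ``selection="best_val"`` the parameters of the best validation-AUC
    epoch are restored at the end.
    """
    labels = {b.label for b in train_bags}
    if labels != {0, 1}:
        raise ValueError(f"training set must contain both classes, got labels {labels}")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.lr, betas=config.betas,
               weight_decay=config.weight_decay)
    rows = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_bags))
        total_loss, total_correct = 0.0, 0
        for lo in range(0, len(order), config.batch_bags):
            chunk = [train_bags[i] for i in order[lo:lo + config.batch_bags]]
            x, seg, y = _pack(chunk)
            opt.zero_grad()
            pooling = "max" if epoch <= config.warmup_epochs else "attention"
            loss, probs = net.loss(x, seg, len(chunk), y, pooling=pooling)
            loss.backward()
            opt.step()
            total_loss += loss.item() * len(chunk)
            total_correct += int(np.sum((probs >= 0.5) == (y == 1)))
        row = {
            "epoch": epoch,
            "train_loss": total_loss / len(train_bags),
            "train_acc": total_correct / len(train_bags),
            "val_loss": np.nan, "val_acc": np.nan, "val_auc": np.nan,
        }
        if val_bags:
            vprobs = predict_probs(net, val_bags)
            vy = np.array([b.label for b in val_bags], dtype=float)
            eps = 1e-12
            row["val_loss"] = float(-np.mean(
                vy * np.log(vprobs + eps) + (1 - vy) * np.log(1 - vprobs + eps)))
            row["val_acc"] = float(np.mean((vprobs >= 0.5) == (vy == 1)))
            if len(np.unique(vy)) == 2:
                row["val_auc"] = roc_auc(vy, vprobs)[0]
                if row["val_auc"] > best_auc:
                    best_auc, best_epoch = row["val_auc"], epoch
                    best_state = net.state_dict()
        rows.append(row)
        if ckpt_dir and config.checkpoint_every and epoch % config.checkpoint_every == 0:
            save_checkpoint(net, ckpt_dir / f"epoch_{epoch:04d}")
        if (config.early_stop_val_acc is not None and val_bags
                and row["val_acc"] > config.early_stop_val_acc):
            break

    if config.selection == "best_val" and best_state is not None:
        net.load_state_dict(best_state)
    else:
        best_epoch = config.epochs
    return TrainResult(net=net, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_state=best_state)
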
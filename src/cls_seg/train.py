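"""Training protocol: Dice loss, Adam schedule, 7:1:2 split, epoch selection.

The loss is soft Dice loss, 1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε) with
ε = 1e-6, evaluated on probabilities so it stays differentiable; for
binary inputs it coincides with 1 - Dice on pixel counts.

After every epoch the model is scored on the validation set with
Score = (Dice + Recall) / 2 computed on binarized predictions, and the
checkpoint with the highest validation score is selected (ties broken by
the later epoch). The learning rate is multiplied by ``lr_decay_factor``
(default 0.1) at ``lr_decay_epoch`` (default 20).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import metrics as _metrics
from ._nn import Adam, Tensor
from .net import CLSNet, NetworkConfig, predict_mask, preprocess

__all__ = ["TrainConfig", "EpochRecord", "dice_loss", "split_dataset",
           "train_segmenter", "select_best_epoch", "lr_at_epoch"]

_EPS = 1e-6


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    lr: float = 0.001
    lr_decay_epoch: int = 20
    lr_decay_factor: float = 0.1
    weight_decay: float = 0.0001
    seed: int = 0
    input_side: int = 640
    encoder: str = "efficientnet-b3"

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "lr_decay_epoch",
                     "lr_decay_factor", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr_decay_epoch > self.epochs:
            raise ValueError("lr_decay_epoch must be <= epochs")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float
    val_recall: float
    val_score: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        expected = (self.val_dice + self.val_recall) / 2
        if self.val_score is None:
            self.val_score = expected
        elif abs(self.val_score - expected) > 1e-9:
            raise ValueError("val_score must equal (val_dice + val_recall)/2")


def dice_loss(prob, truth) -> Tensor | float:
    """Soft Dice loss; accepts autodiff tensors or plain arrays."""
    if isinstance(prob, Tensor):
        t = np.asarray(truth, dtype=np.float32)
        if prob.data.shape != t.shape:
            raise ValueError(f"shape mismatch: prob {prob.data.shape} vs "
                             f"truth {t.shape}")
        inter = (prob * t).sum()
        denom = prob.sum() + float(t.sum()) + _EPS
        return 1.0 - (2.0 * inter + _EPS) / denom
    prob = np.asarray(prob, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if prob.shape != t.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs truth {t.shape}")
    return float(1.0 - (2.0 * (prob * t).sum() + _EPS)
                 / (prob.sum() + t.sum() + _EPS))


def split_dataset(ids, seed: int):
    """Deterministic 7:1:2 split into (train, val, test) id lists.

    Sizes follow the protocol exactly: validation gets ⌊n/10⌋ items, test
    twice that, training the remainder — e.g. 5,455 → (3,820, 545, 1,090)
    and 1,000 → (700, 100, 200). Partitions are disjoint and exhaustive.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 items to split 7:1:2, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_val = n // 10
    n_test = 2 * n_val
    n_train = n - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate in effect during a 1-based epoch."""
    if epoch > config.lr_decay_epoch:
        return config.lr * config.lr_decay_factor
    return config.lr


def _prep_pairs(pairs, side: int):
    xs, ts = [], []
    for img, mask in pairs:
        if img.shape[0] != side or img.shape[1] != side:
            raise ValueError(f"expected {side}x{side} inputs, got "
                             f"{img.shape[:2]}")
        xs.append(preprocess(img))
        ts.append(np.asarray(mask, bool)[None, None].astype(np.float32))
    return np.concatenate(xs), np.concatenate(ts)


def train_segmenter(config: TrainConfig, train_pairs, val_pairs,
                    out_dir: str | os.PathLike | None = None,
                    model: CLSNet | None = None, verbose: bool = False):
    """Run the full training protocol; returns (model, records).

    ``train_pairs`` / ``val_pairs`` are sequences of (uint8 RGB image,
    binary mask) at ``config.input_side``. When ``out_dir`` is given,
    per-epoch checkpoints ``epoch_{k}.ckpt.npz`` and a ``metrics.csv``
    (epoch, train_loss, val_loss, val_dice, val_recall, val_score) are
    written there. The returned model carries the weights of the epoch
    with the highest validation score.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation partitions must be nonempty")
    if model is None:
        model = CLSNet(NetworkConfig(input_side=config.input_side,
                                     encoder=config.encoder,
                                     seed=config.seed))
    rng = np.random.default_rng(config.seed)
    xs, ts = _prep_pairs(train_pairs, config.input_side)
    vxs, vts = _prep_pairs(val_pairs, config.input_side)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    records: list[EpochRecord] = []
    best_state = None
    n = len(train_pairs)
    for epoch in range(1, config.epochs + 1):
        opt.lr = lr_at_epoch(config, epoch)
        model.train()
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = model.forward(Tensor(xs[idx]))
            loss = dice_loss(probs, ts[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
        train_loss = ep_loss / n
        val_loss, val_dice, val_recall = _validate(model, vxs, vts)
        rec = EpochRecord(epoch=epoch, train_loss=train_loss,
                          val_loss=val_loss, val_dice=val_dice,
                          val_recall=val_recall)
        records.append(rec)
        if verbose:
            print(f"epoch {epoch}: train_loss {train_loss:.4f} "
                  f"val_loss {val_loss:.4f} val_score {rec.val_score:.4f}")
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            model.save(os.path.join(out_dir, f"epoch_{epoch}.ckpt.npz"))
        if best_state is None or rec.val_score >= max(
                r.val_score for r in records):
            best_state = model.state_dict()
    if out_dir is not None:
        _write_csv(records, os.path.join(out_dir, "metrics.csv"))
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, records


def _validate(model: CLSNet, vxs: np.ndarray, vts: np.ndarray):
    model.eval()
    losses, dices, recalls = [], [], []
    for i in range(vxs.shape[0]):
        probs = model.forward(Tensor(vxs[i:i + 1]))
        losses.append(dice_loss(probs, vts[i:i + 1]).item())
        pred = predict_mask(probs.data[0, 0])
        c = _metrics.confusion(pred, vts[i, 0] > 0.5)
        dices.append(_metrics.dice(c))
        r = _metrics.recall(c)
        if r is not None:
            recalls.append(r)
    return (float(np.mean(losses)), float(np.mean(dices)),
            float(np.mean(recalls)) if recalls else 1.0)


def _write_csv(records, path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "train_loss", "val_loss", "val_dice",
                    "val_recall", "val_score"])
        for r in records:
            w.writerow([r.epoch, r.train_loss, r.val_loss, r.val_dice,
                        r.val_recall, r.val_score])


def select_best_epoch(records) -> int:
    """Epoch (1-based) with the highest validation score; ties → later."""
    records = list(records)
    if not records:
        raise ValueError("no epoch records to select from")
    best = records[0]
    for r in records[1:]:
        if r.val_score >= best.val_score:
            best = r
    return best.epoch
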
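"""Dice-loss training with Adam, polynomial LR decay and best-weights checkpointing.

The loss is the soft dice of Eq.-style squared-denominator form, averaged
over the four classes: per class c,

    dice_c = 2 * sum(p_i * g_i) / (sum(p_i^2) + sum(g_i^2))

computed over all pixels of the batch, with a small epsilon guarding empty
classes; the loss is 1 minus the class mean. The learning rate decays from
``alpha0`` as ``alpha0 * (1 - e/Ne)**0.9`` with ``e`` the epoch counter —
polynomial decay reaching zero at the final epoch. The best checkpoint is
the epoch with the highest validation dice.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .model import N_CLASSES, SegmentationModel
from .nn import Adam, Tensor
from .preprocess import MultiModalSlice, SegLabelMap

DICE_EPS = 1e-6


@dataclass
class TrainConfig:
    alpha0: float = 1e-4
    epochs: int = 350
    batch_size: int = 5
    split_ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    loss: str = "dice"

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.split_ratios}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_dice: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rates: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -math.inf
    best_state: dict | None = None

    def to_csv(self, path: str):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "train_loss", "train_dice", "train_acc",
                             "val_loss", "val_dice", "val_acc"])
            for e in range(len(self.train_loss)):
                writer.writerow([e, self.learning_rates[e], self.train_loss[e],
                                 self.train_dice[e], self.train_accuracy[e],
                                 self.val_loss[e], self.val_dice[e],
                                 self.val_accuracy[e]])


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(..., ) integer labels -> (..., n_classes) float32 one-hot."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, labels[..., None], 1.0, axis=-1)
    return out


def dice_coefficient(P, G, eps: float = DICE_EPS):
    """Per-class soft dice over all pixels; accepts Tensors or arrays.

    ``P`` holds predicted per-class probabilities, ``G`` the one-hot ground
    truth, both shaped (..., n_classes). Returns a length-n_classes Tensor
    (or array when both inputs are arrays).
    """
    tensor_in = isinstance(P, Tensor) or isinstance(G, Tensor)
    P = Tensor.as_tensor(P)
    G = Tensor.as_tensor(G)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs G {G.shape}")
    axes = tuple(range(P.ndim - 1))
    num = (P * G).sum(axis=axes) * 2.0 + eps
    den = (P * P).sum(axis=axes) + (G * G).sum(axis=axes) + eps
    dice = num / den
    return dice if tensor_in else dice.data


def dice_loss(P, G, eps: float = DICE_EPS):
    """1 - mean over classes of the per-class soft dice."""
    return 1.0 - dice_coefficient(P, G, eps).mean()


def lr_schedule(e: int, Ne: int = 350, alpha0: float = 1e-4) -> float:
    """Polynomial decay alpha0 * (1 - e/Ne)^0.9."""
    if not 0 <= e <= Ne:
        raise ValueError(f"epoch counter {e} outside [0, {Ne}]")
    return alpha0 * (1.0 - e / Ne) ** 0.9


def split_dataset(case_ids, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Random disjoint train/val/test partition.

    Train takes floor(r_train * n); the remainder splits evenly between
    validation and test (369 cases → 295/37/37).
    """
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("cannot split an empty case list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    n = len(case_ids)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(math.floor(ratios[0] * n))
    rem = n - n_train
    n_val = rem // 2
    ids = [case_ids[i] for i in order]
    return ids[:n_train], ids[n_train:n_train + n_val], ids[n_train + n_val:]


def _stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for mm, seg in pairs:
        px = mm.pixels if isinstance(mm, MultiModalSlice) else np.asarray(mm)
        lb = seg.labels if isinstance(seg, SegLabelMap) else np.asarray(seg)
        xs.append(px.astype(np.float32))
        ys.append(lb.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def _epoch_metrics(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    G = one_hot(labels)
    d = dice_coefficient(probs, G)
    loss = 1.0 - float(np.mean(d))
    acc = float((probs.argmax(axis=-1) == labels).mean())
    return loss, float(np.mean(d)), acc


def evaluate_loss(model: SegmentationModel, X: np.ndarray, labels: np.ndarray,
                  batch_size: int = 8) -> tuple[float, float, float]:
    """Mean loss/dice/accuracy over a dataset under inference mode."""
    from .nn import no_grad

    model.eval()
    probs = []
    with no_grad():
        for i in range(0, len(X), batch_size):
            probs.append(model(Tensor(X[i:i + batch_size])).data)
    probs = np.concatenate(probs)
    return _epoch_metrics(probs, labels)


def train(model: SegmentationModel, dataset, config: TrainConfig | None = None,
          log=None) -> TrainHistory:
    """Run the training protocol and return the history.

    ``dataset`` is either a list of (MultiModalSlice, SegLabelMap) pairs —
    split internally per the config ratios — or a ``(train_pairs, val_pairs)``
    tuple. Fully deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    if isinstance(dataset, tuple) and len(dataset) == 2:
        train_pairs, val_pairs = dataset
    else:
        pairs = list(dataset)
        idx_train, idx_val, _ = split_dataset(range(len(pairs)),
                                              config.split_ratios, config.seed)
        train_pairs = [pairs[i] for i in idx_train]
        val_pairs = [pairs[i] for i in idx_val] or train_pairs
    if not train_pairs:
        raise ValueError("empty training set")

    Xtr, Ytr = _stack_pairs(train_pairs)
    Xva, Yva = _stack_pairs(val_pairs)
    Gtr = one_hot(Ytr)

    optimizer = Adam(model.parameters(), lr=config.alpha0)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config.epochs, config.alpha0)
        optimizer.lr = lr
        history.learning_rates.append(lr)
        if log is not None:
            log(f"epoch {epoch}: lr={lr:.3e}")

        model.train()
        order = rng.permutation(len(Xtr))
        losses, dices, accs = [], [], []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            probs = model(Tensor(Xtr[sel]))
            loss = dice_loss(probs, Tensor(Gtr[sel]))
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            dices.append(1.0 - loss.item())
            accs.append(float((probs.data.argmax(-1) == Ytr[sel]).mean()))
        history.train_loss.append(float(np.mean(losses)))
        history.train_dice.append(float(np.mean(dices)))
        history.train_accuracy.append(float(np.mean(accs)))

        vl, vd, va = evaluate_loss(model, Xva, Yva)
        history.val_loss.append(vl)
        history.val_dice.append(vd)
        history.val_accuracy.append(va)
        if vd > history.best_val_dice:
            history.best_val_dice = vd
            history.best_epoch = epoch
            history.best_state = {k: v.copy() for k, v in model.named_state().items()}
    return history


def save_checkpoint(path: str, model: SegmentationModel, state: dict | None = None):
    np.savez(path, **(state if state is not None else model.named_state()))


def load_checkpoint(path: str, model: SegmentationModel):
    with np.load(path) as data:
        model.load_state({k: data[k] for k in data.files})
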
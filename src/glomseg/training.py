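"""Training on partially labeled data: image pool, masked loss, loop.

Because each sample supervises only its own annotated class, batches are
assembled through an *image pool*: samples stream into a buffer whose
capacity equals the number of involved classes, and whenever the buffer
exceeds the batch size a batch is drawn uniformly without replacement.
This decorrelates the class composition of consecutive batches even though
the underlying manifest groups samples by class.

The loss for a sample is soft-Dice + binary cross-entropy on the single
annotated class; other classes receive no gradient from that sample.  The
best model is the epoch checkpoint with the highest mean validation Dice
(ties resolved to the earliest epoch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .catalog import ClassCatalog, LabeledPatch
from .metrics import DiceResult, evaluate
from .nn import Adam, Tensor

__all__ = ["ImagePool", "TrainConfig", "CheckpointRecord", "TrainResult",
           "masked_task_loss", "train", "select_best"]


class ImagePool:
    """Buffer that turns a class-ordered sample stream into mixed batches.

    ``capacity`` is set to the number of involved classes; a batch of
    ``batch_size`` samples is drawn uniformly without replacement whenever
    the buffer length exceeds the batch size.
    """

    def __init__(self, capacity: int, batch_size: int = 4, seed: int = 0):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if batch_size > capacity:
            raise ValueError(f"batch_size {batch_size} exceeds pool capacity "
                             f"{capacity}")
        self.capacity = capacity
        self.batch_size = batch_size
        self.buffer: list[LabeledPatch] = []
        self._rng = np.random.default_rng(seed)
        self.n_pushed = 0
        self.n_drawn = 0

    def push(self, patch: LabeledPatch) -> list[LabeledPatch] | None:
        """Append a sample; return a batch when the pool overflows."""
        self.buffer.append(patch)
        self.n_pushed += 1
        batch = None
        if len(self.buffer) > self.batch_size:
            picks = self._rng.choice(len(self.buffer), size=self.batch_size,
                                     replace=False)
            picks_set = set(int(i) for i in picks)
            batch = [self.buffer[i] for i in sorted(picks_set)]
            self.buffer = [p for i, p in enumerate(self.buffer)
                           if i not in picks_set]
            self.n_drawn += self.batch_size
        if len(self.buffer) > self.capacity:
            raise RuntimeError("image pool invariant violated: buffer "
                               f"{len(self.buffer)} > capacity {self.capacity}")
        return batch

    def drain(self) -> list[LabeledPatch]:
        """Remove and return everything still buffered."""
        out, self.buffer = self.buffer, []
        return out


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    dice_weight: float = 1.0
    bce_weight: float = 1.0
    smooth: float = 1.0
    batch_size: int = 4
    seed: int = 0
    eval_batch_size: int = 8
    threshold: float = 0.5
    clip_norm: float | None = 1.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.dice_weight < 0 or self.bce_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.dice_weight == 0 and self.bce_weight == 0:
            raise ValueError("at least one loss weight must be positive")

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class CheckpointRecord:
    """One epoch's validation snapshot."""
    epoch: int
    per_class_dice: dict[str, float]
    mean_dice: float

    def __post_init__(self):
        if self.per_class_dice:
            expected = float(np.mean(list(self.per_class_dice.values())))
            if abs(expected - self.mean_dice) > 1e-9:
                raise ValueError("mean_dice must equal the arithmetic mean "
                                 "of per-class entries")


@dataclass
class TrainResult:
    records: list[CheckpointRecord]
    best_epoch: int
    best_state: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)


def masked_task_loss(logits, target, dice_weight: float = 1.0,
                     bce_weight: float = 1.0, smooth: float = 1.0) -> Tensor:
    """Per-task loss: dice_w·soft-Dice + bce_w·BCE on the annotated class.

    ``logits`` may be a Tensor or array of shape (N, 1, H, W) (or (H, W) for
    a single sample); ``target`` the matching binary mask(s).  The loss only
    ever sees the annotated class's prediction, which is what makes the
    partial-label scheme sound: unlabeled classes get no gradient.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits))
    t = np.asarray(target, dtype=logits.data.dtype)
    if logits.data.shape != t.shape:
        raise ValueError(f"masked_task_loss: shapes {logits.data.shape} vs "
                         f"{t.shape}")
    if logits.data.ndim == 2:  # single map convenience
        logits = _as_batch(logits)
        t = t[None]
    loss = None
    if dice_weight > 0:
        loss = _scale(nn.soft_dice_loss(logits, t, smooth=smooth), dice_weight)
    if bce_weight > 0:
        bce = _scale(nn.bce_with_logits(logits, t), bce_weight)
        loss = bce if loss is None else nn.add(loss, bce)
    return loss


def _as_batch(x: Tensor) -> Tensor:
    if x.requires_grad or x._parents:
        def backward(g):
            x._accumulate(g[0])
        return Tensor(x.data[None], parents=(x,), backward=backward)
    return Tensor(x.data[None])


def _scale(x: Tensor, s: float) -> Tensor:
    if s == 1.0:
        return x
    if x.requires_grad or x._parents:
        def backward(g):
            x._accumulate(g * s)
        return Tensor(x.data * s, parents=(x,), backward=backward)
    return Tensor(x.data * s)


def select_best(records: list[CheckpointRecord]) -> int:
    """Epoch with the highest mean validation Dice; ties -> earliest."""
    if not records:
        raise ValueError("no checkpoint records")
    best = records[0]
    for r in records[1:]:
        if r.mean_dice > best.mean_dice:
            best = r
    return best.epoch


def train(model, train_set: list[LabeledPatch], val_set: list[LabeledPatch],
          catalog: ClassCatalog, config: TrainConfig,
          log: list | None = None) -> TrainResult:
    """Optimize ``model`` on a partially labeled training set.

    ``model`` is either a :class:`~glomseg.dynamic_head.DynamicSegModel` or
    a :class:`~glomseg.metrics.BaselineModel` — anything exposing
    ``forward_batch(images, class_indices) -> logits`` and
    ``predict_batch``.  Each epoch streams a seeded shuffle of the training
    manifest through the image pool; leftover buffered samples carry over to
    the next epoch.  Returns the per-epoch records, the best epoch and a
    snapshot of its weights (already re-loaded into ``model``).
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    involved = sorted({p.class_index for p in train_set})
    capacity = max(len(involved), config.batch_size + 1)
    rng = np.random.default_rng(config.seed)
    pool = ImagePool(capacity=capacity, batch_size=config.batch_size,
                     seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               clip_norm=config.clip_norm)
    val_classes = {p.class_index for p in val_set}
    absent = [c.name for c in catalog
              if c.index in set(involved) - val_classes]
    if absent:
        warnings.warn(f"classes missing from validation are excluded from "
                      f"the selection mean: {absent}", stacklevel=2)

    records: list[CheckpointRecord] = []
    loss_history: list[float] = []
    best_state: dict[str, np.ndarray] | None = None
    best_mean = -np.inf
    best_epoch = -1

    def step(batch: list[LabeledPatch]) -> float:
        images = np.stack([p.image.transpose(2, 0, 1) for p in batch]) \
            .astype(nn.DTYPE)
        targets = np.stack([p.mask for p in batch])[:, None] \
            .astype(nn.DTYPE)
        logits = model.forward_batch(Tensor(images),
                                     [p.class_index for p in batch])
        loss = masked_task_loss(logits, targets,
                                dice_weight=config.dice_weight,
                                bce_weight=config.bce_weight,
                                smooth=config.smooth)
        opt.zero_grad()
        loss.backward()
        opt.step()
        return float(loss.data)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        for i in order:
            batch = pool.push(train_set[int(i)])
            if batch is not None:
                loss_history.append(step(batch))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result: DiceResult = evaluate(model, val_set, catalog,
                                          threshold=config.threshold,
                                          batch_size=config.eval_batch_size)
        records.append(CheckpointRecord(epoch=epoch,
                                        per_class_dice=result.per_class,
                                        mean_dice=result.mean))
        if log is not None:
            log.append({"epoch": epoch, "mean_val_dice": result.mean,
                        **{f"dice_{k}": v
                           for k, v in result.per_class.items()}})
        if result.mean > best_mean:
            best_mean = result.mean
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(records=records, best_epoch=best_epoch,
                       best_state=best_state, loss_history=loss_history)
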
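"""Dice evaluation and the multi-head ablation baseline.

Evaluation follows the partial-label protocol: each test sample carries a
mask for exactly one class, so the model is scored only on its prediction
for that class.  Per-class Dice is the mean over that class's samples and
the summary figure is the unweighted mean over classes, mirroring the
"Average" column of segmentation result tables.

Conventions for degenerate masks: both-empty pairs score 1.0 and an empty
prediction against a nonempty truth (or vice versa) scores 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import BackboneConfig, ResidualUNet
from .catalog import ClassCatalog, LabeledPatch
from .dynamic_head import PredictionMap, stable_sigmoid
from .nn import Tensor

__all__ = ["dice", "DiceResult", "evaluate", "BaselineModel",
           "baseline_forward"]


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|) for binary masks."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"dice: shape mismatch {p.shape} vs {g.shape}")
    for arr, label in ((p, "pred"), (g, "gt")):
        if not np.all(np.isin(np.unique(arr), (0, 1, True, False))):
            raise ValueError(f"dice: {label} mask must be binary")
    p = p.astype(bool)
    g = g.astype(bool)
    total = int(p.sum()) + int(g.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, g).sum()) / total


@dataclass
class DiceResult:
    """Per-class Dice scores, their unweighted mean, and sample counts."""
    per_class: dict[str, float]
    mean: float
    n_images: dict[str, int] = field(default_factory=dict)

    def as_row(self, label: str) -> dict:
        row = {"method": label}
        row.update({k: round(100.0 * v, 1) for k, v in self.per_class.items()})
        row["Average"] = round(100.0 * self.mean, 1)
        return row


def evaluate(model, dataset: list[LabeledPatch], catalog: ClassCatalog,
             threshold: float = 0.5, batch_size: int = 8) -> DiceResult:
    """Score a model on a partially labeled dataset.

    ``model`` must expose ``predict_batch(images, class_indices)`` returning
    per-pixel probabilities (N, H, W); both the dynamic-head model and the
    multi-head baseline do.  Classes with no samples are excluded from the
    mean with a warning.
    """
    if not dataset:
        raise ValueError("evaluate: dataset is empty")
    scores: dict[int, list[float]] = {}
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start:start + batch_size]
        images = np.stack([p.image.transpose(2, 0, 1) for p in chunk]) \
            .astype(nn.DTYPE)
        idx = [p.class_index for p in chunk]
        probs = model.predict_batch(images, idx)
        for p, prob in zip(chunk, probs):
            d = dice((prob > threshold).astype(np.uint8), p.mask)
            scores.setdefault(p.class_index, []).append(d)
    per_class: dict[str, float] = {}
    n_images: dict[str, int] = {}
    for cls in catalog:
        if cls.index in scores:
            per_class[cls.name] = float(np.mean(scores[cls.index]))
            n_images[cls.name] = len(scores[cls.index])
    missing = [c.name for c in catalog if c.index not in scores]
    if missing:
        warnings.warn(f"classes without evaluation samples excluded from the "
                      f"mean: {missing}", stacklevel=2)
    mean = float(np.mean(list(per_class.values())))
    return DiceResult(per_class=per_class, mean=mean, n_images=n_images)


class BaselineModel(nn.Module):
    """Multi-head residual U-Net: m fixed sigmoid output channels.

    The ablation comparator: same backbone as the dynamic model, but the
    dynamic head is replaced by one ordinary 1×1 convolution emitting all m
    class channels at once.  Trained with the same masked per-class loss —
    only the annotated channel of each sample receives supervision.
    """

    def __init__(self, num_classes: int,
                 backbone_config: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.backbone_config = backbone_config or BackboneConfig()
        self.num_classes = num_classes
        self.backbone = ResidualUNet(self.backbone_config, rng)
        self.head = nn.Conv2d(self.backbone_config.decoder_out_channels,
                              num_classes, 1, rng)

    def forward_all(self, images: Tensor) -> Tensor:
        """Logits for all m classes: (N, m, H, W)."""
        _, m = self.backbone(images)
        return self.head(m)

    def forward_batch(self, images: Tensor, class_indices: list[int]) -> Tensor:
        """Per-sample annotated-class logits (N, 1, H, W); gradients reach
        only each sample's selected channel."""
        return nn.gather_channel(self.forward_all(images), class_indices)

    def predict_batch(self, images: np.ndarray,
                      class_indices: list[int]) -> np.ndarray:
        logits = self.forward_batch(Tensor(np.asarray(images, dtype=nn.DTYPE)),
                                    list(class_indices))
        return stable_sigmoid(logits.data[:, 0].astype(np.float64))


def baseline_forward(image: np.ndarray,
                     model: BaselineModel) -> list[PredictionMap]:
    """All m per-class probability maps for one H×W×3 image."""
    x = np.asarray(image, dtype=nn.DTYPE).transpose(2, 0, 1)[None]
    logits = model.forward_all(Tensor(x)).data[0].astype(np.float64)
    return [PredictionMap(probabilities=stable_sigmoid(lg), logits=lg)
            for lg in logits]
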
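"""Class-aware controller and dynamic segmentation head.

The central mechanism of the model: instead of m fixed output heads, a
single *controller* — one convolutional layer applied to the concatenation
of the globally pooled bottleneck feature GAP(F) with the one-hot task
vector T_k — emits a flat parameter vector ω.  ω is split into the weights
and biases of a three-layer stack of 1×1 convolutions (ω1, ω2, ω3) which is
then applied to the decoder output M:

    ω = ϕ( GAP(F) ∥ T_k ; Θ_ϕ )          P = M * ω1 * ω2 * ω3

with a rectifier after the first two layers and a logistic map from the
final logits to per-pixel foreground probability for the queried class.
Because every class is segmented by its own generated kernels against the
same shared features, predictions for different classes may freely overlap
— there is no mutual-exclusivity constraint, which is what lets nested
anatomy (capsule ⊇ tuft ⊇ mesangium) and lesions be learned in one network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import BackboneConfig, ResidualUNet, global_average_pool
from .catalog import encode_task
from .nn import Tensor


@dataclass(frozen=True)
class HeadSpec:
    """Channel widths of the three dynamic layers; the last is the single
    binary output channel, and all kernels are pointwise (1×1)."""
    layer_widths: tuple[int, int, int] = (8, 8, 1)
    kernel_size: int = 1

    def __post_init__(self):
        c1, c2, c3 = self.layer_widths
        if c1 < 1 or c2 < 1:
            raise ValueError("head widths c1, c2 must be >= 1")
        if c3 != 1:
            raise ValueError("final head width c3 must be 1 (binary per-task "
                             "output)")
        if self.kernel_size != 1:
            raise ValueError("dynamic head kernels are pointwise (1×1)")


def kernel_param_count(decoder_channels: int, spec: HeadSpec) -> int:
    """Closed-form length N of the flat kernel-parameter vector ω.

    N = (D·c1 + c1) + (c1·c2 + c2) + (c2·c3 + c3).
    """
    d = decoder_channels
    c1, c2, c3 = spec.layer_widths
    return (d * c1 + c1) + (c1 * c2 + c2) + (c2 * c3 + c3)


@dataclass
class KernelParams:
    """Flat generated parameter vector ω with per-layer views."""
    flat: np.ndarray
    decoder_channels: int
    spec: HeadSpec = field(default_factory=HeadSpec)

    def __post_init__(self):
        self.flat = np.asarray(self.flat).reshape(-1)
        n = kernel_param_count(self.decoder_channels, self.spec)
        if self.flat.size != n:
            raise ValueError(f"flat kernel vector has length {self.flat.size},"
                             f" expected N={n}")
        if not np.all(np.isfinite(self.flat)):
            raise ValueError("kernel parameters must be finite")

    def _offsets(self):
        d = self.decoder_channels
        c1, c2, c3 = self.spec.layer_widths
        sizes = [d * c1, c1, c1 * c2, c2, c2 * c3, c3]
        offs = np.cumsum([0] + sizes)
        return offs, (d, c1, c2, c3)

    def layers(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """[(W1, b1), (W2, b2), (W3, b3)] with W_i of shape (out, in)."""
        offs, (d, c1, c2, c3) = self._offsets()
        f = self.flat
        w1 = f[offs[0]:offs[1]].reshape(c1, d)
        b1 = f[offs[1]:offs[2]]
        w2 = f[offs[2]:offs[3]].reshape(c2, c1)
        b2 = f[offs[3]:offs[4]]
        w3 = f[offs[4]:offs[5]].reshape(c3, c2)
        b3 = f[offs[5]:offs[6]]
        return [(w1, b1), (w2, b2), (w3, b3)]

    @property
    def omega1(self) -> tuple[np.ndarray, np.ndarray]:
        w, b = self.layers()[0]
        c1, d = w.shape
        return w.reshape(c1, d, 1, 1), b

    @property
    def omega2(self) -> tuple[np.ndarray, np.ndarray]:
        w, b = self.layers()[1]
        c2, c1 = w.shape
        return w.reshape(c2, c1, 1, 1), b

    @property
    def omega3(self) -> tuple[np.ndarray, np.ndarray]:
        w, b = self.layers()[2]
        c3, c2 = w.shape
        return w.reshape(c3, c2, 1, 1), b


def stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic map computed without overflow for large |z|."""
    z = np.asarray(z)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class PredictionMap:
    """Per-pixel foreground probability for one queried class, with the
    pre-sigmoid logits retained for loss computation."""
    probabilities: np.ndarray
    logits: np.ndarray

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        return (self.probabilities > threshold).astype(np.uint8)


class Controller(nn.Module):
    """Single convolutional layer ϕ mapping [GAP(F) ∥ T_k] to ω.

    The pooled feature concatenated with the task vector is a 1×1 spatial
    map, so the 2-D convolution reduces to an affine map; it is stored as a
    dense (N, C_bottleneck + m) weight.
    """

    def __init__(self, bottleneck_channels: int, num_classes: int,
                 decoder_channels: int, spec: HeadSpec,
                 rng: np.random.Generator):
        self.bottleneck_channels = bottleneck_channels
        self.num_classes = num_classes
        self.decoder_channels = decoder_channels
        self.spec = spec
        n = kernel_param_count(decoder_channels, spec)
        self.fc = nn.Linear(bottleneck_channels + num_classes, n, rng)
        # kernel generators need a gentle start: full-strength init makes the
        # product of three generated layers explode and saturate the sigmoid
        self.fc.weight.data *= 0.1

    def __call__(self, pooled_and_task: Tensor) -> Tensor:
        expected = self.bottleneck_channels + self.num_classes
        if pooled_and_task.shape[1] != expected:
            raise ValueError(
                f"controller input has {pooled_and_task.shape[1]} features; "
                f"expected C_bottleneck + m = {self.bottleneck_channels} + "
                f"{self.num_classes} = {expected}")
        return self.fc(pooled_and_task)


def controller_forward(feature_map: np.ndarray, task: np.ndarray,
                       controller: Controller) -> KernelParams:
    """Generate head kernels for one image and one task vector."""
    task = np.asarray(task, dtype=nn.DTYPE).reshape(-1)
    if task.size != controller.num_classes:
        raise ValueError(f"task vector length {task.size} != controller's "
                         f"m = {controller.num_classes}")
    pooled = global_average_pool(feature_map).astype(nn.DTYPE)
    z = Tensor(np.concatenate([pooled, task])[None])
    omega = controller(z)
    return KernelParams(flat=omega.data[0],
                        decoder_channels=controller.decoder_channels,
                        spec=controller.spec)


def dynamic_head_apply(decoder_feature: Tensor, omega: Tensor,
                       decoder_channels: int, spec: HeadSpec) -> Tensor:
    """Differentiable three-layer dynamic head on a batch.

    ``decoder_feature``: (N, D, H, W); ``omega``: (N, N_params) where row n
    holds the generated kernels for sample n.  Returns logits (N, 1, H, W).
    """
    d = decoder_channels
    c1, c2, c3 = spec.layer_widths
    sizes = [d * c1, c1, c1 * c2, c2, c2 * c3, c3]
    offs = np.cumsum([0] + sizes)
    n = omega.shape[0]

    def slab(i):
        return nn.narrow_channels(omega, int(offs[i]), sizes[i])

    w1 = _reshape(slab(0), (n, c1, d))
    b1 = slab(1)
    w2 = _reshape(slab(2), (n, c2, c1))
    b2 = slab(3)
    w3 = _reshape(slab(4), (n, c3, c2))
    b3 = slab(5)
    h = nn.relu(nn.batched_pointwise_conv(decoder_feature, w1, b1))
    h = nn.relu(nn.batched_pointwise_conv(h, w2, b2))
    return nn.batched_pointwise_conv(h, w3, b3)


def _reshape(x: Tensor, shape) -> Tensor:
    if x.requires_grad or x._parents:
        def backward(g):
            x._accumulate(g.reshape(x.data.shape))
        return Tensor(x.data.reshape(shape), parents=(x,), backward=backward)
    return Tensor(x.data.reshape(shape))


def dynamic_head_forward(decoder_feature: np.ndarray,
                         kernels: KernelParams) -> PredictionMap:
    """P = M * ω1 * ω2 * ω3 for one image, as numpy inference.

    ``decoder_feature`` is (D, H, W); the three generated 1×1 convolutions
    are applied with a rectifier after the first two, none after the third;
    probabilities are the logistic of the final logits.
    """
    m = np.asarray(decoder_feature)
    if m.ndim != 3:
        raise ValueError(f"decoder feature must be (D, H, W), got {m.shape}")
    if m.shape[0] != kernels.decoder_channels:
        raise ValueError(f"decoder feature has {m.shape[0]} channels but "
                         f"kernels expect D={kernels.decoder_channels}")
    h = m
    layers = kernels.layers()
    for i, (w, b) in enumerate(layers):
        h = np.einsum("oi,ihw->ohw", w, h) + b[:, None, None]
        if i < 2:
            h = np.maximum(h, 0.0)
    logits = h[0]
    return PredictionMap(probabilities=stable_sigmoid(logits),
                         logits=logits)


class DynamicSegModel(nn.Module):
    """Backbone + controller + dynamic head, end to end.

    One forward pass segments one class per sample, selected by that
    sample's task vector; querying all m classes on the same image yields m
    independent (possibly overlapping) probability maps.
    """

    def __init__(self, num_classes: int,
                 backbone_config: BackboneConfig | None = None,
                 head_spec: HeadSpec | None = None,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.backbone_config = backbone_config or BackboneConfig()
        self.head_spec = head_spec or HeadSpec()
        self.num_classes = num_classes
        self.backbone = ResidualUNet(self.backbone_config, rng)
        self.controller = Controller(
            bottleneck_channels=self.backbone_config.bottleneck_channels,
            num_classes=num_classes,
            decoder_channels=self.backbone_config.decoder_out_channels,
            spec=self.head_spec, rng=rng)

    def forward_batch(self, images: Tensor,
                      class_indices: list[int]) -> Tensor:
        """Logits (N, 1, H, W); sample n is segmented for class_indices[n]."""
        n = images.shape[0]
        if len(class_indices) != n:
            raise ValueError("one class index per sample required")
        f, m = self.backbone(images)
        pooled = nn.global_avg_pool2d(f)
        tasks = Tensor(np.stack([encode_task(c, self.num_classes)
                                 for c in class_indices]).astype(nn.DTYPE))
        omega = self.controller(nn.concat_channels(pooled, tasks))
        return dynamic_head_apply(m, omega,
                                  self.backbone_config.decoder_out_channels,
                                  self.head_spec)

    def predict_batch(self, images: np.ndarray,
                      class_indices: list[int]) -> np.ndarray:
        """Probabilities (N, H, W); sample n queried for class_indices[n]."""
        logits = self.forward_batch(
            Tensor(np.asarray(images, dtype=nn.DTYPE)), list(class_indices))
        return stable_sigmoid(logits.data[:, 0].astype(np.float64))

    def segment_class(self, image: np.ndarray,
                      class_index: int) -> PredictionMap:
        """End-to-end per-class probability map for one H×W×3 image."""
        encode_task(class_index, self.num_classes)  # validates the index
        x = np.asarray(image, dtype=nn.DTYPE).transpose(2, 0, 1)[None]
        logits = self.forward_batch(Tensor(x), [class_index])
        lg = logits.data[0, 0].astype(np.float64)
        return PredictionMap(probabilities=stable_sigmoid(lg), logits=lg)

    def segment_all_classes(self, image: np.ndarray) -> list[PredictionMap]:
        x = np.asarray(image, dtype=nn.DTYPE).transpose(2, 0, 1)
        xt = Tensor(np.repeat(x[None], self.num_classes, axis=0))
        logits = self.forward_batch(xt, list(range(self.num_classes)))
        out = []
        for k in range(self.num_classes):
            lg = logits.data[k, 0].astype(np.float64)
            out.append(PredictionMap(probabilities=stable_sigmoid(lg),
                                     logits=lg))
        return out
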
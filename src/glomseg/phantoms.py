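"""Seeded generator of glomerulus-like phantom images with partial labels.

Real glomerular patch datasets are private, so every other module is
exercised on synthetic phantoms that reproduce the *statistical* structure
the method exploits, not histological appearance:

* nested region classes — a Bowman's-capsule ellipse containing a tuft
  ellipse containing a mesangium ellipse (``mes ⊆ tuft ⊆ cap``);
* small cell disks (podocyte / mesangial-cell analogs) inside the tuft;
* lesion blobs with class-specific shape archetypes that overlap the
  regions — a "global" lesion filling nearly the whole capsule, a
  "segmental" angular sector, a compact "nodular" blob, a small bright
  "microaneurysm" disk, and a smooth "hyaline" boundary blob;
* two domains (source/target) differing by an affine color shift, a
  geometric scale factor and the noise level — a stand-in for the
  rodent-to-human domain gap;
* one-class-per-sample partial labeling: each emitted patch annotates a
  single class while the full ground truth is kept alongside for
  containment-aware tests.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .catalog import (ClassCatalog, LabeledPatch, synthetic_catalog,
                      write_manifest)

__all__ = ["DomainShift", "PhantomSpec", "PhantomSample", "generate_sample",
           "generate_samples", "generate_dataset", "DEFAULT_CLASSES",
           "DEFAULT_TARGET_SHIFT"]

DEFAULT_CLASSES = ("cap", "tuft", "mes", "pod", "mec", "les_global",
                   "les_hyaline", "les_microaneurysm", "les_nodular",
                   "les_segmental")

# flat tint per structure, chosen well-separated in RGB so a color-threshold
# oracle can verify that the segmentation task is solvable
_COLORS = {
    "background": (0.93, 0.89, 0.91),
    "cap": (0.82, 0.74, 0.80),
    "tuft": (0.78, 0.52, 0.58),
    "mes": (0.58, 0.42, 0.68),
    "pod": (0.25, 0.18, 0.38),
    "mec": (0.20, 0.32, 0.30),
    "les_global": (0.72, 0.72, 0.66),
    "les_hyaline": (0.88, 0.82, 0.55),
    "les_microaneurysm": (0.72, 0.20, 0.22),
    "les_nodular": (0.42, 0.28, 0.52),
    "les_segmental": (0.50, 0.55, 0.40),
}

_LESIONS = ("les_global", "les_hyaline", "les_microaneurysm", "les_nodular",
            "les_segmental")
_CELLS = ("pod", "mec")


@dataclass(frozen=True)
class DomainShift:
    """Fixed appearance/geometry offset applied to one domain."""
    color_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: float = 1.0
    scale: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


# the fixed appearance gap between the two synthetic domains: the target is
# slightly dimmer, color-shifted, larger-scale and noisier than the source,
# enough to make zero-shot transfer measurably worse than hybrid training
DEFAULT_TARGET_SHIFT = DomainShift(color_offset=(-0.06, 0.04, -0.08),
                                   intensity=0.92, scale=1.15, noise_sd=0.03)


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 64
    classes: tuple[str, ...] = DEFAULT_CLASSES
    domain: str = "source"
    shift: DomainShift = field(default_factory=DomainShift)
    cap_radius_frac: tuple[float, float] = (0.32, 0.42)
    tuft_frac: tuple[float, float] = (0.68, 0.78)
    mes_frac: tuple[float, float] = (0.52, 0.62)
    cell_count: tuple[int, int] = (3, 6)
    cell_radius_frac: float = 0.045
    global_cover: float = 0.97      # linear scale of the global lesion vs cap
    sector_angle: tuple[float, float] = (1.3, 2.2)  # radians
    nodular_radius_frac: tuple[float, float] = (0.10, 0.16)
    extra_lesion_prob: float = 0.25
    master_seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size too small for nested geometry")
        if not self.classes:
            raise ValueError("spec.classes must be nonempty")
        for r in (self.cap_radius_frac, self.tuft_frac, self.mes_frac):
            if r[0] <= 0 or r[1] < r[0]:
                raise ValueError(f"invalid geometry range {r}")


@dataclass
class PhantomSample:
    """One emitted patch plus the hidden full ground truth."""
    patch: LabeledPatch
    truth: dict[str, np.ndarray]
    annotated_class: str


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0)


def _disk(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r


def generate_sample(spec: PhantomSpec, seed: int,
                    annotated_class: str | None = None) -> PhantomSample:
    """Render one phantom; the annotated class defaults to cycling through
    ``spec.classes`` by seed."""
    rng = np.random.default_rng(seed)
    size = spec.image_size
    s = spec.shift.scale
    if annotated_class is None:
        annotated_class = spec.classes[seed % len(spec.classes)]
    if annotated_class not in spec.classes:
        raise ValueError(f"annotated class {annotated_class!r} not in spec "
                         f"classes {spec.classes}")

    # nested regions: containment enforced by intersection
    cap_r = rng.uniform(*spec.cap_radius_frac) * size * s
    cap_r = min(cap_r, 0.45 * size)
    cy, cx = (size / 2 + rng.uniform(-0.04, 0.04) * size,
              size / 2 + rng.uniform(-0.04, 0.04) * size)
    ecc = rng.uniform(0.75, 0.95)
    ang = rng.uniform(0, np.pi)
    cap = _ellipse_mask(size, cy, cx, cap_r, cap_r * ecc, ang)
    if not cap.any():
        raise RuntimeError("degenerate geometry: empty capsule mask")
    tf = rng.uniform(*spec.tuft_frac)
    tuft = _ellipse_mask(size, cy + rng.uniform(-1, 1), cx + rng.uniform(-1, 1),
                         cap_r * tf, cap_r * ecc * tf, ang) & cap
    mf = rng.uniform(*spec.mes_frac)
    mes = _ellipse_mask(size, cy, cx, cap_r * tf * mf,
                        cap_r * ecc * tf * mf, ang) & tuft
    if not tuft.any() or not mes.any():
        raise RuntimeError("degenerate geometry: nested region vanished")

    truth: dict[str, np.ndarray] = {
        "cap": cap, "tuft": tuft, "mes": mes,
    }

    # cell disks scattered strictly inside the tuft
    inside = np.argwhere(tuft)
    for cell in _CELLS:
        mask = np.zeros((size, size), dtype=bool)
        n_cells = rng.integers(spec.cell_count[0], spec.cell_count[1] + 1)
        r = max(spec.cell_radius_frac * size * s, 1.2)
        for _ in range(n_cells):
            py, px = inside[rng.integers(len(inside))]
            mask |= _disk(size, py, px, r)
        truth[cell] = mask & tuft

    # lesion archetypes; the annotated lesion is always present, the others
    # appear with a fixed probability so images are not trivially decodable
    # from presence alone
    present = {les: (les == annotated_class or
                     rng.random() < spec.extra_lesion_prob)
               for les in _LESIONS}
    zero = np.zeros((size, size), dtype=bool)

    g = spec.global_cover
    truth["les_global"] = (_ellipse_mask(size, cy, cx, cap_r * g,
                                         cap_r * ecc * g, ang) & cap) \
        if present["les_global"] else zero

    if present["les_hyaline"]:
        edge_ang = rng.uniform(0, 2 * np.pi)
        ey = cy + 0.9 * cap_r * tf * ecc * np.sin(edge_ang)
        ex = cx + 0.9 * cap_r * tf * np.cos(edge_ang)
        hy = _ellipse_mask(size, ey, ex, 0.28 * cap_r, 0.2 * cap_r,
                           rng.uniform(0, np.pi)) & cap
        truth["les_hyaline"] = hy
    else:
        truth["les_hyaline"] = zero

    if present["les_microaneurysm"]:
        py, px = inside[rng.integers(len(inside))]
        truth["les_microaneurysm"] = _disk(size, py, px, 0.12 * cap_r) & cap
    else:
        truth["les_microaneurysm"] = zero

    if present["les_nodular"]:
        py, px = inside[rng.integers(len(inside))]
        nr = rng.uniform(*spec.nodular_radius_frac) * size * s
        truth["les_nodular"] = _disk(size, py, px, nr) & cap
    else:
        truth["les_nodular"] = zero

    if present["les_segmental"]:
        theta0 = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(*spec.sector_angle)
        yy, xx = np.mgrid[0:size, 0:size]
        theta = np.arctan2(yy - cy, xx - cx)
        diff = np.mod(theta - theta0 + np.pi, 2 * np.pi) - np.pi
        truth["les_segmental"] = (np.abs(diff) <= width / 2) & tuft
    else:
        truth["les_segmental"] = zero

    # render: paint in containment order, cells last so they stay visible
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = _COLORS["background"]
    paint_order = ["cap", "tuft", "mes", "les_global", "les_segmental",
                   "les_nodular", "les_hyaline", "les_microaneurysm",
                   "pod", "mec"]
    for name in paint_order:
        m = truth[name]
        if m.any():
            alpha = 0.85 if name.startswith("les_") else 1.0
            img[m] = (1 - alpha) * img[m] + alpha * np.asarray(_COLORS[name])

    shift = spec.shift
    img = shift.intensity * img + np.asarray(shift.color_offset)
    img = img + rng.normal(0.0, shift.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    truth = {k: v.astype(np.uint8) for k, v in truth.items()}
    patch = LabeledPatch(image=img, mask=truth[annotated_class],
                         class_index=_class_index(annotated_class),
                         domain=spec.domain, patient_id="")
    return PhantomSample(patch=patch, truth=truth,
                         annotated_class=annotated_class)


def _class_index(name: str) -> int:
    return synthetic_catalog().by_name(name).index


def generate_samples(spec: PhantomSpec, n: int, seed: int,
                     patient_block: int = 4,
                     patient_prefix: str | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms, cycling the annotated class through
    ``spec.classes`` and grouping consecutive samples into patient blocks."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=max(n, 1))
    prefix = patient_prefix or spec.domain
    out = []
    for i in range(n):
        sample = generate_sample(spec, int(child_seeds[i]),
                                 annotated_class=spec.classes[i % len(spec.classes)])
        sample.patch.patient_id = f"{prefix}_p{i // patient_block:04d}"
        out.append(sample)
    return out


def generate_dataset(spec_source: PhantomSpec, spec_target: PhantomSpec,
                     n_source: int, n_target: int, seed: int,
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[PhantomSample], list[dict]]:
    """Two-domain phantom dataset with synthetic patient ids.

    Returns (samples, manifest rows); when ``out_dir`` is given, images and
    masks are written as PNG, the hidden truth as multi-page TIFF, and the
    manifest as CSV alongside them.
    """
    if n_source == 0 and n_target == 0:
        raise ValueError("at least one domain must have samples")
    if n_source < 0 or n_target < 0:
        raise ValueError("sample counts must be nonnegative")
    spec_source = replace(spec_source, domain="source") \
        if spec_source.domain != "source" else spec_source
    spec_target = replace(spec_target, domain="target") \
        if spec_target.domain != "target" else spec_target
    rng = np.random.default_rng(seed)
    s_seed, t_seed = (int(x) for x in rng.integers(0, 2 ** 31 - 1, size=2))
    samples = generate_samples(spec_source, n_source, s_seed)
    samples += generate_samples(spec_target, n_target, t_seed)

    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    for i, sample in enumerate(samples):
        p = sample.patch
        catalog = synthetic_catalog()
        row = {"image_path": f"images/{i:05d}.png",
               "mask_path": f"masks/{i:05d}.png",
               "class_name": catalog.classes[p.class_index].name,
               "domain": p.domain, "patient_id": p.patient_id}
        rows.append(row)
        if out_dir is not None:
            from PIL import Image
            import tifffile
            Image.fromarray((p.image * 255).round().astype(np.uint8)) \
                .save(out_dir / row["image_path"])
            Image.fromarray((p.mask * 255).astype(np.uint8)) \
                .save(out_dir / row["mask_path"])
            stack = np.stack([sample.truth[c.name] * np.uint8(255)
                              for c in catalog])
            tifffile.imwrite(out_dir / "truth" / f"{i:05d}.tiff", stack)
    if out_dir is not None:
        write_manifest(rows, out_dir / "manifest.csv")
        synthetic_catalog().to_yaml(out_dir / "catalog.yaml")
    return samples, rows
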
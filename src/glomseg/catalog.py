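"""Class universe, task encoding, and dataset bookkeeping.

The segmentation problem is multi-label over *m* classes of intraglomerular
structure: region tissue (Bowman's capsule, tuft, mesangium), cells
(podocytes, mesangial cells) and lesion categories.  Because every training
patch is annotated for exactly one class (partial labeling), each class is
treated as a task and selected at forward time by an m-dimensional one-hot
task vector.

This module defines the catalog of classes, the one-hot encoding, the
labeled-patch record, patient-level splitting, and domain filtering used by
the transfer-learning strategies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

GROUPS = ("region", "cell", "lesion")

__all__ = [
    "ClassDef", "ClassCatalog", "LabeledPatch", "SplitAssignment",
    "encode_task", "make_split", "filter_by_domain",
    "default_catalog", "synthetic_catalog",
    "write_manifest", "read_manifest", "load_dataset",
]


@dataclass(frozen=True)
class ClassDef:
    """One segmentation class: its index, short name, structural group and
    the domains (species or generically source/target) it is annotated in."""
    index: int
    name: str
    group: str
    domains: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"class {self.name!r}: group must be one of "
                             f"{GROUPS}, got {self.group!r}")
        if not self.domains:
            raise ValueError(f"class {self.name!r}: domains must be nonempty")
        object.__setattr__(self, "domains", frozenset(self.domains))


class ClassCatalog:
    """Ordered set of classes; indices are contiguous 0..m-1."""

    def __init__(self, classes: list[ClassDef]):
        if not classes:
            raise ValueError("catalog needs at least one class")
        names = [c.name for c in classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        for i, c in enumerate(classes):
            if c.index != i:
                raise ValueError(f"class indices must be contiguous 0..m-1; "
                                 f"position {i} holds index {c.index}")
        self.classes: tuple[ClassDef, ...] = tuple(classes)
        self._by_name = {c.name: c for c in classes}

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def by_name(self, name: str) -> ClassDef:
        return self._by_name[name]

    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def indices_in_group(self, group: str) -> list[int]:
        return [c.index for c in self.classes if c.group == group]

    def to_yaml(self, path: str | Path) -> None:
        entries = [{"index": c.index, "name": c.name, "group": c.group,
                    "domains": sorted(c.domains)} for c in self.classes]
        Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassCatalog":
        entries = yaml.safe_load(Path(path).read_text())
        return cls([ClassDef(index=e["index"], name=e["name"],
                             group=e["group"], domains=frozenset(e["domains"]))
                    for e in entries])

    def content_hash(self) -> str:
        import hashlib
        payload = ";".join(f"{c.index}:{c.name}:{c.group}:{','.join(sorted(c.domains))}"
                           for c in self.classes)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LabeledPatch:
    """The partial-label unit: one image, one single-class binary mask.

    ``image`` is H×W×3 in [0, 1]; ``mask`` is H×W over {0, 1} and annotates
    only the class at ``class_index`` — all other classes are unknown for
    this sample.
    """
    image: np.ndarray
    mask: np.ndarray
    class_index: int
    domain: str
    patient_id: str

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H×W×3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(f"mask {self.mask.shape} does not match image "
                             f"{self.image.shape[:2]}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")


def encode_task(class_index: int, m: int) -> np.ndarray:
    """One-hot task vector T_k of length m selecting a single class."""
    if not (0 <= class_index < m):
        raise ValueError(f"class_index {class_index} out of range for "
                         f"m={m} classes")
    t = np.zeros(m, dtype=np.float32)
    t[class_index] = 1.0
    return t


class SplitAssignment(dict):
    """Mapping patient_id -> split name in {train, val, test}."""

    SPLITS = ("train", "val", "test")

    def patients_in(self, split: str) -> list[str]:
        return [p for p, s in self.items() if s == split]

    def split_hash(self, split: str) -> str:
        import hashlib
        return hashlib.sha256("|".join(sorted(self.patients_in(split)))
                              .encode()).hexdigest()[:16]


def _largest_remainder(n: int, ratios: tuple[int, ...]) -> list[int]:
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def make_split(patient_ids: list[str], ratios: tuple[int, int, int] = (6, 1, 3),
               seed: int = 0) -> SplitAssignment:
    """Patient-level train/val/test partition at the given ratio.

    Sizes are the largest-remainder apportionment of ``ratios`` over the
    patient count; assignment is a seeded shuffle, so the same seed always
    yields the same partition.
    """
    if not patient_ids:
        raise ValueError("patient_ids must be nonempty")
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("patient_ids must be unique")
    n = len(patient_ids)
    nonzero = sum(1 for r in ratios if r > 0)
    if n < nonzero:
        raise ValueError(f"{n} patients cannot fill {nonzero} nonzero splits")
    sizes = _largest_remainder(n, ratios)
    rng = np.random.default_rng(seed)
    order = list(patient_ids)
    rng.shuffle(order)
    assignment = SplitAssignment()
    start = 0
    for split, size in zip(SplitAssignment.SPLITS, sizes):
        for pid in order[start:start + size]:
            assignment[pid] = split
        start += size
    return assignment


def filter_by_domain(dataset: list[LabeledPatch],
                     domains: set[str]) -> list[LabeledPatch]:
    """Patches whose domain is in ``domains``, order preserved."""
    return [p for p in dataset if p.domain in domains]


def default_catalog() -> ClassCatalog:
    """The 14-class glomerular catalog: 3 region + 2 cell + 9 lesion.

    Domain availability follows the annotated species for each class:
    region/cell classes and the AH/CD/ML lesions exist in the rodent data
    only (Cap in both), mesangial expansion (ME) in human only, and the
    five common lesions (GS/HS/MA/NS/SS) in both.
    """
    R, H = "rodent", "human"
    spec = [
        ("Cap", "region", {R, H}),
        ("Tuft", "region", {R}),
        ("Mes", "region", {R}),
        ("Pod", "cell", {R}),
        ("Mec", "cell", {R}),
        ("AH", "lesion", {R}),
        ("CD", "lesion", {R}),
        ("GS", "lesion", {R, H}),
        ("HS", "lesion", {R, H}),
        ("ME", "lesion", {H}),
        ("ML", "lesion", {R}),
        ("MA", "lesion", {R, H}),
        ("NS", "lesion", {R, H}),
        ("SS", "lesion", {R, H}),
    ]
    return ClassCatalog([ClassDef(i, n, g, frozenset(d))
                         for i, (n, g, d) in enumerate(spec)])


def synthetic_catalog() -> ClassCatalog:
    """Catalog for the synthetic phantoms: 3 region + 2 cell + 5 lesion.

    The five lesions mirror the shape archetypes of the common
    human-evaluated lesion set (global, hyaline, microaneurysm, nodular,
    segmental).  All classes exist in both synthetic domains.
    """
    D = {"source", "target"}
    spec = [
        ("cap", "region"), ("tuft", "region"), ("mes", "region"),
        ("pod", "cell"), ("mec", "cell"),
        ("les_global", "lesion"), ("les_hyaline", "lesion"),
        ("les_microaneurysm", "lesion"), ("les_nodular", "lesion"),
        ("les_segmental", "lesion"),
    ]
    return ClassCatalog([ClassDef(i, n, g, frozenset(D))
                         for i, (n, g) in enumerate(spec)])


def save_split(assignment: SplitAssignment, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "split"])
        for pid in sorted(assignment):
            writer.writerow([pid, assignment[pid]])


def load_split(path: str | Path) -> SplitAssignment:
    assignment = SplitAssignment()
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            assignment[row["patient_id"]] = row["split"]
    return assignment


MANIFEST_COLUMNS = ("image_path", "mask_path", "class_name", "domain",
                    "patient_id")


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Dataset manifest CSV with columns image_path, mask_path, class_name,
    domain, patient_id."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in MANIFEST_COLUMNS})


def read_manifest(path: str | Path) -> list[dict]:
    with Path(path).open() as fh:
        return list(csv.DictReader(fh))


def load_dataset(manifest_path: str | Path,
                 catalog: ClassCatalog) -> list[LabeledPatch]:
    """Load every patch referenced by a manifest into memory.

    Images are read as 8-bit RGB PNGs and rescaled to [0, 1]; masks as
    0/255 PNGs binarized to {0, 1}.  Relative paths resolve against the
    manifest's directory.
    """
    from PIL import Image

    base = Path(manifest_path).parent
    patches = []
    for row in read_manifest(manifest_path):
        img_path = Path(row["image_path"])
        msk_path = Path(row["mask_path"])
        if not img_path.is_absolute():
            img_path = base / img_path
        if not msk_path.is_absolute():
            msk_path = base / msk_path
        image = np.asarray(Image.open(img_path).convert("RGB"),
                           dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(msk_path).convert("L")) > 127) \
            .astype(np.uint8)
        patches.append(LabeledPatch(
            image=image, mask=mask,
            class_index=catalog.by_name(row["class_name"]).index,
            domain=row["domain"], patient_id=row["patient_id"]))
    return patches
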
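"""Transfer-learning strategies, species ablation, and batch inference.

Four training strategies are compared on the *target*-domain lesion test
set (in the original study the source is rodent tissue and the target is
human):

* H2H     — train on target lesions only (the data-scarce baseline);
* R2H     — train on source lesions only, zero-shot transfer;
* R&H2H   — hybrid training on the pooled source + target lesions;
* R&H2H+T — hybrid training with tissue-region samples added to the
            training set only (a label-interference stress test).

All strategies are evaluated on the identical patient-level target test
split; protocol hygiene (no patient appears in both a training set and the
test set) is asserted, not assumed.  The ablation crosses {multi-head
baseline, dynamic head} × {source-only, target-only, both}.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import BackboneConfig
from .catalog import ClassCatalog, LabeledPatch, SplitAssignment
from .dynamic_head import DynamicSegModel, HeadSpec
from .errors import ConfigurationError, DataError
from .metrics import BaselineModel, DiceResult, evaluate
from .training import TrainConfig, TrainResult, train

logger = logging.getLogger("glomseg")

__all__ = ["StrategySpec", "ExperimentReport", "standard_strategies",
           "run_strategy", "run_transfer", "run_ablation", "predict_folder"]

SOURCE, TARGET = "source", "target"


@dataclass(frozen=True)
class StrategySpec:
    """One transfer arm: which domains and class groups it trains on."""
    name: str
    train_domains: frozenset
    train_groups: frozenset = frozenset({"lesion"})
    eval_domain: str = TARGET


def standard_strategies(source: str = SOURCE,
                        target: str = TARGET) -> list[StrategySpec]:
    both = frozenset({source, target})
    lesion = frozenset({"lesion"})
    lesion_tissue = frozenset({"lesion", "region"})
    return [
        StrategySpec("H2H", frozenset({target}), lesion, target),
        StrategySpec("R2H", frozenset({source}), lesion, target),
        StrategySpec("R&H2H", both, lesion, target),
        StrategySpec("R&H2H+T", both, lesion_tissue, target),
    ]


@dataclass
class ExperimentReport:
    rows: list[dict]
    test_split_hash: str
    seeds: list[int]
    config: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            raise ValueError("report has no rows")
        cols = list(self.rows[0].keys())
        with Path(path).open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.rows)


def _subset(patches: list[LabeledPatch], split: SplitAssignment, which: str,
            domains: frozenset, groups: frozenset,
            catalog: ClassCatalog) -> list[LabeledPatch]:
    group_of = {c.index: c.group for c in catalog}
    return [p for p in patches
            if split.get(p.patient_id) == which
            and p.domain in domains
            and group_of[p.class_index] in groups]


def _build_model(kind: str, catalog: ClassCatalog,
                 backbone_config: BackboneConfig, head_spec: HeadSpec,
                 seed: int):
    rng = np.random.default_rng(seed)
    if kind == "dynamic":
        return DynamicSegModel(num_classes=catalog.num_classes,
                               backbone_config=backbone_config,
                               head_spec=head_spec, rng=rng)
    if kind == "baseline":
        return BaselineModel(num_classes=catalog.num_classes,
                             backbone_config=backbone_config, rng=rng)
    raise ConfigurationError(f"unknown model kind {kind!r}")


def _assert_hygiene(train_pats: list[LabeledPatch],
                    test_pats: list[LabeledPatch]) -> None:
    overlap = {p.patient_id for p in train_pats} & \
        {p.patient_id for p in test_pats}
    if overlap:
        raise ConfigurationError(f"patient leakage between train and test: "
                                 f"{sorted(overlap)}")


def run_strategy(strategy: StrategySpec, patches: list[LabeledPatch],
                 split: SplitAssignment, catalog: ClassCatalog,
                 config: TrainConfig,
                 backbone_config: BackboneConfig | None = None,
                 head_spec: HeadSpec | None = None,
                 model_kind: str = "dynamic",
                 ) -> tuple[DiceResult, TrainResult]:
    """Train one strategy arm and score it on the target lesion test set.

    Validation (for best-epoch selection) uses the val split filtered the
    same way as the training data, so zero-shot arms never see target
    annotations before test time.
    """
    backbone_config = backbone_config or BackboneConfig()
    head_spec = head_spec or HeadSpec()
    present_domains = {p.domain for p in patches}
    missing = strategy.train_domains - present_domains
    if missing:
        raise ConfigurationError(
            f"strategy {strategy.name} requires domains {sorted(missing)} "
            f"absent from the dataset (has {sorted(present_domains)})")
    train_pats = _subset(patches, split, "train", strategy.train_domains,
                         strategy.train_groups, catalog)
    val_pats = _subset(patches, split, "val", strategy.train_domains,
                       strategy.train_groups, catalog)
    test_pats = _subset(patches, split, "test",
                        frozenset({strategy.eval_domain}),
                        frozenset({"lesion"}), catalog)
    if not train_pats or not val_pats:
        raise ConfigurationError(f"strategy {strategy.name}: empty train or "
                                 f"val subset after filtering")
    if not test_pats:
        raise ConfigurationError(f"no {strategy.eval_domain} lesion test "
                                 f"samples")
    _assert_hygiene(train_pats, test_pats)
    logger.info("strategy=%s train=%d val=%d test=%d seed=%d",
                strategy.name, len(train_pats), len(val_pats),
                len(test_pats), config.seed)
    model = _build_model(model_kind, catalog, backbone_config, head_spec,
                         seed=config.seed)
    result = train(model, train_pats, val_pats, catalog, config)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        score = evaluate(model, test_pats, catalog,
                         threshold=config.threshold,
                         batch_size=config.eval_batch_size)
    return score, result


def run_transfer(patches: list[LabeledPatch], split: SplitAssignment,
                 catalog: ClassCatalog, config: TrainConfig,
                 backbone_config: BackboneConfig | None = None,
                 head_spec: HeadSpec | None = None,
                 strategies: list[StrategySpec] | None = None,
                 model_kind: str = "dynamic") -> ExperimentReport:
    """Run the four standard strategies on one dataset."""
    strategies = strategies or standard_strategies()
    rows = []
    for strat in strategies:
        score, _ = run_strategy(strat, patches, split, catalog, config,
                                backbone_config, head_spec, model_kind)
        row = score.as_row(strat.name)
        row["strategy"] = strat.name
        rows.append(row)
    return ExperimentReport(rows=rows, test_split_hash=split.split_hash("test"),
                            seeds=[config.seed], config=config.to_dict())


def run_ablation(patches: list[LabeledPatch], split: SplitAssignment,
                 catalog: ClassCatalog, config: TrainConfig,
                 backbone_config: BackboneConfig | None = None,
                 head_spec: HeadSpec | None = None) -> ExperimentReport:
    """{baseline, dynamic} × {source-only, target-only, both} on lesions."""
    domains_present = {p.domain for p in patches}
    if not {SOURCE, TARGET} <= domains_present:
        raise ConfigurationError("ablation needs both source and target "
                                 "domains present")
    arms = [("source-only", frozenset({SOURCE})),
            ("target-only", frozenset({TARGET})),
            ("both", frozenset({SOURCE, TARGET}))]
    rows = []
    for kind in ("baseline", "dynamic"):
        for arm_name, domains in arms:
            strat = StrategySpec(f"{kind}/{arm_name}", domains)
            score, _ = run_strategy(strat, patches, split, catalog, config,
                                    backbone_config, head_spec,
                                    model_kind=kind)
            row = score.as_row(strat.name)
            row["model"] = kind
            row["train_domains"] = arm_name
            rows.append(row)
    return ExperimentReport(rows=rows, test_split_hash=split.split_hash("test"),
                            seeds=[config.seed], config=config.to_dict())


def predict_folder(input_dir: str | Path, model, catalog: ClassCatalog,
                   out_dir: str | Path,
                   threshold: float = 0.5) -> tuple[int, int]:
    """Segment every image in a folder for all m classes.

    Writes one m-page TIFF stack per image (pages in catalog order, 0/255)
    plus a summary CSV of per-class foreground pixel areas.  Unreadable or
    incompatible images are logged and skipped; returns
    (n_processed, n_skipped) and raises :class:`DataError` if every present
    file failed.
    """
    import tifffile
    from PIL import Image

    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted([p for p in input_dir.iterdir()
                    if p.suffix.lower() in (".png", ".tif", ".tiff")])
    rows = []
    processed = skipped = 0
    for f in files:
        try:
            image = np.asarray(Image.open(f).convert("RGB"),
                               dtype=np.float32) / 255.0
            if hasattr(model, "segment_all_classes"):
                maps = model.segment_all_classes(image)
            else:
                from .metrics import baseline_forward
                maps = baseline_forward(image, model)
            stack = np.stack([m.binarize(threshold) * np.uint8(255)
                              for m in maps])
            tifffile.imwrite(out_dir / (f.stem + "_masks.tiff"), stack)
            row = {"image": f.name}
            for cls, m in zip(catalog, maps):
                row[cls.name] = int(m.binarize(threshold).sum())
            rows.append(row)
            processed += 1
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            logger.warning("skipping %s: %s", f.name, exc)
            skipped += 1
    with (out_dir / "summary.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image"] + catalog.names())
        writer.writeheader()
        writer.writerows(rows)
    if files and processed == 0:
        raise DataError(f"all {len(files)} images failed in {input_dir}")
    return processed, skipped
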
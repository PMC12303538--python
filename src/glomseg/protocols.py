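"""Fixed desk-scale experiment protocols on synthetic phantoms.

Two canned experiments define the package's reference study conditions, so
the test suite and the reproduction script exercise exactly the same code
path with exactly the same problem sizes:

* :func:`learnability_experiment` — can a single dynamic-head network learn
  five partially labeled, hierarchically overlapping classes (three nested
  regions + two lesion archetypes) from 200 one-label 64×64 phantoms?
* :func:`transfer_experiment` — does hybrid source+target training beat
  zero-shot source-only transfer on a scarce target domain (20 vs 100
  training samples, the 1:5 target:source imbalance), measured on the same
  target test split?

The backbone used here is the desk-scale configuration (depth 3, width 8,
8 decoder channels, head widths (8, 8, 1)); the task vector always spans
the full synthetic catalog even when only a subset of classes is trained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig
from .catalog import LabeledPatch, SplitAssignment, synthetic_catalog
from .dynamic_head import DynamicSegModel, HeadSpec
from .experiments import StrategySpec, run_strategy
from .metrics import DiceResult, evaluate
from .phantoms import DEFAULT_TARGET_SHIFT, PhantomSpec, generate_samples
from .training import TrainConfig, TrainResult, train

__all__ = ["desk_backbone_config", "learnability_experiment",
           "LearnabilityResult", "transfer_experiment", "TransferResult",
           "LEARNABILITY_CLASSES", "LESION_CLASSES"]

LEARNABILITY_CLASSES = ("cap", "tuft", "mes", "les_global", "les_nodular")
LESION_CLASSES = ("les_global", "les_hyaline", "les_microaneurysm",
                  "les_nodular", "les_segmental")


def desk_backbone_config() -> BackboneConfig:
    return BackboneConfig(depth=3, base_width=8, decoder_out_channels=8)


@dataclass
class LearnabilityResult:
    model: DynamicSegModel
    untrained: DiceResult
    trained: DiceResult
    train_result: TrainResult
    test_patches: list[LabeledPatch] = field(repr=False, default_factory=list)


def learnability_experiment(seed: int = 1234, n_train: int = 200,
                            n_val: int = 40, n_test: int = 40,
                            image_size: int = 64,
                            epochs: int = 30) -> LearnabilityResult:
    """Train the dynamic-head model on one-label-per-sample phantoms.

    Counts must be multiples of the 4-sample patient block so the
    train/val/test slices are patient-disjoint by construction.
    """
    for n in (n_train, n_val, n_test):
        if n % 4:
            raise ValueError("sample counts must be multiples of the "
                             "4-sample patient block")
    catalog = synthetic_catalog()
    spec = PhantomSpec(image_size=image_size, classes=LEARNABILITY_CLASSES,
                       domain="source")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=3)
    train_p = [s.patch for s in generate_samples(spec, n_train, int(seeds[0]),
                                                 patient_prefix="tr")]
    val_p = [s.patch for s in generate_samples(spec, n_val, int(seeds[1]),
                                               patient_prefix="va")]
    test_p = [s.patch for s in generate_samples(spec, n_test, int(seeds[2]),
                                                patient_prefix="te")]
    model = DynamicSegModel(num_classes=catalog.num_classes,
                            backbone_config=desk_backbone_config(),
                            head_spec=HeadSpec(),
                            rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        untrained = evaluate(model, test_p, catalog)
        cfg = TrainConfig(epochs=epochs, seed=seed)
        result = train(model, train_p, val_p, catalog, cfg)
        trained = evaluate(model, test_p, catalog)
    return LearnabilityResult(model=model, untrained=untrained,
                              trained=trained, train_result=result,
                              test_patches=test_p)


@dataclass
class TransferResult:
    r2h_means: list[float]
    rh2h_means: list[float]
    test_split_hashes: list[str]

    @property
    def r2h_mean(self) -> float:
        return float(np.mean(self.r2h_means))

    @property
    def rh2h_mean(self) -> float:
        return float(np.mean(self.rh2h_means))


def _two_domain_lesion_data(seed: int, image_size: int
                            ) -> tuple[list[LabeledPatch], SplitAssignment]:
    """1:5 target:source lesion phantoms with a fixed patient-level split.

    Source: 30 patients (25 train / 5 val → 100 / 20 samples).  Target: 15
    patients (5 train / 2 val / 8 test → 20 / 8 / 32 samples).
    """
    rng = np.random.default_rng(seed)
    s_seed, t_seed = (int(x) for x in rng.integers(0, 2 ** 31 - 1, size=2))
    src_spec = PhantomSpec(image_size=image_size, classes=LESION_CLASSES,
                           domain="source")
    tgt_spec = PhantomSpec(image_size=image_size, classes=LESION_CLASSES,
                           domain="target", shift=DEFAULT_TARGET_SHIFT)
    src = [s.patch for s in generate_samples(src_spec, 120, s_seed)]
    tgt = [s.patch for s in generate_samples(tgt_spec, 60, t_seed)]
    split = SplitAssignment()
    for i in range(30):
        split[f"source_p{i:04d}"] = "train" if i < 25 else "val"
    for i in range(15):
        split[f"target_p{i:04d}"] = ("train" if i < 5 else
                                     "val" if i < 7 else "test")
    return src + tgt, split


def transfer_experiment(seeds=(0, 1, 2), image_size: int = 32,
                        epochs: int = 12) -> TransferResult:
    """Zero-shot (R2H analog) vs hybrid (R&H2H analog) transfer.

    For each seed the two strategies are trained on the same data with the
    same patient-level split and scored on the identical target lesion test
    set; reported values are the per-seed mean target-test Dice.
    """
    catalog = synthetic_catalog()
    r2h = StrategySpec("R2H", frozenset({"source"}))
    rh2h = StrategySpec("R&H2H", frozenset({"source", "target"}))
    r2h_means, rh2h_means, hashes = [], [], []
    for seed in seeds:
        patches, split = _two_domain_lesion_data(seed, image_size)
        cfg = TrainConfig(epochs=epochs, seed=seed)
        for strat, sink in ((r2h, r2h_means), (rh2h, rh2h_means)):
            score, _ = run_strategy(strat, patches, split, catalog, cfg,
                                    backbone_config=desk_backbone_config())
            sink.append(score.mean)
        hashes.append(split.split_hash("test"))
    return TransferResult(r2h_means=r2h_means, rh2h_means=rh2h_means,
                          test_split_hashes=hashes)
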
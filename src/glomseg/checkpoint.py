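"""Model checkpoints: weights plus enough metadata to rebuild the model.

A checkpoint is a ``.npz`` holding every named parameter array and a JSON
metadata blob (format version, model kind, backbone config, head widths,
class count and a catalog content hash, so a checkpoint is never silently
evaluated against a different class universe).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .backbone import BackboneConfig
from .catalog import ClassCatalog
from .dynamic_head import DynamicSegModel, HeadSpec
from .metrics import BaselineModel

FORMAT_VERSION = 1


def save_checkpoint(model, catalog: ClassCatalog, path: str | Path) -> None:
    kind = "dynamic" if isinstance(model, DynamicSegModel) else "baseline"
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": kind,
        "num_classes": model.num_classes,
        "backbone": model.backbone_config.to_dict(),
        "catalog_hash": catalog.content_hash(),
    }
    if kind == "dynamic":
        meta["head_widths"] = list(model.head_spec.layer_widths)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path, catalog: ClassCatalog | None = None):
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version "
                         f"{meta.get('format_version')}")
    if catalog is not None and catalog.content_hash() != meta["catalog_hash"]:
        raise ValueError("checkpoint was trained against a different class "
                         "catalog")
    cfg = BackboneConfig.from_dict(meta["backbone"])
    rng = np.random.default_rng(0)
    if meta["kind"] == "dynamic":
        model = DynamicSegModel(num_classes=meta["num_classes"],
                                backbone_config=cfg,
                                head_spec=HeadSpec(tuple(meta["head_widths"])),
                                rng=rng)
    else:
        model = BaselineModel(num_classes=meta["num_classes"],
                              backbone_config=cfg, rng=rng)
    model.load_state_dict(state)
    return model
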
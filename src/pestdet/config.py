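"""Shared pipeline configuration and seed fan-out.

One global seed reproduces the whole pipeline, but each stage must also be
reproducible in isolation, so the global seed fans out through fixed
per-stage offsets rather than by consuming a shared RNG stream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

__all__ = ["MODULE_SEED_OFFSETS", "derive_seed", "load_config", "DEFAULT_TRAINING"]

#: Fixed per-stage offsets for deriving stage seeds from the global seed.
MODULE_SEED_OFFSETS: dict[str, int] = {
    "split": 11,
    "augment": 23,
    "enhance": 37,
    "anchors": 53,
    "fixtures": 71,
    "evaluate": 89,
}

#: Reference training hyper-parameters carried for downstream use only (this
#: package specifies models and data, it does not train).  The source
#: protocol reports the initial learning rate inconsistently as 0.002 in one
#: place and 0.0002 in another; both are recorded, no side is taken.
DEFAULT_TRAINING: dict[str, Any] = {
    "batch_size": 16,
    "epochs": 100,
    "freeze_epochs": 50,
    "optimizer": "adam",
    "learning_rate": 0.002,
    "learning_rate_alternate": 0.0002,
    "lr_decay_per_epoch": 0.94,
    "weight_decay": 0.00005,
    "input_size": 416,
    "iou_threshold": 0.5,
}


def derive_seed(global_seed: int, module: str) -> int:
    """Stage seed = (global seed + fixed stage offset) mod 2**31."""
    return (int(global_seed) + MODULE_SEED_OFFSETS[module]) % (2**31)


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load the shared YAML config; missing path gives an empty config."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return data
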
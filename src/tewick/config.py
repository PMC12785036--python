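"""YAML configuration: one file drives database build, training, inference.

Sections (all optional; missing keys fall back to package defaults):

.. code-block:: yaml

    database:
      label_separator: "#"
      classes: null        # null -> the sixteen Wicker superfamilies
      strict_labels: true
      fractions: [0.75, 0.15, 0.10]
      seed: 0
    model:        # ModelConfig fields
      kmer_size: 5
      max_embeddings: 2048
    training:     # TrainConfig fields (checkpoint_dir, num_epochs, ...)
      num_epochs: 100
    augmentation: # AugmentationConfig fields
      snp_prob: 0.05
    classify:
      threshold: 0.7
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .encoder import ModelConfig
from .trainer import TrainConfig


@dataclass
class DatabaseConfig:
    label_separator: str = "#"
    strict_labels: bool = True
    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    seed: int = 0
    #: expected class names; None selects the sixteen Wicker superfamilies
    classes: list[str] | None = None


@dataclass
class ClassifyConfig:
    threshold: float = 0.7
    batch_size: int = 16


@dataclass
class Config:
    database: DatabaseConfig = field(default_factory=DatabaseConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)


def load_config(path: str | Path) -> Config:
    """Parse a YAML config file into typed configuration objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    db = DatabaseConfig(**raw.get("database", {}))
    db.fractions = tuple(db.fractions)
    model = ModelConfig(**raw.get("model", {}))
    training_kwargs = dict(raw.get("training", {}))
    aug_kwargs = raw.get("augmentation", {})
    augmentation = (AugmentationConfig(**aug_kwargs) if aug_kwargs
                    else AugmentationConfig())
    training = TrainConfig(augmentation=augmentation, **training_kwargs)
    classify = ClassifyConfig(**raw.get("classify", {}))
    return Config(database=db, model=model, training=training,
                  classify=classify)
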
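"""Experiment configuration: one validated, serializable object drives every stage.

Defaults describe a desk-scale demonstration run (small cohort, small canvas,
narrow channel schedules) that exercises the full pipeline in well under a
minute; full-scale values are all reachable through the same fields.
"""

from __future__ import annotations

import datetime
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class DatasetSection(BaseModel):
    n_per_sex: int = 8
    size_classes: tuple[str, ...] = ("large",)
    frames_min: int = 3
    frames_max: int = 6
    canvas: tuple[int, int] = (96, 96)
    locations: tuple[str, ...] = ("BML",)
    start_date: datetime.date = datetime.date(2024, 3, 1)
    effect_size: float = 1.0
    ghost_rate: float = 0.12
    suppress_rate: float = 0.06
    truncate_rate: float = 0.06
    overlay_border_px: int = 8
    overlay_text_px: int = 6


class PreprocessSection(BaseModel):
    threshold: int = 5
    border: str = "auto"  # "auto" or "T,B,L,R"
    text_band: int = 6
    pad: str = "auto"  # "auto" (dataset-wide maxima) or "HxW"
    qc: bool = True


class SplitSection(BaseModel):
    n_val_per_sex: int = 2
    n_test_per_sex: int = 2


class BalanceSection(BaseModel):
    enabled: bool = True
    target: str = "auto"  # "auto" or an integer string
    cap: Optional[int] = None


class BaselineSection(BaseModel):
    enabled: bool = True
    use_augmented: bool = True
    C_values: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    penalties: tuple[str, ...] = ("l1", "l2")
    solvers: tuple[str, ...] = ("liblinear",)
    pca_components: tuple[int, ...] = (5, 10, 20)


class CNNSection(BaseModel):
    enabled: bool = True
    family: str = "reverse"
    size_variant: str = "S"
    schedule: Optional[tuple[int, ...]] = (16, 8)
    convs_per_block: int = 2
    input_size: int = 32
    dropout_rate: float = 0.2
    dense_head: tuple[int, ...] = (32,)
    batch_size: int = 16
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    max_epochs: int = 40
    monitor_start_epoch: int = 0
    patience: int = 30
    checkpoint_gate: float = 0.70
    train_time_augment: bool = False
    warm_start: Optional[str] = None  # path to a checkpoint .npz


class InterpretSection(BaseModel):
    enabled: bool = True
    k_min: int = 2
    k_max: int = 6
    perplexity: float = 8.0
    n_pca_components: int = 2
    layer_index: Optional[int] = None


class ExperimentConfig(BaseModel):
    """Top-level configuration; nested sections mirror the pipeline stages."""

    seed: int = 0
    dataset: DatasetSection = Field(default_factory=DatasetSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    split: SplitSection = Field(default_factory=SplitSection)
    balance: BalanceSection = Field(default_factory=BalanceSection)
    baseline: BaselineSection = Field(default_factory=BaselineSection)
    cnn: CNNSection = Field(default_factory=CNNSection)
    interpret: InterpretSection = Field(default_factory=InterpretSection)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not (0 <= v < 2**31):
            raise ValueError("seed must be a 31-bit non-negative integer")
        return v

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
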
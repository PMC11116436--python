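"""Pipeline configuration with the published operating constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    dicom_dir: str = ""
    report_table: str = ""
    output_dir: str = "out"
    # plug-in model names per stage (registry keys)
    models: dict[str, str] = field(
        default_factory=lambda: {
            "classifier": "truth",
            "detector": "truth",
            "segmenter": "truth",
            "severity": "geometric",
        }
    )
    # operating constants
    target_mm: float = 17.5
    iou_threshold: float = 0.5
    score_threshold: float = 0.5
    smoothing_window: int = 3
    clip_frames: int = 24
    m1_threshold: float = 0.16
    pci_offset_min: float = 25.0
    severity_binarization: float = 0.23
    gt_threshold_pct: float = 70.0
    qca_threshold_pct: float = 50.0
    bootstrap_fraction: float = 0.8
    bootstrap_iterations: int = 1000
    youden_grid_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            0 <= self.iou_threshold <= 1,
            0 <= self.score_threshold <= 1,
            self.smoothing_window >= 1 and self.smoothing_window % 2 == 1,
            self.clip_frames >= 1,
            0 <= self.m1_threshold <= 1,
            self.pci_offset_min >= 0,
            0 <= self.severity_binarization <= 1,
            0 < self.bootstrap_fraction <= 1,
            self.bootstrap_iterations >= 1,
            self.youden_grid_size >= 2,
            self.target_mm > 0,
        ]
        if not all(checks):
            raise ValueError("configuration value outside its documented range")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
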
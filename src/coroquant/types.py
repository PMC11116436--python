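"""Shared domain containers flowing between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from . import segments as seg

STRUCTURE_LABELS = ("RCA", "LCA", "other", "unknown")


@dataclass
class AngioVideo:
    """A cine angiogram: grayscale frame stack plus acquisition metadata."""

    frames: np.ndarray  # (T, H, W) uint8
    pixel_spacing_mm: float
    fps: float
    patient_id: str = ""
    study_date: str = ""
    acquisition_time: datetime | None = None
    dicom_id: str = ""
    structure_label: str = "unknown"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class PciInterval:
    artery_side: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("PCI interval start must not exceed end")


@dataclass
class ClinicalReportRow:
    """One reported per-segment stenosis grade of a (patient, date) exam."""

    patient_id: str
    study_date: str
    segment_id: str
    stenosis_pct: float
    pci_intervals: list[PciInterval] = field(default_factory=list)
    cabg_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.stenosis_pct <= 100:
            raise ValueError(f"stenosis_pct {self.stenosis_pct} outside [0, 100]")
        if not seg.is_segment(self.segment_id):
            raise ValueError(f"unknown segment code {self.segment_id!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel region, 0-based half-open: [x0, x1) x [y0, y1)."""

    frame_index: int
    x0: int
    y0: int
    x1: int
    y1: int
    class_label: str = "stenosis"
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("degenerate box: require x0 < x1 and y0 < y1")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """Geometric centre in pixel-centre coordinates: ((x0+x1-1)/2, (y0+y1-1)/2)."""
        return (self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0

    def translated(self, dx: int, dy: int, frame_index: int | None = None) -> "BoundingBox":
        return replace(
            self,
            frame_index=self.frame_index if frame_index is None else frame_index,
            x0=self.x0 + dx,
            x1=self.x1 + dx,
            y0=self.y0 + dy,
            y1=self.y1 + dy,
        )


@dataclass(frozen=True)
class ReferenceArea:
    """A stenosis box paired to its preliminary coronary segment."""

    video_ref: str
    reference_frame: int
    stenosis_box: BoundingBox
    preliminary_segment: str

    def __post_init__(self) -> None:
        if self.stenosis_box.frame_index != self.reference_frame:
            raise ValueError("stenosis_box.frame_index must equal reference_frame")


@dataclass
class DisplacementSeries:
    """Per-frame integer (dx, dy) offsets relative to a reference frame."""

    dx: np.ndarray
    dy: np.ndarray
    reference_frame: int
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=int)
        self.dy = np.asarray(self.dy, dtype=int)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.dx)
        if not (len(self.dy) == len(self.confidence) == n):
            raise ValueError("dx, dy and confidence must have equal length")
        if not (0 <= self.reference_frame < n):
            raise ValueError("reference_frame out of range")

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class RegisteredClip:
    """Motion-compensated square sub-video centred on one stenosis box."""

    frames: np.ndarray  # (T, s, s)
    box_side_px: int
    box_side_mm: float
    dicom_id: str = ""
    reference_frame: int = 0
    segment_id: str | None = None

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class StenosisRecord:
    """One assigned stenosis flowing through exclusion, severity and evaluation."""

    patient_id: str
    study_date: str
    dicom_id: str
    reference_frame: int
    n_frames: int
    artery_side: str
    segment_id: str | None = None
    predicted_pct: float | None = None
    report_pct: float | None = None
    acquisition_time: datetime | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for v in (self.predicted_pct, self.report_pct):
            if v is not None and not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")
        if self.segment_id is not None and seg.artery_side(self.segment_id) != self.artery_side:
            raise ValueError(
                f"segment {self.segment_id} does not belong to artery {self.artery_side}"
            )
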
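"""PCI and CABG exclusion.

Videos recorded during or after a percutaneous coronary intervention carry
stale stenosis labels (the plaque was modified), so they are detected and
removed by two complementary methods:

* **Method 1** — instrument evidence: the fraction *m1* of frames containing a
  detected guidewire, balloon or stent; the video is flagged when
  ``m1 >= threshold`` (default 0.16).
* **Method 2** — report timing: the video's acquisition time falls inside a
  reported PCI interval, widened by subtracting an offset (default 25 min)
  from the procedure start to absorb clock discrepancies.

A video is PCI-related when either method flags it.  All of a patient's
videos acquired at or after their earliest flagged video are removed too, and
patients with a CABG flag are excluded entirely.  Both thresholds can be
re-derived on labelled data by maximizing Youden's J over a grid of
candidates.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from . import segments as seg
from .types import BoundingBox, ClinicalReportRow, PciInterval, StenosisRecord

log = logging.getLogger(__name__)

DEFAULT_M1_THRESHOLD = 0.16
DEFAULT_OFFSET_MINUTES = 25.0
YOUDEN_GRID_SIZE = 100
OFFSET_CANDIDATES_MIN = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass
class PciDecision:
    m1: float
    method1_flag: bool
    method2_flag: bool
    m1_threshold: float
    offset_minutes: float

    @property
    def combined_flag(self) -> bool:
        return self.method1_flag or self.method2_flag


def compute_m1(instrument_boxes: Iterable[BoundingBox], n_frames: int) -> float:
    """Fraction of frames containing at least one instrument box."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = {
        b.frame_index for b in instrument_boxes if b.class_label in seg.INSTRUMENT_CLASSES
    }
    return len(frames) / n_frames


def flag_method1(m1: float, threshold: float = DEFAULT_M1_THRESHOLD) -> bool:
    """Instrument-evidence flag: m1 greater or equal to the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return m1 >= threshold


def flag_method2(
    acquisition_time: datetime | None,
    pci_intervals: Sequence[PciInterval],
    artery_side: str | None = None,
    offset_minutes: float = DEFAULT_OFFSET_MINUTES,
    side_matched: bool = True,
) -> bool:
    """Report-timing flag: acquisition inside [start - offset, end].

    When ``side_matched`` (the default), only intervals of the video's artery
    side count.
    """
    if offset_minutes < 0:
        raise ValueError("offset_minutes must be >= 0")
    if acquisition_time is None:
        return False
    offset = timedelta(minutes=offset_minutes)
    for iv in pci_intervals:
        if side_matched and artery_side is not None and iv.artery_side != artery_side:
            continue
        if iv.start - offset <= acquisition_time <= iv.end:
            return True
    return False


def decide_pci(
    instrument_boxes: Iterable[BoundingBox],
    n_frames: int,
    acquisition_time: datetime | None,
    pci_intervals: Sequence[PciInterval],
    artery_side: str | None = None,
    m1_threshold: float = DEFAULT_M1_THRESHOLD,
    offset_minutes: float = DEFAULT_OFFSET_MINUTES,
    side_matched: bool = True,
) -> PciDecision:
    """Run both methods on one video and combine them with OR."""
    m1 = compute_m1(instrument_boxes, n_frames)
    return PciDecision(
        m1=m1,
        method1_flag=flag_method1(m1, m1_threshold),
        method2_flag=flag_method2(
            acquisition_time, pci_intervals, artery_side, offset_minutes, side_matched
        ),
        m1_threshold=m1_threshold,
        offset_minutes=offset_minutes,
    )


def youden_j(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """Youden's J = sensitivity + specificity - 1 under the >= decision rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    sens = np.count_nonzero(pred & labels) / np.count_nonzero(labels)
    spec = np.count_nonzero(~pred & ~labels) / np.count_nonzero(~labels)
    return sens + spec - 1.0


def optimize_threshold_youden(
    scores: Sequence[float],
    labels: Sequence[bool],
    grid: Sequence[float] | None = None,
) -> float:
    """Grid value maximizing Youden's J; ties go to the smallest threshold.

    The default grid is 100 equally spaced values on [0, 1] inclusive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    grid_arr = (
        np.linspace(0.0, 1.0, YOUDEN_GRID_SIZE) if grid is None else np.asarray(grid, dtype=float)
    )
    if grid_arr.size == 0:
        raise ValueError("candidate grid is empty")
    js = np.array([youden_j(scores, labels, t) for t in grid_arr])
    # smallest threshold among the maxima
    return float(grid_arr[js >= js.max() - 1e-12].min())


@dataclass
class ExclusionEntry:
    dicom_id: str
    reason: str  # "pci" | "post_pci" | "cabg"
    m1: float | None = None


def apply_exclusions(
    records: Sequence[StenosisRecord],
    decisions: dict[str, PciDecision],
    report_rows: Sequence[ClinicalReportRow],
) -> tuple[list[StenosisRecord], list[ExclusionEntry]]:
    """Remove PCI-flagged, post-PCI and CABG records; return kept + audit log.

    For each patient, the earliest combined-flagged acquisition time defines a
    cutoff: that video and everything at or after it is removed.  Patients
    with a CABG flag lose all their videos.  The operation is idempotent.
    """
    cabg_patients = {r.patient_id for r in report_rows if r.cabg_flag}

    cutoff: dict[str, datetime] = {}
    flagged_dicoms: set[str] = set()
    for r in records:
        d = decisions.get(r.dicom_id)
        if d is not None and d.combined_flag:
            flagged_dicoms.add(r.dicom_id)
            if r.acquisition_time is not None:
                cur = cutoff.get(r.patient_id)
                if cur is None or r.acquisition_time < cur:
                    cutoff[r.patient_id] = r.acquisition_time

    kept: list[StenosisRecord] = []
    audit: list[ExclusionEntry] = []
    seen_audit: set[str] = set()
    for r in records:
        d = decisions.get(r.dicom_id)
        if r.patient_id in cabg_patients:
            reason = "cabg"
        elif r.dicom_id in flagged_dicoms:
            reason = "pci"
        elif (
            r.patient_id in cutoff
            and r.acquisition_time is not None
            and r.acquisition_time >= cutoff[r.patient_id]
        ):
            reason = "post_pci"
        else:
            kept.append(r)
            continue
        r.flags.add(reason)
        if r.dicom_id not in seen_audit:
            audit.append(ExclusionEntry(r.dicom_id, reason, None if d is None else d.m1))
            seen_audit.add(r.dicom_id)
    log.info("exclusions: %d records kept, %d removed", len(kept), len(audit))
    return kept, audit
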
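"""End-to-end orchestration of the video-analysis pipeline.

Stage order per video: primary-structure vote -> detection -> structure
filtering -> stenosis/segment pairing and central reference-area selection ->
box standardization, tracking, smoothing and registration -> clip
segmentation -> segment assignment and per-DICOM deduplication -> PCI/CABG
exclusion -> severity prediction -> artery-level aggregation -> evaluation.

Every dropped video is recorded in the audit trail with the stage and reason,
so the sum of per-reason exclusion counts plus surviving records equals the
input video count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assignment, detection, evaluation, exclusion, registration, segmentation
from . import segments as seg
from .config import PipelineConfig
from .phantom import ModelBundle
from .severity import (
    SeverityInput,
    SeverityPrediction,
    geometric_reference_severity,
    normalize_age,
    predict_severity,
)
from .types import AngioVideo, BoundingBox, ClinicalReportRow, StenosisRecord

log = logging.getLogger(__name__)


@dataclass
class AuditEntry:
    dicom_id: str
    stage: str
    reason: str


@dataclass
class PipelineResult:
    records: list[StenosisRecord]
    eval_result: evaluation.EvalResult | None
    audit: list[AuditEntry] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        from .io import write_records_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records_csv(self.records, out / "records.csv")
        with open(out / "audit.jsonl", "w") as fh:
            for a in self.audit:
                fh.write(json.dumps({"dicom_id": a.dicom_id, "stage": a.stage,
                                     "reason": a.reason}) + "\n")
        if self.eval_result is not None:
            with open(out / "evaluation.json", "w") as fh:
                json.dump(self.eval_result.to_dict(), fh, indent=2, sort_keys=True)


def process_video(
    video: AngioVideo,
    models: ModelBundle,
    report_rows: list[ClinicalReportRow],
    config: PipelineConfig,
) -> tuple[list[StenosisRecord], exclusion.PciDecision | None, list[AuditEntry]]:
    """Run the per-video stages; returns (records, PCI decision, audit)."""
    audit: list[AuditEntry] = []
    did = video.dicom_id

    structure = detection.classify_primary_structure(video, models.classifier)
    if structure not in ("RCA", "LCA"):
        audit.append(AuditEntry(did, "structure", f"not analysable: {structure}"))
        return [], None, audit

    boxes = models.detector(video)
    boxes = detection.filter_by_structure(boxes, structure, config.score_threshold)
    stenosis_boxes = [b for b in boxes if b.class_label == seg.STENOSIS_CLASS]
    segment_boxes = [b for b in boxes if seg.is_segment(b.class_label)]
    instrument_boxes = [b for b in boxes if b.class_label in seg.INSTRUMENT_CLASSES]

    day_rows = [
        r for r in report_rows
        if r.patient_id == video.patient_id and r.study_date == video.study_date
    ]
    intervals = day_rows[0].pci_intervals if day_rows else []
    decision = exclusion.decide_pci(
        instrument_boxes, video.n_frames, video.acquisition_time, intervals,
        artery_side=structure,
        m1_threshold=config.m1_threshold, offset_minutes=config.pci_offset_min,
    )

    areas = detection.pair_stenosis_to_segments(
        stenosis_boxes, segment_boxes, config.iou_threshold, video_ref=did
    )
    if not areas:
        reason = "no stenosis box" if not stenosis_boxes else "no segment pairing at IoU > 0.5"
        audit.append(AuditEntry(did, "pairing", reason))
        return [], decision, audit

    by_segment: dict[str, list] = {}
    for a in areas:
        by_segment.setdefault(a.preliminary_segment, []).append(a)

    records: list[StenosisRecord] = []
    for prelim, cand in by_segment.items():
        area = detection.select_central_reference(cand, video.n_frames)
        ref_frame = area.reference_frame
        try:
            box = registration.standardize_box(
                area.stenosis_box, video.pixel_spacing_mm, video.frame_shape,
                config.target_mm,
            )
        except ValueError as exc:
            audit.append(AuditEntry(did, "registration", str(exc)))
            continue
        series = registration.track_displacements(video, box, ref_frame)
        series = registration.smooth_displacements(series, config.smoothing_window)
        clip = registration.apply_registration(video, series, box)
        idx = registration.clip_window_indices(video.n_frames, ref_frame, config.clip_frames)
        windows = [
            (box.y0 + int(series.dy[i]), box.y1 + int(series.dy[i]),
             box.x0 + int(series.dx[i]), box.x1 + int(series.dx[i]))
            for i in idx
        ]
        clip24 = registration.extract_clip_window(clip, config.clip_frames)
        segmap = segmentation.segment_video(
            clip24.frames, models.segmenters,
            frame_indices=[int(i) for i in idx], windows=windows,
        )

        full_box = BoundingBox(0, 0, 0, clip24.box_side_px, clip24.box_side_px)
        frame_assignments = [
            assignment.assign_frame(segmap[t], full_box, structure)
            for t in range(segmap.shape[0])
        ]
        segment_id = assignment.assign_video(frame_assignments)
        if segment_id is None:
            audit.append(AuditEntry(did, "assignment", "no artery segment prediction"))
            continue
        clip24.segment_id = segment_id

        report_pct = next(
            (r.stenosis_pct for r in day_rows if r.segment_id == segment_id), None
        )
        rec = StenosisRecord(
            patient_id=video.patient_id,
            study_date=video.study_date,
            dicom_id=did,
            reference_frame=ref_frame,
            n_frames=video.n_frames,
            artery_side=structure,
            segment_id=segment_id,
            report_pct=report_pct,
            acquisition_time=video.acquisition_time,
        )
        rec.predicted_pct = _predict(clip24, segmap, structure, models, config)
        records.append(rec)

    records = assignment.deduplicate(records)
    if not records:
        return [], decision, audit
    return records, decision, audit


def _predict(clip24, segmap, structure, models: ModelBundle, config: PipelineConfig) -> float | None:
    if config.models.get("severity") == "geometric" or models.severity_model is None:
        try:
            return geometric_reference_severity(segmap, clip24.segment_id).pct
        except ValueError as exc:
            log.warning("geometric severity failed: %s", exc)
            return None
    inp = SeverityInput(
        clip=clip24,
        artery_onehot=(1.0, 0.0) if structure == "RCA" else (0.0, 1.0),
        age_norm=normalize_age(None),
    )
    return predict_severity(inp, models.severity_model).pct


def run_pipeline(
    videos_and_models: list[tuple[AngioVideo, ModelBundle]],
    report_rows: list[ClinicalReportRow],
    config: PipelineConfig | None = None,
    evaluate: bool = True,
) -> PipelineResult:
    """Run the full pipeline over a set of videos.

    ``videos_and_models`` pairs each video with the model bundle answering
    for it (truth-backed bundles are per-phantom; learned plug-ins can be
    shared).  With ``evaluate`` the surviving records are aggregated to the
    artery level and scored against the report percentages.
    """
    config = config or PipelineConfig()
    all_records: list[StenosisRecord] = []
    decisions: dict[str, exclusion.PciDecision] = {}
    audit: list[AuditEntry] = []

    if not videos_and_models:
        log.warning("no analysable videos")
        return PipelineResult(records=[], eval_result=None, audit=audit)

    for video, models in videos_and_models:
        recs, decision, video_audit = process_video(video, models, report_rows, config)
        audit.extend(video_audit)
        all_records.extend(recs)
        if decision is not None:
            decisions[video.dicom_id] = decision

    kept, excl_audit = exclusion.apply_exclusions(all_records, decisions, report_rows)
    audit.extend(AuditEntry(e.dicom_id, "exclusion", e.reason) for e in excl_audit)

    eval_result = None
    if evaluate and kept:
        aggregates = evaluation.aggregate_artery_level(kept)
        if len(aggregates):
            eval_result = evaluation.evaluate_aggregates(
                aggregates,
                binarization_threshold=config.severity_binarization,
                severe_threshold_pct=config.gt_threshold_pct,
                bootstrap_iterations=config.bootstrap_iterations,
                bootstrap_fraction=config.bootstrap_fraction,
                seed=config.seed,
            )
    return PipelineResult(records=kept, eval_result=eval_result, audit=audit)
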
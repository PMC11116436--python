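"""DICOM cine and clinical-report table input/output.

Cine angiograms travel as multi-frame grayscale DICOM objects; the reader
insists on pixel-spacing metadata because box standardization needs physical
dimensions, and it never rescales intensities.  Clinical reports are a
delimited table with one row per reported segment; PCI procedure intervals and
the CABG flag ride along on the same rows and are grouped per
(patient, date, artery side).

Report-table schema (CSV, header required)::

    patient_id, study_date, segment_id, stenosis_pct,
    pci_side, pci_start, pci_end, cabg

``pci_side``/``pci_start``/``pci_end`` may be empty; timestamps are ISO 8601.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from datetime import datetime
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import segments as seg
from .types import AngioVideo, ClinicalReportRow, PciInterval, StenosisRecord

log = logging.getLogger(__name__)

MULTIFRAME_SC_SOP = "1.2.840.10008.5.1.4.1.1.7.2"  # multi-frame grayscale byte SC


class ReportParseError(ValueError):
    """Raised on malformed clinical-report rows; carries the line number."""


def _parse_dicom_datetime(ds: pydicom.Dataset) -> datetime | None:
    date = getattr(ds, "AcquisitionDate", None) or getattr(ds, "StudyDate", None)
    time = getattr(ds, "AcquisitionTime", None) or getattr(ds, "StudyTime", None)
    if not date:
        return None
    time = (time or "000000").split(".")[0].ljust(6, "0")
    try:
        return datetime.strptime(f"{date}{time}", "%Y%m%d%H%M%S")
    except ValueError:
        return None


def read_dicom_video(path: str | Path) -> AngioVideo:
    """Read a multi-frame grayscale DICOM into an :class:`AngioVideo`.

    Pixel spacing is taken from PixelSpacing, falling back to
    ImagerPixelSpacing; absence of both is a hard error since downstream box
    standardization cannot work without physical dimensions.  If the two
    spacing components differ by more than 1% the mean is used with a warning
    (spacing is treated as isotropic throughout).
    """
    ds = pydicom.dcmread(str(path))
    spacing_tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing_tag is None:
        raise ValueError(f"{path}: missing pixel spacing (PixelSpacing/ImagerPixelSpacing)")
    spacing = [float(v) for v in spacing_tag]
    if len(spacing) == 2 and spacing[0] > 0 and abs(spacing[0] - spacing[1]) > 0.01 * spacing[0]:
        warnings.warn(
            f"anisotropic pixel spacing {spacing}; using the mean", stacklevel=2
        )
        pixel_spacing = float(np.mean(spacing))
    else:
        pixel_spacing = spacing[0]

    frames = ds.pixel_array
    if frames.ndim == 2:
        raise ValueError(f"{path}: single-frame object; a cine stack is required")
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale multi-frame object")
    frames = np.ascontiguousarray(frames.astype(np.uint8, copy=False))

    fps = None
    if getattr(ds, "CineRate", None):
        fps = float(ds.CineRate)
    elif getattr(ds, "FrameTime", None):
        fps = 1000.0 / float(ds.FrameTime)
    if not fps or fps <= 0:
        raise ValueError(f"{path}: missing frame-rate metadata (CineRate/FrameTime)")

    label = str(getattr(ds, "SeriesDescription", "") or "unknown")
    if label not in ("RCA", "LCA", "other"):
        label = "unknown"

    return AngioVideo(
        frames=frames,
        pixel_spacing_mm=pixel_spacing,
        fps=fps,
        patient_id=str(getattr(ds, "PatientID", "")),
        study_date=str(getattr(ds, "StudyDate", "")),
        acquisition_time=_parse_dicom_datetime(ds),
        dicom_id=str(getattr(ds, "StudyID", "") or getattr(ds, "SOPInstanceUID", "")),
        structure_label=label,
    )


def write_dicom_video(video: AngioVideo, path: str | Path) -> None:
    """Write an :class:`AngioVideo` as a multi-frame grayscale byte DICOM."""
    frames = np.ascontiguousarray(video.frames.astype(np.uint8, copy=False))
    t, rows, cols = frames.shape

    # opaque ids (e.g. "P0001.V0") are not legal UIDs; carry them in StudyID
    is_uid = bool(re.fullmatch(r"[0-9.]+", video.dicom_id or ""))
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MULTIFRAME_SC_SOP
    meta.MediaStorageSOPInstanceUID = video.dicom_id if is_uid else generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = MULTIFRAME_SC_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyID = (video.dicom_id or "")[:16]
    ds.Modality = "XA"
    ds.PatientID = video.patient_id
    ds.PatientName = video.patient_id
    ds.StudyDate = video.study_date
    if video.acquisition_time is not None:
        ds.AcquisitionDate = video.acquisition_time.strftime("%Y%m%d")
        ds.AcquisitionTime = video.acquisition_time.strftime("%H%M%S")
    ds.SeriesDescription = video.structure_label
    ds.NumberOfFrames = t
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{video.pixel_spacing_mm:.6f}", f"{video.pixel_spacing_mm:.6f}"]
    ds.CineRate = int(round(video.fps))
    ds.FrameTime = 1000.0 / video.fps
    ds.PixelData = frames.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


_REPORT_COLUMNS = (
    "patient_id",
    "study_date",
    "segment_id",
    "stenosis_pct",
    "pci_side",
    "pci_start",
    "pci_end",
    "cabg",
)


def read_report_table(path: str | Path) -> list[ClinicalReportRow]:
    """Parse a clinical-report CSV into :class:`ClinicalReportRow` objects.

    PCI intervals are grouped per (patient, date, artery side) and attached to
    every row of that patient-day.  Malformed percentages or unknown segment
    codes raise :class:`ReportParseError` naming the offending line.
    """
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            log.warning("report table %s is empty", path)
            return []
        missing = set(_REPORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ReportParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, raw in enumerate(reader, start=2):
            raw["_line"] = lineno
            rows.append(raw)
    if not rows:
        log.warning("report table %s has a header but no rows", path)
        return []

    # First pass: collect PCI intervals and CABG flags per patient-day
    intervals: dict[tuple[str, str], list[PciInterval]] = {}
    cabg: dict[tuple[str, str], bool] = {}
    for raw in rows:
        key = (raw["patient_id"], raw["study_date"])
        cabg[key] = cabg.get(key, False) or raw.get("cabg", "").strip() in ("1", "true", "True")
        if raw.get("pci_start", "").strip():
            try:
                iv = PciInterval(
                    artery_side=raw["pci_side"].strip(),
                    start=datetime.fromisoformat(raw["pci_start"].strip()),
                    end=datetime.fromisoformat(raw["pci_end"].strip()),
                )
            except ValueError as exc:
                raise ReportParseError(f"line {raw['_line']}: bad PCI interval: {exc}") from exc
            intervals.setdefault(key, []).append(iv)

    out: list[ClinicalReportRow] = []
    for raw in rows:
        if not raw.get("segment_id", "").strip():
            continue  # interval-only row
        try:
            pct = float(raw["stenosis_pct"])
        except (TypeError, ValueError) as exc:
            raise ReportParseError(
                f"line {raw['_line']}: unparseable stenosis_pct {raw['stenosis_pct']!r}"
            ) from exc
        if not 0 <= pct <= 100:
            raise ReportParseError(
                f"line {raw['_line']}: stenosis_pct {pct} outside [0, 100]"
            )
        code = raw["segment_id"].strip()
        if not seg.is_segment(code):
            raise ReportParseError(f"line {raw['_line']}: unknown segment code {code!r}")
        key = (raw["patient_id"], raw["study_date"])
        out.append(
            ClinicalReportRow(
                patient_id=raw["patient_id"],
                study_date=raw["study_date"],
                segment_id=code,
                stenosis_pct=pct,
                pci_intervals=list(intervals.get(key, [])),
                cabg_flag=cabg.get(key, False),
            )
        )
    return out


def write_report_table(rows: list[ClinicalReportRow], path: str | Path) -> None:
    """Write report rows in the schema :func:`read_report_table` expects.

    Every PCI interval of a patient-day is emitted on that day's first row
    (extra interval-only rows are appended when a day has more intervals than
    segment rows).
    """
    by_day: dict[tuple[str, str], list[ClinicalReportRow]] = {}
    for r in rows:
        by_day.setdefault((r.patient_id, r.study_date), []).append(r)

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REPORT_COLUMNS)
        writer.writeheader()
        for (pid, date), day_rows in by_day.items():
            ivs = list(day_rows[0].pci_intervals)
            cabg_val = "1" if any(r.cabg_flag for r in day_rows) else "0"
            n = max(len(day_rows), len(ivs))
            for i in range(n):
                rec: dict[str, str] = {
                    "patient_id": pid,
                    "study_date": date,
                    "segment_id": "",
                    "stenosis_pct": "",
                    "pci_side": "",
                    "pci_start": "",
                    "pci_end": "",
                    "cabg": cabg_val,
                }
                if i < len(day_rows):
                    rec["segment_id"] = day_rows[i].segment_id
                    rec["stenosis_pct"] = f"{day_rows[i].stenosis_pct:g}"
                if i < len(ivs):
                    rec["pci_side"] = ivs[i].artery_side
                    rec["pci_start"] = ivs[i].start.isoformat()
                    rec["pci_end"] = ivs[i].end.isoformat()
                writer.writerow(rec)


_RECORD_COLUMNS = (
    "patient_id",
    "study_date",
    "dicom_id",
    "reference_frame",
    "n_frames",
    "artery_side",
    "segment_id",
    "predicted_pct",
    "report_pct",
    "acquisition_time",
    "flags",
)


def write_records_csv(records: list[StenosisRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.study_date,
                    r.dicom_id,
                    r.reference_frame,
                    r.n_frames,
                    r.artery_side,
                    r.segment_id or "",
                    "" if r.predicted_pct is None else f"{r.predicted_pct:.4f}",
                    "" if r.report_pct is None else f"{r.report_pct:.4f}",
                    r.acquisition_time.isoformat() if r.acquisition_time else "",
                    "|".join(sorted(r.flags)),
                ]
            )


def read_records_csv(path: str | Path) -> list[StenosisRecord]:
    out = []
    with open(path, newline="") as fh:
        for raw in csv.DictReader(fh):
            out.append(
                StenosisRecord(
                    patient_id=raw["patient_id"],
                    study_date=raw["study_date"],
                    dicom_id=raw["dicom_id"],
                    reference_frame=int(raw["reference_frame"]),
                    n_frames=int(raw["n_frames"]),
                    artery_side=raw["artery_side"],
                    segment_id=raw["segment_id"] or None,
                    predicted_pct=float(raw["predicted_pct"]) if raw["predicted_pct"] else None,
                    report_pct=float(raw["report_pct"]) if raw["report_pct"] else None,
                    acquisition_time=(
                        datetime.fromisoformat(raw["acquisition_time"])
                        if raw["acquisition_time"]
                        else None
                    ),
                    flags=set(raw["flags"].split("|")) if raw["flags"] else set(),
                )
            )
    return out
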
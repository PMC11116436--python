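"""Stenosis-to-segment assignment: frame-level, video-level, deduplication.

A stenosis box is assigned to the coronary segment whose pixels come closest
to the box centre, among the pixels inside the box that belong to the video's
artery side.  Ties at the minimal distance are resolved first by the number of
pixels at that distance, then by the lowest SYNTAX index.  Video-level
assignment is a majority vote over the per-frame assignments, and when one
DICOM yields several videos of the same segment only the temporally central
instance is kept.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Sequence

import numpy as np

from . import segments as seg
from .types import BoundingBox, StenosisRecord

#: tolerance for "equally distant" comparisons on squared pixel distances
DISTANCE_TOL = 1e-9


def assign_frame(
    segmap_frame: np.ndarray, box: BoundingBox, artery_side: str
) -> str | None:
    """Assign one frame's stenosis box to a segment of the given artery side.

    Among in-box pixels labelled with a same-side segment, the candidate
    classes owning a pixel at the minimal Euclidean distance from the box
    centre compete: most pixels at that distance wins, then lowest SYNTAX
    index.  Returns ``None`` when the box contains no qualifying vessel pixel.
    """
    if artery_side not in ("RCA", "LCA"):
        raise ValueError("artery_side must be RCA or LCA")
    h, w = segmap_frame.shape
    x0, y0 = max(box.x0, 0), max(box.y0, 0)
    x1, y1 = min(box.x1, w), min(box.y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    patch = segmap_frame[y0:y1, x0:x1]

    side_classes = [seg.class_index(c) for c in seg.segments_of_side(artery_side)]
    mask = np.isin(patch, side_classes)
    if not mask.any():
        return None

    cx, cy = box.center
    ys, xs = np.nonzero(mask)
    d2 = (xs + x0 - cx) ** 2 + (ys + y0 - cy) ** 2
    dmin = d2.min()
    at_min = d2 <= dmin + DISTANCE_TOL
    labels = patch[ys[at_min], xs[at_min]]
    counts = Counter(int(v) for v in labels)
    best = max(
        counts,
        key=lambda c: (counts[c], -seg.syntax_index(seg.class_name(c))),
    )
    return seg.class_name(best)


def assign_video(frame_assignments: Sequence[str | None]) -> str | None:
    """Majority vote over per-frame assignments; ``None`` frames abstain.

    A tie is broken toward the lowest SYNTAX index, mirroring the frame-level
    ladder.  All-``None`` input returns ``None`` (the video makes no further
    predictions).
    """
    counts = Counter(a for a in frame_assignments if a is not None)
    if not counts:
        return None
    return max(counts, key=lambda c: (counts[c], -seg.syntax_index(c)))


def deduplicate(records: Sequence[StenosisRecord]) -> list[StenosisRecord]:
    """Keep one record per assigned segment of a DICOM: the central instance.

    Centrality is distance of the reference frame to the video midpoint
    (T-1)/2; ties go to the earlier frame.  Records with no assigned segment
    pass through untouched.
    """
    dicoms = {r.dicom_id for r in records}
    if len(dicoms) > 1:
        raise ValueError("deduplicate operates on the records of one DICOM")
    best: dict[str, StenosisRecord] = {}
    passthrough: list[StenosisRecord] = []
    for r in records:
        if r.segment_id is None:
            passthrough.append(r)
            continue
        cur = best.get(r.segment_id)
        if cur is None or _centrality(r) < _centrality(cur):
            best[r.segment_id] = r
    return [r for r in records if r in passthrough or best.get(r.segment_id) is r]


def _centrality(r: StenosisRecord) -> tuple[float, int]:
    mid = (r.n_frames - 1) / 2.0
    return abs(r.reference_frame - mid), r.reference_frame
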
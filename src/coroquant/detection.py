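"""Detection-stage plumbing around the pluggable frame models.

The neural stages themselves (primary-structure classification, stenosis /
segment / instrument box detection) are plug-in contracts; what lives here is
the deterministic logic the pipeline wraps around them: the per-video majority
vote over frame labels, IoU computation and stenosis-to-segment pairing,
structure-conditional box filtering and central reference-area selection.

Coordinate convention: boxes are 0-based half-open pixel intervals
``[x0, x1) x [y0, y1)``; IoU is the ratio of pixel-count areas under that
convention.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Callable, Iterable, Sequence

import numpy as np

from . import segments as seg
from .types import AngioVideo, BoundingBox, ReferenceArea

#: A frame classifier maps (frame, frame_index) -> structure label.
FrameClassifier = Callable[[np.ndarray, int], str]

DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_IOU_THRESHOLD = 0.5


def classify_primary_structure(video: AngioVideo, model: FrameClassifier) -> str:
    """Video-level primary structure: the most frequent frame-level prediction.

    Ties are broken toward the lexicographically smallest label.  Downstream
    stages only proceed for RCA/LCA videos.
    """
    if video.n_frames == 0:
        raise ValueError("empty video")
    labels = [model(video.frames[i], i) for i in range(video.n_frames)]
    counts = Counter(labels)
    best = max(counts.values())
    return min(lbl for lbl, c in counts.items() if c == best)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def pair_stenosis_to_segments(
    stenosis_boxes: Iterable[BoundingBox],
    segment_boxes: Sequence[BoundingBox],
    threshold: float = DEFAULT_IOU_THRESHOLD,
    video_ref: str = "",
) -> list[ReferenceArea]:
    """Pair each stenosis box with its best-overlapping segment box.

    A pairing requires IoU strictly greater than ``threshold`` with a segment
    box on the same frame; when several qualify, the highest IoU wins.
    Stenosis boxes without a qualifying partner are dropped.
    """
    out: list[ReferenceArea] = []
    for sbox in stenosis_boxes:
        best: tuple[float, BoundingBox] | None = None
        for gbox in segment_boxes:
            if gbox.frame_index != sbox.frame_index or not seg.is_segment(gbox.class_label):
                continue
            val = iou(sbox, gbox)
            if val > threshold and (best is None or val > best[0]):
                best = (val, gbox)
        if best is not None:
            out.append(
                ReferenceArea(
                    video_ref=video_ref,
                    reference_frame=sbox.frame_index,
                    stenosis_box=sbox,
                    preliminary_segment=best[1].class_label,
                )
            )
    return out


def filter_by_structure(
    boxes: Iterable[BoundingBox],
    structure: str,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[BoundingBox]:
    """Drop low-confidence predictions and wrong-artery segment boxes.

    Predictions with score below ``score_threshold`` are discarded; segment
    boxes of the artery opposite to the video's structure are removed;
    stenosis and instrument boxes pass through (subject only to the score
    cut).
    """
    if structure not in ("RCA", "LCA"):
        raise ValueError("structure must be RCA or LCA")
    kept = []
    for box in boxes:
        if box.score < score_threshold:
            continue
        if seg.is_segment(box.class_label) and seg.artery_side(box.class_label) != structure:
            continue
        kept.append(box)
    return kept


def select_central_reference(
    areas: Sequence[ReferenceArea], n_frames: int
) -> ReferenceArea:
    """Pick the reference area closest to the video midpoint (T-1)/2.

    Ties go to the earlier frame, which makes the choice independent of the
    candidate ordering.
    """
    if not areas:
        raise ValueError("no candidate reference areas")
    mid = (n_frames - 1) / 2.0
    return min(areas, key=lambda a: (abs(a.reference_frame - mid), a.reference_frame))
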
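"""Stenosis-box registration: standardize, track, smooth, crop.

Each stenosis box is first resized to a square whose physical side is as
close as possible to 17.5 mm given the video's pixel spacing.  A correlation
template tracker, initialized on the reference-frame content of that box, then
estimates a translation-only displacement for every frame, running outward
from the reference frame in both directions.  The raw displacement series is
smoothed with a centred uniform (moving-average) filter to suppress
single-frame tracker jumps, and the video is finally cropped at the translated
box to yield a fixed-size, motion-compensated clip.

Displacements are integer pixels (crop-shift, no resampling), which keeps the
clip resolution-exact.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.feature import match_template

from .types import AngioVideo, BoundingBox, DisplacementSeries, RegisteredClip

TARGET_BOX_MM = 17.5
DEFAULT_SMOOTHING_WINDOW = 3
CLIP_FRAMES = 24


def standardize_box(
    box: BoundingBox, pixel_spacing_mm: float, frame_shape: tuple[int, int],
    target_mm: float = TARGET_BOX_MM,
) -> BoundingBox:
    """Resize a stenosis box to a square of physical side closest to target_mm.

    The integer pixel side minimizing ``|side * spacing - target_mm|`` is
    chosen and the square is centred on the input box's centre, shifting the
    centre where needed to stay within the frame.
    """
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    h, w = frame_shape
    side = max(1, int(round(target_mm / pixel_spacing_mm)))
    # round() can be off by one for the |side*spacing - target| objective
    side = min(
        (side - 1, side, side + 1),
        key=lambda s: (abs(s * pixel_spacing_mm - target_mm), s) if s >= 1 else (np.inf, s),
    )
    if side > min(h, w):
        raise ValueError(
            f"standardized side {side} px exceeds frame bounds {frame_shape}"
        )
    cx, cy = box.center
    x0 = int(round(cx - (side - 1) / 2.0))
    y0 = int(round(cy - (side - 1) / 2.0))
    x0 = min(max(x0, 0), w - side)
    y0 = min(max(y0, 0), h - side)
    return BoundingBox(
        frame_index=box.frame_index,
        x0=x0, y0=y0, x1=x0 + side, y1=y0 + side,
        class_label=box.class_label,
        score=box.score,
    )


class CorrelationTemplateTracker:
    """Translation estimator: normalized cross-correlation against a template.

    Satisfies the tracker contract used by :func:`track_displacements`: it is
    initialized on a template patch and, frame by frame, returns the patch
    translation maximizing the zero-normalized cross-correlation inside a
    search window around the previous position, together with the correlation
    peak as a confidence.  NCC is invariant to affine intensity changes, which
    makes the tracker robust to the contrast wash-in/out of angiograms.
    """

    def __init__(self, search_radius: int = 25, min_confidence: float = 0.2):
        self.search_radius = search_radius
        self.min_confidence = min_confidence
        self._template: np.ndarray | None = None
        self._box: BoundingBox | None = None

    def init(self, frame: np.ndarray, box: BoundingBox) -> None:
        if box.width < 2 or box.height < 2:
            raise ValueError("degenerate template box")
        self._template = frame[box.y0:box.y1, box.x0:box.x1].astype(np.float32)
        self._box = box

    def update(self, frame: np.ndarray, prev_offset: tuple[int, int]) -> tuple[int, int, float]:
        """Return (dx, dy, confidence) for this frame.

        On failure (correlation peak below ``min_confidence``) the previous
        offset is returned with confidence 0.
        """
        assert self._template is not None and self._box is not None
        box, r = self._box, self.search_radius
        h, w = frame.shape
        px, py = prev_offset
        y0 = box.y0 + py - r
        x0 = box.x0 + px - r
        window = _padded_crop(
            frame.astype(np.float32), y0, y0 + box.height + 2 * r, x0, x0 + box.width + 2 * r
        )
        if window.std() == 0 or self._template.std() == 0:
            return px, py, 0.0
        resp = match_template(window, self._template, pad_input=False)
        peak = float(resp.max())
        if peak < self.min_confidence:
            return px, py, 0.0
        iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
        dy = y0 + int(iy) - box.y0
        dx = x0 + int(ix) - box.x0
        return dx, dy, float(np.clip(peak, 0.0, 1.0))


def _padded_crop(img: np.ndarray, y0: int, y1: int, x0: int, x1: int) -> np.ndarray:
    """Crop with edge replication; works even for fully out-of-bounds windows."""
    h, w = img.shape
    yy = np.clip(np.arange(y0, y1), 0, h - 1)
    xx = np.clip(np.arange(x0, x1), 0, w - 1)
    return img[np.ix_(yy, xx)]


def track_displacements(
    video: AngioVideo,
    ref_box: BoundingBox,
    ref_frame: int,
    tracker: CorrelationTemplateTracker | None = None,
) -> DisplacementSeries:
    """Track the reference box bidirectionally through the video.

    The tracker is initialized on the reference frame; frames are visited
    forward (ref+1 .. end) and backward (ref-1 .. 0), each step searching
    around the previous frame's offset.  A failed step carries over the
    nearest successful offset with confidence 0.
    """
    h, w = video.frame_shape
    if not (0 <= ref_box.x0 and ref_box.x1 <= w and 0 <= ref_box.y0 and ref_box.y1 <= h):
        raise ValueError("ref_box must lie within frame bounds")
    t = video.n_frames
    if not 0 <= ref_frame < t:
        raise ValueError("ref_frame out of range")

    tracker = tracker or CorrelationTemplateTracker()
    tracker.init(video.frames[ref_frame], ref_box)

    dx = np.zeros(t, dtype=int)
    dy = np.zeros(t, dtype=int)
    conf = np.zeros(t, dtype=float)
    conf[ref_frame] = 1.0

    for indices in (range(ref_frame + 1, t), range(ref_frame - 1, -1, -1)):
        prev = (0, 0)
        for i in indices:
            ox, oy, c = tracker.update(video.frames[i], prev)
            dx[i], dy[i], conf[i] = ox, oy, c
            if c > 0:
                prev = (ox, oy)
    return DisplacementSeries(dx=dx, dy=dy, reference_frame=ref_frame, confidence=conf)


def smooth_displacements(
    series: DisplacementSeries, window: int = DEFAULT_SMOOTHING_WINDOW
) -> DisplacementSeries:
    """Centred moving-average smoothing of dx/dy with edge replication.

    After smoothing, offsets are rounded to integers and the series is
    re-pinned so the reference frame is exactly (0, 0).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return DisplacementSeries(
            dx=series.dx.copy(), dy=series.dy.copy(),
            reference_frame=series.reference_frame,
            confidence=series.confidence.copy(),
        )
    sm_dx = np.rint(uniform_filter1d(series.dx.astype(float), window, mode="nearest")).astype(int)
    sm_dy = np.rint(uniform_filter1d(series.dy.astype(float), window, mode="nearest")).astype(int)
    r = series.reference_frame
    sm_dx -= sm_dx[r]
    sm_dy -= sm_dy[r]
    return DisplacementSeries(
        dx=sm_dx, dy=sm_dy, reference_frame=r, confidence=series.confidence.copy()
    )


def apply_registration(
    video: AngioVideo, series: DisplacementSeries, ref_box: BoundingBox,
    segment_id: str | None = None,
) -> RegisteredClip:
    """Crop every frame at the reference box translated by its offset.

    Out-of-bounds crops are padded with edge replication so the clip size is
    constant.
    """
    if len(series) != video.n_frames:
        raise ValueError("displacement series must cover every frame")
    side_y, side_x = ref_box.height, ref_box.width
    out = np.empty((video.n_frames, side_y, side_x), dtype=video.frames.dtype)
    for i in range(video.n_frames):
        y0 = ref_box.y0 + int(series.dy[i])
        x0 = ref_box.x0 + int(series.dx[i])
        out[i] = _padded_crop(video.frames[i], y0, y0 + side_y, x0, x0 + side_x)
    return RegisteredClip(
        frames=out,
        box_side_px=side_x,
        box_side_mm=side_x * video.pixel_spacing_mm,
        dicom_id=video.dicom_id,
        reference_frame=series.reference_frame,
        segment_id=segment_id,
    )


def clip_window_indices(n_total: int, ref_frame: int, n_frames: int = CLIP_FRAMES) -> np.ndarray:
    """Frame indices of an ``n_frames`` window centred on the reference frame.

    The window starts at ``ref - (n_frames - 1) // 2``; indices beyond either
    end are clamped, replicating the terminal frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    start = ref_frame - (n_frames - 1) // 2
    return np.clip(np.arange(start, start + n_frames), 0, n_total - 1)


def extract_clip_window(clip: RegisteredClip, n_frames: int = CLIP_FRAMES) -> RegisteredClip:
    """Temporal window of ``n_frames`` centred on the clip's reference frame."""
    idx = clip_window_indices(clip.n_frames, clip.reference_frame, n_frames)
    return RegisteredClip(
        frames=clip.frames[idx],
        box_side_px=clip.box_side_px,
        box_side_mm=clip.box_side_mm,
        dicom_id=clip.dicom_id,
        reference_frame=int(np.searchsorted(idx, clip.reference_frame)),
        segment_id=clip.segment_id,
    )
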
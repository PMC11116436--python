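"""Stenosis severity prediction.

The learned severity regressor is a plug-in contract: any callable mapping a
24-frame registered clip (plus an artery one-hot and normalized patient age)
to a sigmoid-bounded value in [0, 1], scaled to a stenosis percentage.

The module also ships a deterministic *geometric reference predictor* so the
pipeline produces meaningful severities without any trained weights: it
measures the vessel width profile along the segment's skeleton in the clip's
central frame (distance-transform diameters) and reports the percent diameter
reduction of the narrowest point relative to a robust reference width.  This
is a classical QCA-style estimate, not a learned model.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, uniform_filter1d
from skimage.morphology import skeletonize

from . import segments as seg
from .types import RegisteredClip

CLIP_FRAMES = 24
DEFAULT_BINARIZATION_THRESHOLD = 0.23  # on the raw [0, 1] scale
GT_SEVERE_THRESHOLD_PCT = 70.0
QCA_SEVERE_THRESHOLD_PCT = 50.0


@dataclass
class SeverityInput:
    clip: RegisteredClip
    artery_onehot: tuple[float, float]  # (RCA, LCA)
    age_norm: float

    def __post_init__(self) -> None:
        if self.clip.n_frames != CLIP_FRAMES:
            raise ValueError(f"clip must have {CLIP_FRAMES} frames")
        if abs(sum(self.artery_onehot) - 1.0) > 1e-9:
            raise ValueError("artery_onehot must sum to 1")
        if not 0.0 <= self.age_norm <= 1.0:
            raise ValueError("age_norm must lie in [0, 1]")


@dataclass
class SeverityPrediction:
    raw: float  # [0, 1]
    model_id: str = ""

    @property
    def pct(self) -> float:
        return 100.0 * self.raw


#: severity model contract: SeverityInput -> raw value in [0, 1]
SeverityModel = Callable[[SeverityInput], float]


def normalize_age(age_years: float | None) -> float:
    """Patient age scaled to [0, 1] (age / 100, clamped); missing age -> 0.5."""
    if age_years is None:
        return 0.5
    return float(np.clip(age_years / 100.0, 0.0, 1.0))


def predict_severity(inp: SeverityInput, model: SeverityModel, model_id: str = "") -> SeverityPrediction:
    """Run a severity model; out-of-range output is a contract violation."""
    raw = float(model(inp))
    if not 0.0 <= raw <= 1.0:
        raise ValueError(f"severity model output {raw} outside [0, 1]")
    return SeverityPrediction(raw=raw, model_id=model_id)


def _width_profile(mask: np.ndarray) -> np.ndarray:
    """Vessel diameters (px) at skeleton points, away from the crop border.

    For a straight strip of w foreground pixels the centre pixel's Euclidean
    distance to the nearest background pixel is (w+1)/2, hence the diameter
    estimate 2*EDT - 1.  Where the tube is truncated by the crop boundary,
    skeletonization grows spurs toward the cut-face corners whose widths are
    meaningless; skeleton points within one vessel radius of the border are
    therefore discarded (unless that empties the profile).
    """
    skel = skeletonize(mask)
    edt = distance_transform_edt(mask)
    margin = int(np.ceil(edt.max())) + 2
    pruned = _prune_spurs(skel, n_iter=margin)
    if pruned.any():
        skel = pruned
    if margin > 0 and 2 * margin < min(mask.shape):
        trimmed = np.zeros_like(skel)
        trimmed[margin:-margin, margin:-margin] = skel[margin:-margin, margin:-margin]
        if trimmed.any():
            skel = trimmed

    ys, xs = np.nonzero(skel)
    widths = 2.0 * edt[ys, xs] - 1.0
    if widths.size < 5:
        return widths
    # digital tubes carry ~1 px staircase fluctuation in the EDT diameter;
    # smooth the profile along the path (ordered by principal-axis
    # projection) so the minimum reflects anatomy, not quantization
    coords = np.column_stack([xs, ys]).astype(float)
    coords -= coords.mean(axis=0)
    axis = np.linalg.svd(coords, full_matrices=False)[2][0]
    order = np.argsort(coords @ axis)
    profile = widths[order]
    if profile.size > 12:
        profile = profile[3:-3]  # path ends still feel the truncation
    return uniform_filter1d(profile, 5, mode="nearest")


def _prune_spurs(skel: np.ndarray, n_iter: int) -> np.ndarray:
    """Iteratively strip skeleton endpoints, removing side spurs shorter than
    ``n_iter`` (the main path loses at most ``n_iter`` pixels per end, which
    the border trim discards anyway)."""
    from scipy.ndimage import convolve

    skel = skel.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(n_iter):
        neighbours = convolve(skel.astype(int), kernel, mode="constant") - skel
        endpoints = skel & (neighbours <= 1)
        if not endpoints.any():
            break
        skel &= ~endpoints
    return skel


def geometric_reference_severity(
    clip_segmentation: np.ndarray, segment_id: str
) -> SeverityPrediction:
    """Percent diameter stenosis measured from the clip's segmentation.

    On the temporally central frame containing the segment, vessel widths are
    measured along the skeleton via the Euclidean distance transform;
    severity = 100 * (1 - min_width / reference_width), with the reference
    width the median of the top quartile of widths, clamped to [0, 100].
    """
    labels = np.asarray(clip_segmentation)
    if labels.ndim == 2:
        labels = labels[None]
    cls = seg.class_index(segment_id)
    present = [t for t in range(labels.shape[0]) if (labels[t] == cls).any()]
    if not present:
        raise ValueError(f"segment {segment_id} absent from every clip frame")
    mid = (labels.shape[0] - 1) / 2.0
    t = min(present, key=lambda i: (abs(i - mid), i))
    mask = labels[t] == cls

    widths = _width_profile(mask)
    widths = widths[widths > 0]
    if widths.size == 0:
        raise ValueError(f"segment {segment_id} too thin to measure in frame {t}")
    top_quartile = widths[widths >= np.quantile(widths, 0.75)]
    reference = float(np.median(top_quartile))
    min_width = float(widths.min())
    raw = float(np.clip(1.0 - min_width / reference, 0.0, 1.0))
    return SeverityPrediction(raw=raw, model_id="geometric-reference")


def binarize_severity(value: float, threshold: float) -> bool:
    """Severe / non-severe decision under the >= rule.

    ``value`` and ``threshold`` must share a scale: raw [0, 1] predictions
    against the 0.23 operating point, report percentages against 70, QCA
    percentages against 50.
    """
    return value >= threshold
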
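"""Multi-class segmentation ensembling, labelling and quality metrics.

The segmentation networks themselves are plug-ins; this module owns the
model-agnostic logic: averaging the per-class probability maps of an ensemble,
converting probabilities to label maps by per-pixel argmax (with a tie-break
that prefers vessel classes over background and then the lowest SYNTAX index),
and computing Dice / PPV / sensitivity per class with a truth-pixel-weighted
average across segments.

Probability maps are arrays of shape ``(..., C, H, W)`` with C = 12 classes
(background + 11 segments); label maps are integer arrays of shape
``(..., H, W)`` with values indexing :data:`coroquant.segments.CLASS_NAMES`.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np

from . import segments as seg

log = logging.getLogger(__name__)

#: A frame segmenter maps a grayscale frame to (C, H, W) class probabilities.
#: ``frame_index`` and ``window`` (y0, y1, x0, x1 in source-frame coordinates)
#: allow truth-backed reference segmenters to answer positionally.
FrameSegmenter = Callable[..., np.ndarray]

SIMPLEX_TOL = 1e-6

# class-preference order for argmax ties: vessels in ascending SYNTAX index,
# background last.  Vessel class indices 1..11 are already in SYNTAX order.
_TIE_ORDER = np.array(
    sorted(range(seg.N_CLASSES), key=lambda c: (c == 0, 0 if c == 0 else seg.SEGMENTS[seg.CLASS_NAMES[c]].syntax_index))
)


def _check_simplex(p: np.ndarray) -> None:
    if np.any(p < -SIMPLEX_TOL):
        raise ValueError("probabilities must be non-negative")
    sums = p.sum(axis=-3)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("per-pixel class probabilities must sum to 1")


def ensemble_average(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of the member probability maps."""
    if len(maps) == 0:
        raise ValueError("ensemble needs at least one member")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"member shape mismatch: {shapes}")
    return np.mean(np.stack([np.asarray(m, dtype=float) for m in maps]), axis=0)


def argmax_map(p: np.ndarray) -> np.ndarray:
    """Per-pixel most probable class with a vessel-preferring tie-break.

    Exact probability ties are resolved toward vessel classes (background
    last) and, among vessels, toward the lowest SYNTAX index — this prevents
    thin vessels from dropping out under symmetric ensemble disagreement.
    """
    p = np.asarray(p, dtype=float)
    reordered = np.take(p, _TIE_ORDER, axis=-3)
    picked = np.argmax(reordered, axis=-3)  # first max wins -> preferred class
    return _TIE_ORDER[picked]


def segment_video(
    frames: np.ndarray,
    models: Sequence[FrameSegmenter],
    frame_indices: Sequence[int] | None = None,
    windows: Sequence[tuple[int, int, int, int]] | tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Segment each frame with the model ensemble: average then argmax.

    ``frame_indices`` and ``windows`` (a single (y0, y1, x0, x1) tuple or one
    per frame, in source-frame coordinates) are forwarded to the segmenters
    so positional reference implementations can answer; learned models ignore
    them.
    """
    if len(models) == 0:
        raise ValueError("need at least one segmenter")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    per_frame_windows = (
        windows if windows is not None and not isinstance(windows, tuple) else None
    )
    out = np.empty(frames.shape, dtype=np.int64)
    for t in range(frames.shape[0]):
        idx = None if frame_indices is None else frame_indices[t]
        win = per_frame_windows[t] if per_frame_windows is not None else windows
        member_maps = [m(frames[t], frame_index=idx, window=win) for m in models]
        avg = ensemble_average(member_maps)
        _check_simplex(avg)
        out[t] = argmax_map(avg)
    return out


@dataclass
class SegMetrics:
    """Per-class and truth-weighted segmentation quality."""

    dice: dict[int, float]
    ppv: dict[int, float]
    sensitivity: dict[int, float]
    weighted_dice: float
    weighted_ppv: float
    weighted_sensitivity: float


def seg_metrics(
    pred: np.ndarray, truth: np.ndarray, include_background: bool = False
) -> SegMetrics:
    """Dice, PPV and sensitivity per class plus truth-weighted averages.

    Weights are the truth pixel counts per class; classes absent from both
    prediction and truth are excluded.  Undefined ratios (empty denominator)
    are reported as 0 with a warning.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    classes = range(0 if include_background else 1, seg.N_CLASSES)

    dice: dict[int, float] = {}
    ppv: dict[int, float] = {}
    sens: dict[int, float] = {}
    weights: dict[int, int] = {}
    for c in classes:
        p = pred == c
        t = truth == c
        tp = int(np.count_nonzero(p & t))
        fp = int(np.count_nonzero(p & ~t))
        fn = int(np.count_nonzero(~p & t))
        if tp + fp + fn == 0:
            continue  # class absent from both
        dice[c] = 2 * tp / (2 * tp + fp + fn)
        if tp + fp == 0:
            log.warning("class %s absent from prediction; PPV reported as 0", seg.class_name(c))
            ppv[c] = 0.0
        else:
            ppv[c] = tp / (tp + fp)
        if tp + fn == 0:
            log.warning("class %s absent from truth; sensitivity reported as 0", seg.class_name(c))
            sens[c] = 0.0
        else:
            sens[c] = tp / (tp + fn)
        weights[c] = tp + fn  # truth pixel count

    total = sum(weights.values())
    if total == 0:
        # truth entirely background: fall back to unweighted means
        wavg = lambda d: float(np.mean(list(d.values()))) if d else 0.0
    else:
        wavg = lambda d: sum(d[c] * weights[c] for c in d) / total
    return SegMetrics(
        dice=dice, ppv=ppv, sensitivity=sens,
        weighted_dice=wavg(dice), weighted_ppv=wavg(ppv), weighted_sensitivity=wavg(sens),
    )
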
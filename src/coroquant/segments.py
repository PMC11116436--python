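"""Coronary segment taxonomy.

Eleven epicardial segments are analysed: five on the right coronary artery
(proximal, middle and distal RCA, the posterior descending artery and the
posterolateral branch) and six on the left (left main, proximal/middle/distal
LAD, proximal and distal LCX).  Each segment carries the standard SYNTAX
segment number, used throughout the pipeline as a deterministic tie-break key,
and the artery side it belongs to.

Class index 0 is background; vessel classes are indexed 1..11 in ascending
SYNTAX order so that ``numpy.argmax`` tie behaviour coincides with the
lowest-SYNTAX-index preference.
"""

from __future__ import annotations

from dataclasses import dataclass

RCA = "RCA"
LCA = "LCA"

BACKGROUND = "background"


@dataclass(frozen=True)
class SegmentInfo:
    code: str
    artery_side: str
    syntax_index: int
    class_index: int


# (code, side, SYNTAX segment number) in ascending SYNTAX order
_SEGMENT_DEFS: tuple[tuple[str, str, int], ...] = (
    ("prox-RCA", RCA, 1),
    ("mid-RCA", RCA, 2),
    ("dist-RCA", RCA, 3),
    ("PDA", RCA, 4),
    ("left-main", LCA, 5),
    ("prox-LAD", LCA, 6),
    ("mid-LAD", LCA, 7),
    ("dist-LAD", LCA, 8),
    ("prox-LCX", LCA, 11),
    ("dist-LCX", LCA, 13),
    ("RCA-posterolateral", RCA, 16),
)

SEGMENTS: dict[str, SegmentInfo] = {
    code: SegmentInfo(code, side, syntax, i + 1)
    for i, (code, side, syntax) in enumerate(_SEGMENT_DEFS)
}

SEGMENT_CODES: tuple[str, ...] = tuple(SEGMENTS)
N_CLASSES: int = len(SEGMENT_CODES) + 1  # + background

#: class index -> code ("background" at 0)
CLASS_NAMES: tuple[str, ...] = (BACKGROUND,) + SEGMENT_CODES

INSTRUMENT_CLASSES: frozenset[str] = frozenset({"guidewire", "balloon", "stent"})
STENOSIS_CLASS = "stenosis"


def artery_side(code: str) -> str:
    return SEGMENTS[code].artery_side


def syntax_index(code: str) -> int:
    return SEGMENTS[code].syntax_index


def class_index(code: str) -> int:
    """Integer label used in segmentation maps (background == 0)."""
    if code == BACKGROUND:
        return 0
    return SEGMENTS[code].class_index


def class_name(index: int) -> str:
    return CLASS_NAMES[index]


def segments_of_side(side: str) -> tuple[str, ...]:
    return tuple(c for c in SEGMENT_CODES if SEGMENTS[c].artery_side == side)


def is_segment(code: str) -> bool:
    return code in SEGMENTS
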
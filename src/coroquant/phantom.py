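"""Vessel-motion phantom: synthetic angiograms with complete ground truth.

The phantom emulates the data regime of clinical cine angiography — 512x512
grayscale frames at 15 fps with ~0.35 mm pixels — at the level of detail the
pipeline's non-neural algorithms care about: a dark tubular vessel with a
parametric width profile and known percent-diameter stenoses, rigid global
motion from summed cardiac (~1 Hz) and respiratory (~0.25 Hz) sinusoids,
contrast wash-in/out, Gaussian noise, and optional instrument boxes marking
PCI frames.  Every rendered quantity (per-frame displacement, multi-class
segment masks, stenosis/segment/instrument boxes, true severities, clinical
report rows) is emitted as ground truth in the pipeline's own coordinate
conventions.

Because the scene moves rigidly, frames and masks are rendered once in base
coordinates and translated per frame; the truth masks of frame t are exactly
the frame-0 masks shifted by the relative truth displacement.

Deliberately not modelled: foreshortening, branch overlap, panning, and
photorealistic X-ray texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter1d, shift as nd_shift
from scipy.spatial import cKDTree

from . import segments as seg
from .types import AngioVideo, BoundingBox, ClinicalReportRow, PciInterval

# ------------------------------------------------------------------ specs

@dataclass(frozen=True)
class StenosisSpec:
    segment_id: str
    position: float  # fractional position along that segment's centreline
    severity_pct: float
    length_mm: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity_pct <= 100.0:
            raise ValueError("severity_pct must lie in [0, 100]")
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must lie in [0, 1]")


@dataclass(frozen=True)
class MotionSpec:
    """Two-sinusoid rigid motion, amplitudes in px and frequencies in Hz."""

    cardiac_amp: tuple[float, float] = (8.0, 6.0)
    cardiac_hz: float = 1.0
    respiratory_amp: tuple[float, float] = (3.0, 4.0)
    respiratory_hz: float = 0.25
    cardiac_phase: tuple[float, float] = (0.0, 1.2)
    respiratory_phase: tuple[float, float] = (0.7, 0.0)


@dataclass
class PhantomSpec:
    image_size: int = 512
    fps: float = 15.0
    n_frames: int = 76
    pixel_spacing_mm: float = 0.35
    artery_side: str = "RCA"
    base_diameter_mm: float = 4.0
    stenoses: list[StenosisSpec] = field(default_factory=list)
    motion: MotionSpec = field(default_factory=MotionSpec)
    wash_in_frames: int = 8
    wash_out_start_frac: float = 0.8
    contrast_floor: float = 0.3
    noise_sigma: float = 5.0
    n_distractors: int = 2
    instrument_frames: list[tuple[int, int]] = field(default_factory=list)
    patient_id: str = "phantom-000"
    patient_age: float = 65.0
    study_date: str = "20240101"
    acquisition_time: datetime = field(
        default_factory=lambda: datetime(2024, 1, 1, 10, 0, 0)
    )
    dicom_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        amp = max(
            max(self.motion.cardiac_amp) + max(self.motion.respiratory_amp), 1.0
        )
        if amp >= self.image_size / 4:
            raise ValueError("motion amplitude must stay below image_size / 4")


#: fraction of arclength covered by each segment, per artery side
_SEGMENT_FRACTIONS: dict[str, tuple[tuple[str, float], ...]] = {
    "RCA": (("prox-RCA", 0.30), ("mid-RCA", 0.30), ("dist-RCA", 0.25), ("PDA", 0.15)),
    "LCA": (("left-main", 0.12), ("prox-LAD", 0.28), ("mid-LAD", 0.30), ("dist-LAD", 0.30)),
}


@dataclass(frozen=True)
class StenosisTruth:
    segment_id: str
    severity_pct: float
    center_xy: tuple[float, float]  # base-scene coordinates
    box: BoundingBox  # base-scene square box on frame 0


@dataclass
class PhantomTruth:
    """Ground truth rendered alongside a phantom video, base-scene indexed."""

    displacements: np.ndarray  # (T, 2) int, (dx, dy) applied to the base scene
    base_mask: np.ndarray  # (H, W) uint8 class indices
    base_segment_boxes: list[BoundingBox]  # enclosing bbox per segment mask
    stenoses: list[StenosisTruth]
    instrument_boxes: list[BoundingBox]  # already frame-indexed
    report_rows: list[ClinicalReportRow]
    artery_side: str = "RCA"
    centreline_xy: np.ndarray | None = None  # (N, 2) base coordinates
    width_profile_px: np.ndarray | None = None
    # local detector-style segment boxes sliding along the centreline; these
    # are what a detection model emits and what stenosis boxes pair with
    base_sliding_boxes: list[BoundingBox] = field(default_factory=list)

    def mask(self, t: int) -> np.ndarray:
        dx, dy = self.displacements[t]
        return _shift2d(self.base_mask, dx, dy, order0=True)

    def masks(self) -> np.ndarray:
        return np.stack([self.mask(t) for t in range(len(self.displacements))])

    def boxes(self, t: int) -> list[BoundingBox]:
        """Detector-style truth boxes of frame t (stenosis + segment + instruments)."""
        dx, dy = (int(v) for v in self.displacements[t])
        out = [s.box.translated(dx, dy, frame_index=t) for s in self.stenoses]
        out += [b.translated(dx, dy, frame_index=t) for b in self.base_sliding_boxes]
        out += [b for b in self.instrument_boxes if b.frame_index == t]
        return out

    def all_boxes(self) -> list[BoundingBox]:
        return [b for t in range(len(self.displacements)) for b in self.boxes(t)]

    def severity_of(self, segment_id: str) -> float:
        for s in self.stenoses:
            if s.segment_id == segment_id:
                return s.severity_pct
        return 0.0


def _shift2d(img: np.ndarray, dx: int, dy: int, order0: bool = False) -> np.ndarray:
    return nd_shift(
        img, (int(dy), int(dx)), order=0 if order0 else 1, mode="nearest", prefilter=False
    )


# ------------------------------------------------------------------ geometry

def _centreline(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Dense smooth centreline samples (N, 2) and cumulative arclength (N,)."""
    size = spec.image_size
    margin = size * 0.22
    n_ctrl = 7
    u = np.linspace(0.0, 1.0, n_ctrl)
    x = margin + u * (size - 2 * margin)
    y = size / 2 + 0.18 * size * np.sin(2 * np.pi * 0.6 * u + rng.uniform(0, 2 * np.pi))
    y += rng.normal(0.0, size * 0.015, n_ctrl)
    y = np.clip(y, margin, size - margin)
    if spec.artery_side == "RCA":
        x, y = y, x  # mostly vertical course, as the RCA appears in LAO views

    # densify then smooth to a gently curving path
    t_dense = np.linspace(0.0, 1.0, 60)
    xd = np.interp(t_dense, u, x)
    yd = np.interp(t_dense, u, y)
    xd = gaussian_filter1d(xd, 3, mode="nearest")
    yd = gaussian_filter1d(yd, 3, mode="nearest")

    # resample at ~0.5 px spacing
    d = np.hypot(np.diff(xd), np.diff(yd))
    s = np.r_[0.0, np.cumsum(d)]
    n = max(int(s[-1] / 0.5), 64)
    s_new = np.linspace(0.0, s[-1], n)
    pts = np.column_stack([np.interp(s_new, s, xd), np.interp(s_new, s, yd)])
    return pts, s_new


def _segment_labels_along(spec: PhantomSpec, arclength: np.ndarray) -> np.ndarray:
    """Class index of each centreline sample from the per-side fractions."""
    fracs = _SEGMENT_FRACTIONS[spec.artery_side]
    total = arclength[-1]
    bounds = np.cumsum([f for _, f in fracs]) * total
    labels = np.empty(arclength.size, dtype=np.uint8)
    lo = 0.0
    for (code, _), hi in zip(fracs, bounds):
        sel = (arclength >= lo) & (arclength <= hi + 1e-9)
        labels[sel] = seg.class_index(code)
        lo = hi
    return labels


def _radius_profile(
    spec: PhantomSpec, arclength: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Per-sample vessel radius in px after applying the stenosis notches."""
    base_r = spec.base_diameter_mm / spec.pixel_spacing_mm / 2.0
    r = np.full(arclength.size, base_r)
    fracs = _SEGMENT_FRACTIONS[spec.artery_side]
    total = arclength[-1]
    bounds = np.r_[0.0, np.cumsum([f for _, f in fracs]) * total]
    seg_span = {code: (bounds[i], bounds[i + 1]) for i, (code, _) in enumerate(fracs)}
    for st in spec.stenoses:
        if st.segment_id not in seg_span:
            raise ValueError(
                f"stenosis segment {st.segment_id} not in the {spec.artery_side} layout"
            )
        lo, hi = seg_span[st.segment_id]
        s0 = lo + st.position * (hi - lo)
        sigma = st.length_mm / spec.pixel_spacing_mm / 4.0
        notch = (st.severity_pct / 100.0) * np.exp(-0.5 * ((arclength - s0) / sigma) ** 2)
        r *= 1.0 - notch
    return r


# ------------------------------------------------------------------ rendering

def _render_base_scene(spec: PhantomSpec, rng: np.random.Generator):
    """Render the static scene once; frames are shifted copies of it.

    Returns (vessel_depth, base_mask, distractor_depth, centreline, radius,
    arclength).
    """
    size = spec.image_size
    pts, s = _centreline(spec, rng)
    labels = _segment_labels_along(spec, s)
    radius = _radius_profile(spec, s, labels)

    depth = np.zeros((size, size), dtype=np.float32)
    mask = np.zeros((size, size), dtype=np.uint8)
    rmax = radius.max()
    x0 = max(int(pts[:, 0].min() - rmax - 2), 0)
    x1 = min(int(pts[:, 0].max() + rmax + 3), size)
    y0 = max(int(pts[:, 1].min() - rmax - 2), 0)
    y1 = min(int(pts[:, 1].max() + rmax + 3), size)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    dist, idx = cKDTree(pts).query(pix, k=1)
    r_here = radius[idx]
    inside = dist <= r_here
    # X-ray attenuation of a cylinder: proportional to the chord length
    chord = np.zeros_like(dist)
    chord[inside] = 2.0 * np.sqrt(
        np.maximum(r_here[inside] ** 2 - dist[inside] ** 2, 0.0)
    )
    depth[yy.ravel()[inside], xx.ravel()[inside]] = chord[inside]
    mask[yy.ravel()[inside], xx.ravel()[inside]] = labels[idx[inside]]

    distractor = np.zeros((size, size), dtype=np.float32)
    for _ in range(spec.n_distractors):
        # faint static wire: a thin, slightly curved line
        u = np.linspace(0, 1, 200)
        wx = rng.uniform(0.1, 0.9) * size + (u - 0.5) * rng.uniform(0.3, 0.8) * size
        wy = rng.uniform(0.1, 0.9) * size + 30 * np.sin(2 * np.pi * u * rng.uniform(0.5, 2))
        wi = np.clip(np.round(wy).astype(int), 0, size - 1)
        wj = np.clip(np.round(wx).astype(int), 0, size - 1)
        distractor[wi, wj] = 25.0
    return depth, mask, distractor, pts, radius, s


def _displacements(spec: PhantomSpec) -> np.ndarray:
    t = np.arange(spec.n_frames) / spec.fps
    m = spec.motion
    dx = m.cardiac_amp[0] * np.sin(2 * np.pi * m.cardiac_hz * t + m.cardiac_phase[0]) + m.respiratory_amp[0] * np.sin(2 * np.pi * m.respiratory_hz * t + m.respiratory_phase[0])
    dy = m.cardiac_amp[1] * np.sin(2 * np.pi * m.cardiac_hz * t + m.cardiac_phase[1]) + m.respiratory_amp[1] * np.sin(2 * np.pi * m.respiratory_hz * t + m.respiratory_phase[1])
    return np.column_stack([np.rint(dx), np.rint(dy)]).astype(int)


def _contrast_curve(spec: PhantomSpec) -> np.ndarray:
    t = np.arange(spec.n_frames, dtype=float)
    c = np.ones(spec.n_frames)
    if spec.wash_in_frames > 0:
        ramp = np.clip(t / spec.wash_in_frames, 0.0, 1.0)
        c *= ramp
    out_start = int(spec.wash_out_start_frac * spec.n_frames)
    if out_start < spec.n_frames - 1:
        fall = (t - out_start) / (spec.n_frames - 1 - out_start)
        c = np.where(t > out_start, np.maximum(1.0 - (1.0 - spec.contrast_floor) * fall, spec.contrast_floor), c)
    return c


def _stenosis_boxes(
    spec: PhantomSpec, pts: np.ndarray, s: np.ndarray
) -> list[StenosisTruth]:
    out = []
    fracs = _SEGMENT_FRACTIONS[spec.artery_side]
    total = s[-1]
    bounds = np.r_[0.0, np.cumsum([f for _, f in fracs]) * total]
    seg_span = {code: (bounds[i], bounds[i + 1]) for i, (code, _) in enumerate(fracs)}
    for st in spec.stenoses:
        lo, hi = seg_span[st.segment_id]
        s0 = lo + st.position * (hi - lo)
        i0 = int(np.argmin(np.abs(s - s0)))
        cx, cy = pts[i0]
        side = int(np.clip(round(1.75 * st.length_mm / spec.pixel_spacing_mm), 24, 64))
        x0 = int(round(cx - side / 2))
        y0 = int(round(cy - side / 2))
        box = BoundingBox(
            frame_index=0, x0=x0, y0=y0, x1=x0 + side, y1=y0 + side,
            class_label=seg.STENOSIS_CLASS, score=1.0,
        )
        out.append(StenosisTruth(st.segment_id, st.severity_pct, (float(cx), float(cy)), box))
    return out


def _sliding_segment_boxes(
    pts: np.ndarray, s: np.ndarray, labels: np.ndarray,
    side: int = 40, step_px: float = 10.0,
) -> list[BoundingBox]:
    """Detector-style local segment boxes spaced along the centreline.

    A detection model emits box proposals around local vessel appearance, not
    one box per anatomical segment; these square boxes, one every ``step_px``
    of arclength and labelled with the local segment, reproduce that regime
    and give stenosis boxes realistic IoU > 0.5 partners.
    """
    out = []
    for target in np.arange(0.0, s[-1], step_px):
        i = int(np.argmin(np.abs(s - target)))
        cx, cy = pts[i]
        x0 = int(round(cx - side / 2))
        y0 = int(round(cy - side / 2))
        out.append(
            BoundingBox(0, x0, y0, x0 + side, y0 + side,
                        class_label=seg.class_name(int(labels[i])), score=1.0)
        )
    return out


def _segment_boxes(base_mask: np.ndarray) -> list[BoundingBox]:
    out = []
    for c in range(1, seg.N_CLASSES):
        ys, xs = np.nonzero(base_mask == c)
        if ys.size == 0:
            continue
        out.append(
            BoundingBox(
                frame_index=0,
                x0=int(xs.min()), y0=int(ys.min()),
                x1=int(xs.max()) + 1, y1=int(ys.max()) + 1,
                class_label=seg.class_name(c), score=1.0,
            )
        )
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[AngioVideo, PhantomTruth]:
    """Render one phantom video with its complete ground truth.

    The same spec (including its seed) always produces bitwise-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    depth, base_mask, distractor, pts, radius, arclen = _render_base_scene(spec, rng)
    disp = _displacements(spec)
    contrast = _contrast_curve(spec)

    background = 200.0
    atten = 140.0 / max(2.0 * radius.max(), 1.0)

    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size), dtype=np.uint8)
    for t in range(spec.n_frames):
        dx, dy = disp[t]
        scene = (
            background
            - contrast[t] * atten * _shift2d(depth, dx, dy)
            - _shift2d(distractor, dx, dy)
        )
        if spec.noise_sigma > 0:
            scene = scene + rng.normal(0.0, spec.noise_sigma, scene.shape)
        frames[t] = np.clip(scene, 0, 255).astype(np.uint8)

    sten_truth = _stenosis_boxes(spec, pts, arclen)

    instrument_boxes = []
    for (f0, f1) in spec.instrument_frames:
        for t in range(max(f0, 0), min(f1, spec.n_frames)):
            cx, cy = pts[len(pts) // 2]
            x0, y0 = int(cx) - 10, int(cy) - 10
            instrument_boxes.append(
                BoundingBox(frame_index=t, x0=x0, y0=y0, x1=x0 + 20, y1=y0 + 20,
                            class_label="guidewire", score=1.0)
            )

    report_rows = _report_rows(spec, sten_truth, rng=None)

    video = AngioVideo(
        frames=frames,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        fps=spec.fps,
        patient_id=spec.patient_id,
        study_date=spec.study_date,
        acquisition_time=spec.acquisition_time,
        dicom_id=spec.dicom_id or f"{spec.patient_id}.{spec.seed}",
        structure_label=spec.artery_side,
    )
    truth = PhantomTruth(
        displacements=disp,
        base_mask=base_mask,
        base_segment_boxes=_segment_boxes(base_mask),
        stenoses=sten_truth,
        instrument_boxes=instrument_boxes,
        report_rows=report_rows,
        artery_side=spec.artery_side,
        centreline_xy=pts,
        width_profile_px=2.0 * radius,
        base_sliding_boxes=_sliding_segment_boxes(
            pts, arclen, _segment_labels_along(spec, arclen)
        ),
    )
    return video, truth


def _report_rows(
    spec: PhantomSpec,
    stenoses: list[StenosisTruth],
    rng: np.random.Generator | None,
    observer_noise_sd: float = 0.0,
    pci_intervals: list[PciInterval] | None = None,
    cabg: bool = False,
) -> list[ClinicalReportRow]:
    """One report row per laid-out segment; unmentioned segments read 0%."""
    by_seg = {s.segment_id: s.severity_pct for s in stenoses}
    rows = []
    for code, _ in _SEGMENT_FRACTIONS[spec.artery_side]:
        pct = by_seg.get(code, 0.0)
        if observer_noise_sd > 0 and rng is not None and pct > 0:
            pct = float(np.clip(pct + rng.normal(0.0, observer_noise_sd), 0.0, 100.0))
        rows.append(
            ClinicalReportRow(
                patient_id=spec.patient_id,
                study_date=spec.study_date,
                segment_id=code,
                stenosis_pct=pct,
                pci_intervals=list(pci_intervals or []),
                cabg_flag=cabg,
            )
        )
    return rows


# ------------------------------------------------------------------ cohort

@dataclass
class CohortConfig:
    """Study conditions for a synthetic patient cohort.

    Defaults mirror the clinical regime the pipeline targets: roughly half of
    reported segments are healthy (0% stenosis), diseased severities spread
    widely, visual reports carry ~10% observer noise (inter-observer
    variability for visual grading is quoted at 6.9-26.4%), about 30% of
    patients undergo a PCI (yielding an instrument-laden later video plus a
    reported procedure interval), and about 10% carry a CABG flag.
    """

    healthy_fraction: float = 0.45
    severity_range: tuple[float, float] = (20.0, 90.0)
    observer_noise_sd: float = 10.0
    pci_fraction: float = 0.3
    cabg_fraction: float = 0.1
    views_per_patient: int = 1
    n_frames: int = 76
    image_size: int = 512
    noise_sigma: float = 5.0
    base_date: str = "20240101"


@dataclass
class PhantomCase:
    """One cohort video: its spec, truth-level metadata and lazy renderer."""

    spec: PhantomSpec
    report_rows: list[ClinicalReportRow]
    is_pci_video: bool = False
    is_post_pci: bool = False
    cabg: bool = False
    _rendered: tuple[AngioVideo, PhantomTruth] | None = None

    def render(self, cache: bool = False) -> tuple[AngioVideo, PhantomTruth]:
        if self._rendered is not None:
            return self._rendered
        video, truth = generate_phantom(self.spec)
        truth.report_rows = self.report_rows
        if cache:
            self._rendered = (video, truth)
        return video, truth


def generate_cohort(
    n_patients: int, config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[PhantomCase], list[ClinicalReportRow]]:
    """Build a reproducible synthetic cohort.

    Each patient contributes one or more diagnostic videos of one artery
    side; PCI patients additionally contribute a later instrument-laden video
    inside a reported procedure interval.  Reported severities equal the true
    programmed severities plus truncated-Gaussian observer noise.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    all_rows: list[ClinicalReportRow] = []

    for p in range(n_patients):
        pid = f"P{p:04d}"
        side = "RCA" if rng.random() < 0.5 else "LCA"
        age = float(rng.uniform(40, 90))
        is_pci = rng.random() < config.pci_fraction
        is_cabg = rng.random() < config.cabg_fraction
        layout = _SEGMENT_FRACTIONS[side]
        # one mid-course stenosis on a random segment, or a healthy exam
        stenoses: list[StenosisSpec] = []
        if rng.random() >= config.healthy_fraction:
            code = layout[int(rng.integers(1, len(layout)))][0]
            sev = float(rng.uniform(*config.severity_range))
            stenoses.append(StenosisSpec(code, float(rng.uniform(0.35, 0.65)), sev))

        t0 = datetime(2024, 1, 1, 9, 0, 0) + timedelta(minutes=int(rng.integers(0, 120)))
        pci_intervals: list[PciInterval] = []
        if is_pci:
            pci_start = t0 + timedelta(minutes=40)
            pci_intervals = [PciInterval(side, pci_start, pci_start + timedelta(minutes=20))]

        base_spec = PhantomSpec(
            image_size=config.image_size,
            n_frames=config.n_frames,
            artery_side=side,
            stenoses=stenoses,
            noise_sigma=config.noise_sigma,
            patient_id=pid,
            patient_age=age,
            study_date=config.base_date,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sten_truth_tmp = [
            StenosisTruth(s.segment_id, s.severity_pct, (0.0, 0.0),
                          BoundingBox(0, 0, 0, 1, 1, seg.STENOSIS_CLASS))
            for s in stenoses
        ]
        rows = _report_rows(
            base_spec, sten_truth_tmp, rng,
            observer_noise_sd=config.observer_noise_sd,
            pci_intervals=pci_intervals, cabg=is_cabg,
        )
        all_rows.extend(rows)

        for v in range(config.views_per_patient):
            spec_v = replace(
                base_spec,
                dicom_id=f"{pid}.V{v}",
                acquisition_time=t0 + timedelta(minutes=2 * v),
                seed=base_spec.seed if v == 0 else int(rng.integers(0, 2**31 - 1)),
            )
            cases.append(PhantomCase(spec=spec_v, report_rows=rows, cabg=is_cabg))

        if is_pci:
            # intra-procedure video: instruments visible in most frames
            n_inst = int(0.8 * config.n_frames)
            spec_p = replace(
                base_spec,
                dicom_id=f"{pid}.PCI",
                acquisition_time=pci_intervals[0].start + timedelta(minutes=5),
                instrument_frames=[(3, 3 + n_inst)],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases.append(
                PhantomCase(spec=spec_p, report_rows=rows, is_pci_video=True, cabg=is_cabg)
            )
            # post-procedure check video: no instruments, outside the reported
            # interval, removed only by the "subsequent videos" propagation
            spec_post = replace(
                base_spec,
                dicom_id=f"{pid}.POST",
                acquisition_time=pci_intervals[0].end + timedelta(minutes=10),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases.append(
                PhantomCase(spec=spec_post, report_rows=rows, is_post_pci=True, cabg=is_cabg)
            )
    return cases, all_rows


# ------------------------------------------------------------------ truth-backed models

@dataclass
class ModelBundle:
    """Reference implementations of the four neural-stage contracts.

    Each answers from phantom ground truth, with configurable corruption so
    degradation behaviour can be studied: ``label_noise`` flips segmentation
    pixel labels, ``box_jitter_px`` perturbs detected boxes, ``severity_sd``
    adds noise to the truth severity, and ``dropout`` makes the detector miss
    instrument boxes.
    """

    classifier: object
    detector: object
    segmenters: list
    severity_model: object


def truth_backed_models(
    truth: PhantomTruth,
    label_noise: float = 0.0,
    box_jitter_px: int = 0,
    instrument_dropout: float = 0.0,
    severity_sd: float = 0.0,
    n_segmenters: int = 1,
    seed: int = 0,
) -> ModelBundle:
    rng = np.random.default_rng(seed)

    def classifier(frame: np.ndarray, frame_index: int) -> str:
        return truth.artery_side

    def detector(video: AngioVideo) -> list[BoundingBox]:
        out = []
        h, w = video.frame_shape
        for b in truth.all_boxes():
            if b.class_label in seg.INSTRUMENT_CLASSES and rng.random() < instrument_dropout:
                continue
            if box_jitter_px > 0:
                jx, jy = rng.integers(-box_jitter_px, box_jitter_px + 1, size=2)
                b = b.translated(int(jx), int(jy))
            x0 = int(np.clip(b.x0, 0, w - 1))
            y0 = int(np.clip(b.y0, 0, h - 1))
            x1 = int(np.clip(b.x1, x0 + 1, w))
            y1 = int(np.clip(b.y1, y0 + 1, h))
            out.append(BoundingBox(b.frame_index, x0, y0, x1, y1, b.class_label, b.score))
        return out

    def make_segmenter(member_seed: int):
        member_rng = np.random.default_rng(member_seed)

        def segmenter(frame: np.ndarray, frame_index: int | None = None,
                      window: tuple[int, int, int, int] | None = None) -> np.ndarray:
            if frame_index is None:
                raise ValueError("truth-backed segmenter needs a frame index")
            labels = truth.mask(frame_index)
            if window is not None:
                y0, y1, x0, x1 = window
                labels = _padded_crop_int(labels, y0, y1, x0, x1)
            labels = labels.copy()
            if label_noise > 0:
                flip = member_rng.random(labels.shape) < label_noise
                labels[flip] = member_rng.integers(0, seg.N_CLASSES, size=int(flip.sum()))
            onehot = np.zeros((seg.N_CLASSES,) + labels.shape, dtype=float)
            for c in range(seg.N_CLASSES):
                onehot[c] = labels == c
            return onehot

        return segmenter

    segmenters = [make_segmenter(int(rng.integers(0, 2**31 - 1))) for _ in range(n_segmenters)]

    def severity_model(inp) -> float:
        true_pct = truth.severity_of(inp.clip.segment_id) if inp.clip.segment_id else 0.0
        noisy = true_pct + (rng.normal(0.0, severity_sd) if severity_sd > 0 else 0.0)
        return float(np.clip(noisy / 100.0, 0.0, 1.0))

    return ModelBundle(
        classifier=classifier,
        detector=detector,
        segmenters=segmenters,
        severity_model=severity_model,
    )


def _padded_crop_int(img: np.ndarray, y0: int, y1: int, x0: int, x1: int) -> np.ndarray:
    h, w = img.shape
    core = img[max(y0, 0):min(y1, h), max(x0, 0):min(x1, w)]
    pads = ((max(0, -y0), max(0, y1 - h)), (max(0, -x0), max(0, x1 - w)))
    if any(p for pair in pads for p in pair):
        core = np.pad(core, pads, mode="edge")
    return core
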
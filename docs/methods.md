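# Methods

This note documents the models, conventions and numerical choices behind
`coroquant`, and what validation on the phantom does and does not establish.

## Coordinate and data conventions

Bounding boxes are 0-based half-open pixel intervals `[x0, x1) × [y0, y1)`;
the geometric centre of a box is `((x0+x1−1)/2, (y0+y1−1)/2)`, i.e. the
centroid of the covered pixel centres. Pixel spacing is treated as isotropic;
if a DICOM carries two components differing by more than 1%, their mean is
used with a warning. Videos are 8-bit grayscale stacks; the reader never
rescales intensities. Clinical reports are one CSV row per
(patient, date, segment) with PCI intervals and the CABG flag grouped per
patient-day (the schema is this package's convention — clinical reports in
the wild are free text).

## Registration

Every stenosis box is standardized to a square whose integer pixel side
minimizes `|side · spacing − 17.5 mm|`, centred on the original box (shifted
only to stay inside the frame). Tracking is translation-only by design: a
correlation template tracker is initialized on the reference-frame content of
the box and run outward in both temporal directions, each step searching a
window (default ±25 px) around the previous offset for the peak of the
zero-normalized cross-correlation. ZNCC is invariant to affine intensity
changes, which makes the tracker insensitive to contrast wash-in/out; the
correlation peak serves as a confidence, and steps whose peak falls below 0.2
carry the previous offset forward with confidence 0. Any other
template-initialized translation estimator (e.g. a discriminative correlation
filter) can be substituted through the same contract.

The raw series is smoothed with a centred uniform (moving-average) filter
with edge replication, rounded to integers, and re-pinned to (0, 0) at the
reference frame. The window default is **3 frames**. This was a genuinely
open choice: a centred uniform filter attenuates a sinusoid of frequency f
sampled at fs by `sin(πfw/fs) / (w·sin(πf/fs))`, which for cardiac motion
(~1 Hz at 15 fps) is ~6% at w = 3 but ~17% at w = 5 — enough, at realistic
15–20 px amplitudes, to move the crop several pixels off target at the motion
extremes. Three frames still suppresses the single-frame tracker jumps the
filter exists for, while keeping cardiac amplitude essentially intact.
Displacements are integer pixels (crop-shift, no resampling), so clips are
resolution-exact; temporal and spatial padding replicate the nearest
edge/frame. The 24-frame clip window starts at `ref − (24−1)//2`, replicating
terminal frames when the video is short.

## Segmentation and assignment

Twelve classes: background plus 11 epicardial segments (prox/mid/dist RCA,
PDA, RCA posterolateral; left main, prox/mid/dist LAD, prox/dist LCX), each
carrying its standard SYNTAX segment number (1, 2, 3, 4, 16; 5, 6, 7, 8, 11,
13), used everywhere as the deterministic tie-break key. Ensemble members
contribute probability maps (not logits), which are averaged and
argmax-labelled; exact ties prefer vessel classes over background and then
the lowest SYNTAX index, preventing thin-vessel dropout under symmetric
disagreement. Dice, PPV and sensitivity are computed per class from confusion
counts, with truth-pixel-count weights for the weighted averages; classes
absent from both maps are excluded, and undefined ratios are reported as 0
with a warning.

Frame-level assignment takes, among in-box pixels of the video's artery
side, those at minimal Euclidean distance (tolerance 1e−9 on squared
distances) from the exact box centre; candidates are ranked by pixel count at
that distance, then by SYNTAX index. Frames with no qualifying pixel abstain
from the video-level majority vote, whose ties fall to the lowest SYNTAX
index, mirroring the frame-level ladder. Per DICOM and segment, only the
record whose reference frame is closest to the video midpoint `(T−1)/2`
survives (ties to the earlier frame).

## PCI and CABG exclusion

Method 1 flags a video when the fraction of frames containing a detected
guidewire, balloon or stent reaches the threshold (default 0.16, `≥` rule).
Method 2 flags a video acquired inside `[start − offset, end]` of a reported
procedure interval (default offset 25 min; closed on both ends — the
interval-end side was unspecified and closed was chosen); intervals are
matched to the video's artery side by default (configurable). The combined
flag is the OR. All of a patient's videos acquired at or after their earliest
flagged video are removed (labels after plaque modification are stale), and
CABG patients are removed entirely. The Youden optimizer maximizes
J = sensitivity + specificity − 1 under the `≥` rule over 100 equally spaced
thresholds on [0, 1] inclusive, breaking ties toward the smallest threshold;
derivation/hold-out splitting for threshold fitting is 80/20 with a seed.

## Severity

The learned regressor is a contract: any callable mapping a 24-frame
registered clip plus an artery one-hot and normalized age (age/100, clamped
to [0, 1]; missing age → 0.5) to a value in [0, 1]; outputs outside [0, 1]
are contract violations, not clamped. The packaged **geometric reference
predictor** is a deliberately simple, deterministic stand-in so the pipeline
produces meaningful severities with no trained weights: on the temporally
central clip frame containing the segment, the segment mask is skeletonized,
diameters are read from the Euclidean distance transform (`2·EDT − 1`, exact
for straight digital strips), spurs shorter than one vessel radius and
skeleton points within one radius of the crop border are discarded
(truncation artifacts), the width profile is ordered along the principal axis
and smoothed over 5 samples (digital tubes carry ~1 px staircase
fluctuation), and severity = `100·(1 − min width / reference width)` with the
reference the median of the top quartile of widths, clamped to [0, 100]. This
is a percent-*diameter* convention, matching clinical visual-estimate
semantics. On rendered phantoms it recovers programmed severities of
0/20/40/60/80% as roughly 1/13/40/64/82% — strictly monotone, a few points
low at mild stenoses where the notch depth nears the quantization floor.

Binarization uses the `≥` rule: raw predictions against the 0.23 operating
point, visual report percentages against 70, QCA percentages against 50.

## Evaluation

Artery-level aggregation averages predicted and reported percentages over
all videos of one (patient, day, segment); scopes are LCA, RCA and combined.
AUROC uses the Mann–Whitney rank formulation (ties ½); AUPRC is step
integration of the precision–recall curve (the average-precision form).
Confidence intervals subsample **without replacement** — the evaluation
protocol re-selects 80% of the rows rather than bootstrap-resampling them — 
1000 times, taking 2.5/97.5 percentiles; a classical with-replacement mode
is a flag. The resampling unit is the artery-level row. DeLong's test
compares paired AUROCs via placement values; since its variance theory is
specific to the AUROC, AUPRC differences use a paired bootstrap instead.
"Healthy" counts are rows with report exactly 0%.

## The phantom, and what passing means

The phantom renders a smoothly curving dark tube (X-ray chord-length
attenuation profile) on a brighter background: 512×512, 15 fps, 0.35 mm
pixels, 76 frames; base vessel diameter 4.0 mm; stenoses are Gaussian
diameter notches (default length 8 mm) reaching `1 − severity/100` of the
base diameter; rigid global motion is the sum of a cardiac (1 Hz) and a
respiratory (0.25 Hz) sinusoid (defaults 8/6 px and 3/4 px amplitude);
contrast ramps in over 8 frames and decays to 0.3 at the end; Gaussian noise
(σ = 5) and faint static distractor wires are added. Frames and masks are
rendered once and translated per frame, so truth masks are *exactly* the
frame-0 masks shifted by the truth displacement. Detector-style truth boxes
slide along the centreline every 10 px (side 40 px) — local proposals like a
detection network emits, which is what gives stenosis boxes realistic
IoU > 0.5 partners — alongside per-segment enclosing boxes and instrument
boxes in designated frame ranges.

Cohorts emulate the clinical regime: ~45% of reported segments healthy (0%),
diseased severities uniform on 20–90%, visual-report observer noise
truncated-Gaussian with σ = 10% (inter-observer variability for visual
grading is commonly quoted at 6.9–26.4%), ~30% of patients with a PCI (an
instrument-laden video inside a reported interval, plus a post-procedure
video catching the propagation rule) and ~10% with CABG. Truth-backed model
bundles answer each neural-stage contract from ground truth with configurable
corruption (label noise, box jitter, instrument dropout, severity noise).

The phantom deliberately omits foreshortening, branch overlap, vessel
overlap with the spine/diaphragm, panning, and non-rigid deformation. Tests
passing on it validate the *algorithmic* layer — registration arithmetic,
tie ladders, exclusion cascades, statistics — under known truth; they say
nothing about the performance of any learned model on clinical images, and
the geometric severity predictor is a reference implementation, not a
clinical-grade QCA tool.

## Problem sizes and determinism

Validation runs at desk scale by choice: 20 seeds for registration recovery,
1000 random instances for the assignment oracle, 50-patient cohorts for
exclusion logic, 20-patient rendered cohorts end-to-end. All randomness flows
from explicit seeds (`numpy.random.default_rng`); identical config + seed
reproduces records CSV and evaluation JSON byte-for-byte.
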
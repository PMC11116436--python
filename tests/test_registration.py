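"""Registration: box standardization, tracking, smoothing, cropping."""

import numpy as np
import pytest

from coroquant import registration as reg
from coroquant.types import AngioVideo, BoundingBox, DisplacementSeries


def _box(x0=100, y0=100, side=30, frame=0):
    return BoundingBox(frame, x0, y0, x0 + side, y0 + side, "stenosis")


class TestStandardizeBox:
    @pytest.mark.parametrize(
        "spacing,expected_side",
        [(0.35, 50), (0.5, 35), (0.37, 47)],  # 47*0.37 deviates 0.11 < 48*0.37's 0.26
    )
    def test_side_minimizes_physical_deviation(self, spacing, expected_side):
        out = reg.standardize_box(_box(), spacing, (512, 512))
        assert out.width == out.height == expected_side

    def test_centre_preserved_when_unclamped(self):
        box = _box(x0=100, y0=120, side=30)
        out = reg.standardize_box(box, 0.35, (512, 512))
        ocx, ocy = out.center
        cx, cy = box.center
        assert abs(ocx - cx) <= 0.5 and abs(ocy - cy) <= 0.5

    def test_clamped_to_frame_preserving_size(self):
        out = reg.standardize_box(_box(x0=0, y0=0, side=10), 0.35, (512, 512))
        assert out.x0 >= 0 and out.y0 >= 0 and out.width == 50

    def test_target_larger_than_frame_errors(self):
        with pytest.raises(ValueError):
            reg.standardize_box(_box(x0=5, y0=5, side=4), 0.35, (40, 40))


def _textured_video(rng, t=10, size=160):
    from scipy.ndimage import gaussian_filter

    base = gaussian_filter(rng.normal(128, 60, (size, size)), 3)
    frames = np.stack([np.clip(base, 0, 255) for _ in range(t)]).astype(np.uint8)
    return base, frames


class TestTracking:
    def test_static_video_gives_zero_offsets(self, rng):
        _, frames = _textured_video(rng)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        series = reg.track_displacements(video, _box(x0=60, y0=60, side=40), 4)
        assert np.all(series.dx == 0) and np.all(series.dy == 0)
        assert series.dx[series.reference_frame] == 0

    def test_programmed_shift_recovered_within_one_pixel(self, rng):
        base, _ = _textured_video(rng, size=220)
        t = 8
        frames = np.stack(
            [np.clip(np.roll(base, (0, 3 * k), axis=(0, 1)), 0, 255) for k in range(t)]
        ).astype(np.uint8)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        series = reg.track_displacements(video, _box(x0=90, y0=90, side=40), 0)
        truth = 3 * np.arange(t)
        assert np.all(np.abs(series.dx - truth) <= 1)
        assert np.all(np.abs(series.dy) <= 1)

    def test_lost_target_carries_offset_with_zero_confidence(self, rng):
        base, _ = _textured_video(rng)
        frames = np.stack([base] * 4 + [np.full_like(base, 127)] * 4).astype(np.uint8)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        series = reg.track_displacements(video, _box(x0=60, y0=60, side=40), 0)
        assert np.all(series.confidence[4:] == 0.0)
        assert np.all(series.dx[4:] == series.dx[3])

    def test_degenerate_box_errors(self, rng):
        _, frames = _textured_video(rng, t=3)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        tracker = reg.CorrelationTemplateTracker()
        with pytest.raises(ValueError):
            tracker.init(video.frames[0], BoundingBox(0, 10, 10, 11, 11))


def _series(dx, ref=0):
    n = len(dx)
    return DisplacementSeries(
        dx=np.asarray(dx), dy=np.zeros(n, dtype=int),
        reference_frame=ref, confidence=np.ones(n),
    )


class TestSmoothing:
    def test_window_one_is_identity(self):
        s = _series([0, 2, 5, 1])
        out = reg.smooth_displacements(s, 1)
        assert np.array_equal(out.dx, s.dx)

    def test_constant_series_is_fixed_point(self):
        s = _series([0, 0, 0, 0, 0])
        out = reg.smooth_displacements(s, 3)
        assert np.array_equal(out.dx, s.dx)

    def test_hand_computed_moving_average(self):
        out = reg.smooth_displacements(_series([0, 0, 3, 0, 0]), 3)
        assert out.dx.tolist() == [0, 1, 1, 1, 0]

    def test_reference_frame_repinned_to_zero(self):
        out = reg.smooth_displacements(_series([0, 0, 3, 0, 0], ref=2), 3)
        assert out.dx[2] == 0

    def test_output_bounded_by_input_range(self, rng):
        dx = rng.integers(-10, 10, 25)
        out = reg.smooth_displacements(_series(dx.tolist()), 5)
        span = dx.max() - dx.min()
        assert out.dx.max() - out.dx.min() <= span + 1  # +1 for rounding

    def test_even_window_errors(self):
        with pytest.raises(ValueError):
            reg.smooth_displacements(_series([0, 1, 2]), 4)


class TestApplyRegistration:
    def test_zero_series_equals_fixed_crop(self, rng):
        _, frames = _textured_video(rng, t=5)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        box = _box(x0=40, y0=50, side=30)
        series = _series([0] * 5)
        clip = reg.apply_registration(video, series, box)
        assert clip.frames.shape == (5, 30, 30)
        assert np.array_equal(clip.frames[2], frames[2][50:80, 40:70])
        assert clip.box_side_mm == pytest.approx(30 * 0.35)

    def test_out_of_bounds_crop_is_padded(self, rng):
        _, frames = _textured_video(rng, t=3)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        series = _series([-200, 0, 200])
        clip = reg.apply_registration(video, series, _box(x0=60, y0=60, side=30))
        assert clip.frames.shape == (3, 30, 30)

    def test_series_must_cover_all_frames(self, rng):
        _, frames = _textured_video(rng, t=5)
        video = AngioVideo(frames=frames, pixel_spacing_mm=0.35, fps=15)
        with pytest.raises(ValueError):
            reg.apply_registration(video, _series([0, 0]), _box())


class TestClipWindow:
    def test_centred_24_frame_window(self):
        idx = reg.clip_window_indices(76, 36, 24)
        assert idx[0] == 25 and idx[-1] == 48 and len(idx) == 24

    def test_short_video_replicates_ends(self):
        idx = reg.clip_window_indices(10, 5, 24)
        assert len(idx) == 24 and idx[0] == 0 and idx[-1] == 9

    def test_single_frame_window_is_reference(self):
        assert reg.clip_window_indices(76, 36, 1).tolist() == [36]
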
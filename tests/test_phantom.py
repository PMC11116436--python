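"""Phantom generator: determinism, truth consistency, rendered geometry."""

import numpy as np
import pytest

from coroquant import segments as seg
from coroquant.phantom import (
    CohortConfig,
    MotionSpec,
    PhantomSpec,
    StenosisSpec,
    _shift2d,
    generate_cohort,
    generate_phantom,
    truth_backed_models,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        spec = PhantomSpec(image_size=192, n_frames=10, stenoses=[StenosisSpec("mid-RCA", 0.5, 40)], seed=5)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        assert np.array_equal(v1.frames, v2.frames)
        assert np.array_equal(t1.base_mask, t2.base_mask)
        assert np.array_equal(t1.displacements, t2.displacements)

    def test_different_seed_differs(self):
        a, _ = generate_phantom(PhantomSpec(image_size=192, n_frames=6, seed=1))
        b, _ = generate_phantom(PhantomSpec(image_size=192, n_frames=6, seed=2))
        assert not np.array_equal(a.frames, b.frames)


class TestStaticScene:
    def test_zero_motion_zero_noise_constant_video(self, static_phantom):
        video, truth = static_phantom
        assert np.all(truth.displacements == 0)
        assert np.array_equal(video.frames[0], video.frames[-1])

    def test_vessel_darker_than_background(self, static_phantom):
        video, truth = static_phantom
        vessel = video.frames[0][truth.base_mask > 0]
        background = video.frames[0][truth.base_mask == 0]
        assert vessel.mean() < background.mean() - 30


class TestTruthConsistency:
    def test_masks_are_shifted_frame0_masks(self, small_phantom):
        _, truth = small_phantom
        m0 = truth.mask(0)
        d0 = truth.displacements[0]
        for t in (5, 17, 33):
            dt = truth.displacements[t]
            moved = _shift2d(m0, dt[0] - d0[0], dt[1] - d0[1], order0=True)
            assert np.array_equal(moved, truth.mask(t))

    def test_boxes_enclose_mask_components(self, small_phantom):
        _, truth = small_phantom
        for t in (0, 20):
            mask = truth.mask(t)
            by_class = {b.class_label: b for b in truth.boxes(t) if seg.is_segment(b.class_label)}
            # every sliding box contains some pixels of its segment class
            hits = 0
            for b in truth.boxes(t):
                if not seg.is_segment(b.class_label):
                    continue
                patch = mask[max(b.y0, 0):b.y1, max(b.x0, 0):b.x1]
                if np.any(patch == seg.class_index(b.class_label)):
                    hits += 1
            assert hits > 0.9 * len([b for b in truth.boxes(t) if seg.is_segment(b.class_label)])

    def test_stenosis_box_contains_narrowing(self, static_phantom):
        _, truth = static_phantom
        st = truth.stenoses[0]
        b = st.box
        patch = truth.base_mask[b.y0:b.y1, b.x0:b.x1]
        assert np.any(patch == seg.class_index(st.segment_id))


class TestRenderedSeverity:
    @pytest.mark.parametrize("severity", [40.0, 70.0])
    def test_mask_width_matches_programmed_severity(self, severity):
        spec = PhantomSpec(
            image_size=256, n_frames=3, noise_sigma=0.0, wash_in_frames=0,
            motion=MotionSpec(cardiac_amp=(0, 0), respiratory_amp=(0, 0)),
            stenoses=[StenosisSpec("mid-RCA", 0.5, severity)],
            seed=9,
        )
        _, truth = generate_phantom(spec)
        widths = truth.width_profile_px
        base = np.median(widths[widths > 0.9 * widths.max()])
        ratio = widths.min() / base
        expected = 1.0 - severity / 100.0
        # analytic truth profile; quantization enters only through rendering
        assert ratio == pytest.approx(expected, abs=0.02)

        # and measured from the rendered mask, within ~1 px of diameter
        from scipy.ndimage import distance_transform_edt
        from skimage.morphology import skeletonize

        mask = truth.base_mask > 0
        skel = skeletonize(mask)
        diam = 2.0 * distance_transform_edt(mask)[skel] - 1.0
        base_px = np.median(diam[diam >= np.quantile(diam, 0.75)])
        measured = 1.0 - diam.min() / base_px
        assert measured * 100 == pytest.approx(severity, abs=100 * 1.5 / base_px)


class TestCohort:
    def test_reproducible(self):
        c1, r1 = generate_cohort(6, seed=4)
        c2, r2 = generate_cohort(6, seed=4)
        assert [c.spec.dicom_id for c in c1] == [c.spec.dicom_id for c in c2]
        assert [(r.segment_id, r.stenosis_pct) for r in r1] == [
            (r.segment_id, r.stenosis_pct) for r in r2
        ]

    def test_pci_fraction_controls_interval_patients(self):
        cfg = CohortConfig(pci_fraction=0.3)
        cases, rows = generate_cohort(40, cfg, seed=1)
        pci_patients = {c.spec.patient_id for c in cases if c.is_pci_video}
        assert 4 <= len(pci_patients) <= 20  # ~12 expected
        for c in cases:
            if c.is_pci_video:
                assert c.spec.instrument_frames
                assert any(r.pci_intervals for r in c.report_rows)

    def test_observer_noise_zero_reports_equal_truth(self):
        cfg = CohortConfig(observer_noise_sd=0.0, healthy_fraction=0.0)
        cases, rows = generate_cohort(5, cfg, seed=2)
        for c in cases:
            truth_by_seg = {s.segment_id: s.severity_pct for s in c.spec.stenoses}
            for r in c.report_rows:
                assert r.stenosis_pct == pytest.approx(truth_by_seg.get(r.segment_id, 0.0))

    def test_post_pci_video_emitted_for_pci_patients(self):
        cases, _ = generate_cohort(20, CohortConfig(pci_fraction=0.5), seed=3)
        pci = {c.spec.patient_id for c in cases if c.is_pci_video}
        post = {c.spec.patient_id for c in cases if c.is_post_pci}
        assert pci == post and pci


class TestTruthBackedModels:
    def test_zero_corruption_segmenter_matches_truth(self, static_phantom):
        _, truth = static_phantom
        models = truth_backed_models(truth, seed=0)
        probs = models.segmenters[0](None, frame_index=0)
        assert np.array_equal(np.argmax(probs, axis=0), truth.mask(0))

    def test_windowed_segmenter_crops_truth(self, static_phantom):
        _, truth = static_phantom
        models = truth_backed_models(truth, seed=0)
        probs = models.segmenters[0](None, frame_index=0, window=(10, 40, 20, 50))
        assert probs.shape == (seg.N_CLASSES, 30, 30)
        assert np.array_equal(np.argmax(probs, axis=0), truth.mask(0)[10:40, 20:50])

    def test_severity_model_reads_truth(self, static_phantom):
        from coroquant.severity import SeverityInput
        from coroquant.types import RegisteredClip

        _, truth = static_phantom
        models = truth_backed_models(truth, seed=0)
        clip = RegisteredClip(
            frames=np.zeros((24, 50, 50), dtype=np.uint8), box_side_px=50,
            box_side_mm=17.5, segment_id="mid-RCA",
        )
        inp = SeverityInput(clip=clip, artery_onehot=(1.0, 0.0), age_norm=0.65)
        assert models.severity_model(inp) == pytest.approx(0.5)  # 50% programmed

    def test_instrument_dropout_removes_boxes(self, rng):
        spec = PhantomSpec(image_size=192, n_frames=10, instrument_frames=[(0, 10)], seed=6)
        video, truth = generate_phantom(spec)
        full = truth_backed_models(truth, seed=1).detector(video)
        dropped = truth_backed_models(truth, instrument_dropout=0.5, seed=1).detector(video)
        n_full = sum(b.class_label == "guidewire" for b in full)
        n_drop = sum(b.class_label == "guidewire" for b in dropped)
        assert n_drop < n_full
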
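"""PCI/CABG exclusion logic and the Youden threshold optimizer."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from coroquant import exclusion as ex
from coroquant.types import BoundingBox, ClinicalReportRow, PciInterval, StenosisRecord


def _inst_boxes(frames, label="guidewire"):
    return [BoundingBox(f, 10, 10, 30, 30, label) for f in frames]


class TestM1:
    def test_no_instruments(self):
        assert ex.compute_m1([], 75) == 0.0

    def test_every_frame(self):
        assert ex.compute_m1(_inst_boxes(range(10)), 10) == 1.0

    def test_partial_fraction(self):
        assert ex.compute_m1(_inst_boxes(range(12)), 75) == pytest.approx(12 / 75)

    def test_multiple_boxes_per_frame_count_once(self):
        boxes = _inst_boxes([3, 3, 3], "balloon") + _inst_boxes([3], "stent")
        assert ex.compute_m1(boxes, 10) == pytest.approx(0.1)

    def test_non_instrument_boxes_ignored(self):
        assert ex.compute_m1(_inst_boxes(range(5), "stenosis"), 10) == 0.0


class TestFlags:
    def test_method1_greater_or_equal_rule(self):
        assert ex.flag_method1(0.16, 0.16)
        assert not ex.flag_method1(0.0)
        assert ex.flag_method1(1.0)

    def test_method2_inside_widened_interval(self):
        iv = [PciInterval("RCA", datetime(2024, 1, 1, 10, 50), datetime(2024, 1, 1, 11, 10))]
        assert ex.flag_method2(datetime(2024, 1, 1, 10, 40), iv, "RCA", 25.0)

    def test_method2_outside_widened_interval(self):
        iv = [PciInterval("RCA", datetime(2024, 1, 1, 10, 50), datetime(2024, 1, 1, 11, 10))]
        assert not ex.flag_method2(datetime(2024, 1, 1, 10, 0), iv, "RCA", 25.0)

    def test_method2_no_intervals(self):
        assert not ex.flag_method2(datetime(2024, 1, 1, 10, 0), [], "RCA")

    def test_method2_side_matching(self):
        iv = [PciInterval("LCA", datetime(2024, 1, 1, 10, 50), datetime(2024, 1, 1, 11, 10))]
        t = datetime(2024, 1, 1, 10, 55)
        assert not ex.flag_method2(t, iv, "RCA", side_matched=True)
        assert ex.flag_method2(t, iv, "RCA", side_matched=False)

    def test_combined_flag_is_or(self):
        d = ex.PciDecision(m1=0.5, method1_flag=True, method2_flag=False,
                           m1_threshold=0.16, offset_minutes=25)
        assert d.combined_flag
        d2 = ex.PciDecision(m1=0.0, method1_flag=False, method2_flag=False,
                            m1_threshold=0.16, offset_minutes=25)
        assert not d2.combined_flag


def oracle_youden(scores, labels, grid):
    best_t, best_j = None, -np.inf
    for t in grid:
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t < best_t):
            best_t, best_j = t, j
    return best_t


class TestYouden:
    def test_separable_set_returns_smallest_grid_point_in_gap(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [False, False, True, True]
        t = ex.optimize_threshold_youden(scores, labels)
        grid = np.linspace(0, 1, 100)
        assert t == pytest.approx(grid[grid > 0.2][0])
        assert 0.2 < t <= 0.8

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ex.optimize_threshold_youden([0.1, 0.9], [True, True])

    def test_single_candidate_grid(self):
        assert ex.optimize_threshold_youden([0.1, 0.9], [False, True], [0.5]) == 0.5

    def test_matches_exhaustive_oracle(self):
        grid = np.linspace(0, 1, 100)
        for s in range(50):
            rng = np.random.default_rng(s)
            n = int(rng.integers(6, 40))
            labels = np.zeros(n, dtype=bool)
            labels[: n // 2] = True
            rng.shuffle(labels)
            scores = np.clip(rng.normal(0.6, 0.2, n) * labels + rng.normal(0.4, 0.2, n) * ~labels, 0, 1)
            assert ex.optimize_threshold_youden(scores, labels) == pytest.approx(
                oracle_youden(scores, labels, grid)
            )

    def test_grid_includes_endpoints(self):
        grid = np.linspace(0.0, 1.0, ex.YOUDEN_GRID_SIZE)
        assert grid[0] == 0.0 and grid[-1] == 1.0 and len(grid) == 100


def _rec(pid, dicom, t, flags=None):
    return StenosisRecord(
        patient_id=pid, study_date="20240101", dicom_id=dicom,
        reference_frame=5, n_frames=20, artery_side="RCA", segment_id="mid-RCA",
        acquisition_time=t, flags=flags or set(),
    )


def _decision(flag):
    return ex.PciDecision(m1=0.5 if flag else 0.0, method1_flag=flag, method2_flag=False,
                          m1_threshold=0.16, offset_minutes=25.0)


class TestApplyExclusions:
    def test_subsequent_videos_removed(self):
        t0 = datetime(2024, 1, 1, 10, 0)
        recs = [
            _rec("p1", "d1", t0),
            _rec("p1", "d2", t0 + timedelta(minutes=10)),
            _rec("p1", "d3", t0 + timedelta(minutes=20)),
        ]
        decisions = {"d1": _decision(False), "d2": _decision(True), "d3": _decision(False)}
        kept, audit = ex.apply_exclusions(recs, decisions, [])
        assert [r.dicom_id for r in kept] == ["d1"]
        assert {(a.dicom_id, a.reason) for a in audit} == {("d2", "pci"), ("d3", "post_pci")}

    def test_cabg_patient_fully_removed(self):
        recs = [_rec("p1", "d1", datetime(2024, 1, 1, 10, 0))]
        row = ClinicalReportRow("p1", "20240101", "mid-RCA", 50.0, cabg_flag=True)
        kept, audit = ex.apply_exclusions(recs, {}, [row])
        assert kept == [] and audit[0].reason == "cabg"

    def test_no_flags_unchanged(self):
        recs = [_rec("p1", "d1", datetime(2024, 1, 1, 10, 0))]
        kept, audit = ex.apply_exclusions(recs, {"d1": _decision(False)}, [])
        assert kept == recs and audit == []

    def test_idempotent(self):
        t0 = datetime(2024, 1, 1, 10, 0)
        recs = [_rec("p1", "d1", t0), _rec("p1", "d2", t0 + timedelta(minutes=5))]
        decisions = {"d1": _decision(False), "d2": _decision(True)}
        kept, _ = ex.apply_exclusions(recs, decisions, [])
        kept2, audit2 = ex.apply_exclusions(kept, decisions, [])
        assert kept2 == kept and audit2 == []
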
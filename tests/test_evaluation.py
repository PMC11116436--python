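"""Evaluation statistics: aggregation, AUROC/AUPRC, bootstrap, DeLong."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coroquant import evaluation as ev
from coroquant.types import StenosisRecord


def _rec(pid, segment, pred, report, dicom="d", date="20240101"):
    from coroquant import segments as seg

    return StenosisRecord(
        patient_id=pid, study_date=date, dicom_id=dicom, reference_frame=0,
        n_frames=20, artery_side=seg.artery_side(segment), segment_id=segment,
        predicted_pct=pred, report_pct=report,
    )


class TestAggregation:
    def test_mean_of_two_views(self):
        recs = [_rec("p", "mid-RCA", 40, 50, "d1"), _rec("p", "mid-RCA", 60, 50, "d2")]
        agg = ev.aggregate_artery_level(recs)
        assert len(agg) == 1
        assert agg.predicted_pct.iloc[0] == pytest.approx(50.0)

    def test_single_video_unchanged(self):
        agg = ev.aggregate_artery_level([_rec("p", "PDA", 33, 40)])
        assert agg.predicted_pct.iloc[0] == 33

    def test_groupby_count(self):
        recs = [
            _rec("p", "prox-RCA", 10, 10, "d1"),
            _rec("p", "mid-RCA", 20, 20, "d2"),
            _rec("p", "dist-RCA", 30, 30, "d3"),
        ]
        assert len(ev.aggregate_artery_level(recs)) == 3

    def test_permutation_invariant_and_idempotent(self, rng):
        recs = [
            _rec(f"p{i % 3}", "mid-RCA", float(rng.uniform(0, 100)), 50.0, f"d{i}")
            for i in range(8)
        ]
        a = ev.aggregate_artery_level(recs)
        perm = [recs[i] for i in rng.permutation(len(recs))]
        b = ev.aggregate_artery_level(perm)
        assert np.allclose(
            a.sort_values("patient_id").predicted_pct.to_numpy(),
            b.sort_values("patient_id").predicted_pct.to_numpy(),
        )


def oracle_auroc(preds, labels):
    """Exhaustive pairwise concordance with ties counting one half."""
    pos = [p for p, l in zip(preds, labels) if l]
    neg = [p for p, l in zip(preds, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_ranking(self):
        assert ev.auroc([0.2, 0.8], [False, True]) == 1.0

    def test_worked_four_case(self):
        assert ev.auroc([0.1, 0.4, 0.35, 0.8], [False, False, True, True]) == pytest.approx(0.75)

    def test_all_equal_predictions(self):
        assert ev.auroc([0.5] * 6, [True, False] * 3) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ev.auroc([0.1, 0.9], [True, True])

    def test_matches_concordance_oracle_small_n(self):
        for s in range(60):
            rng = np.random.default_rng(s)
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            preds = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert ev.auroc(preds, labels) == pytest.approx(oracle_auroc(preds, labels))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            labels = rng.integers(0, 2, 50).astype(bool)
            if labels.all() or not labels.any():
                continue
            preds = rng.random(50)
            assert ev.auroc(preds, labels) == pytest.approx(roc_auc_score(labels, preds))


class TestAUPRC:
    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            labels = rng.integers(0, 2, 40).astype(bool)
            if labels.all() or not labels.any():
                continue
            preds = np.round(rng.random(40), 1)
            assert ev.auprc(preds, labels) == pytest.approx(
                average_precision_score(labels, preds)
            )

    def test_perfect_predictor(self):
        assert ev.auprc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0


class TestRegressionMetrics:
    def test_identity(self):
        mae, r = ev.regression_metrics([10, 20, 40], [10, 20, 40])
        assert mae == 0.0 and r == pytest.approx(1.0)

    def test_constant_offset(self):
        mae, r = ev.regression_metrics([10, 30], [20, 40])
        assert mae == 10.0 and r == pytest.approx(1.0)

    def test_anticorrelation(self):
        _, r = ev.regression_metrics([0, 100], [100, 0])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ev.regression_metrics([5, 5, 5], [1, 2, 3])


class TestYoudenBinarization:
    def test_default_without_validation_data(self):
        assert ev.youden_binarization_threshold() == 0.23

    def test_separable_validation_set(self):
        t = ev.youden_binarization_threshold([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert 0.2 < t <= 0.8


class TestBootstrap:
    def test_constant_metric_degenerate_ci(self, rng):
        data = rng.random(20)
        lo, hi = ev.bootstrap_ci(lambda d: 1.0, data, seed=0, iterations=100)
        assert lo == hi == 1.0

    def test_same_seed_bitwise_reproducible(self, rng):
        data = rng.normal(50, 10, 40)
        a = ev.bootstrap_ci(np.mean, data, seed=5)
        b = ev.bootstrap_ci(np.mean, data, seed=5)
        assert a == b

    def test_ci_contains_full_sample_mae(self, rng):
        preds = rng.uniform(0, 100, 60)
        truths = preds + rng.normal(0, 10, 60)
        mae_fn = lambda d: float(np.mean(np.abs(d[:, 0] - d[:, 1])))
        data = np.column_stack([preds, truths])
        lo, hi = ev.bootstrap_ci(mae_fn, data, seed=1)
        assert lo <= mae_fn(data) <= hi

    def test_full_fraction_without_replacement_is_degenerate(self, rng):
        data = rng.random(20)
        point = float(np.mean(data))
        lo, hi = ev.bootstrap_ci(np.mean, data, fraction=1.0, iterations=50, seed=2)
        assert lo == pytest.approx(point) and hi == pytest.approx(point)

    def test_different_seed_different_ci(self, rng):
        data = rng.normal(0, 1, 30)
        assert ev.bootstrap_ci(np.mean, data, seed=1) != ev.bootstrap_ci(np.mean, data, seed=2)


def oracle_delong(pa, pb, labels):
    """Placement-value DeLong from explicit double loops."""
    pa, pb, labels = map(np.asarray, (pa, pb, labels))
    pos_idx = np.where(labels)[0]
    neg_idx = np.where(~labels)[0]
    m, n = len(pos_idx), len(neg_idx)

    def parts(preds):
        psi = np.zeros((m, n))
        for i, pi in enumerate(pos_idx):
            for j, nj in enumerate(neg_idx):
                if preds[pi] > preds[nj]:
                    psi[i, j] = 1.0
                elif preds[pi] == preds[nj]:
                    psi[i, j] = 0.5
        return psi.mean(axis=1), psi.mean(axis=0), psi.mean()

    v10a, v01a, auca = parts(pa)
    v10b, v01b, aucb = parts(pb)
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    z = (auca - aucb) / np.sqrt(var)
    return z, 2 * stats.norm.sf(abs(z))


class TestDeLong:
    def test_identical_predictors(self):
        preds = [0.2, 0.3, 0.7, 0.9]
        z, p = ev.delong_test(preds, preds, [False, False, True, True])
        assert z == 0.0 and p == 1.0

    def test_matches_placement_oracle(self, rng):
        labels = rng.integers(0, 2, 30).astype(bool)
        labels[:3] = True
        labels[-3:] = False
        pa = np.clip(labels + rng.normal(0, 0.6, 30), 0, 2)
        pb = rng.random(30)
        z, p = ev.delong_test(pa, pb, labels)
        zo, po = oracle_delong(pa, pb, labels)
        assert z == pytest.approx(zo) and p == pytest.approx(po)

    def test_separable_vs_random_is_significant(self, rng):
        n = 200
        labels = np.arange(n) % 2 == 0
        pa = labels.astype(float)  # perfect
        pb = rng.random(n)
        _, p = ev.delong_test(pa, pb, labels)
        assert p < 0.05


class TestPairedBootstrap:
    def test_p_value_in_range_and_insignificant_for_identical(self, rng):
        labels = rng.integers(0, 2, 40).astype(bool)
        labels[0], labels[1] = True, False
        preds = rng.random(40)
        p = ev.paired_bootstrap_test(preds, preds, labels, iterations=100, seed=0)
        assert p == 1.0


class TestEvaluateAggregates:
    def test_scopes_counts_and_ci_ordering(self, rng):
        recs = []
        for i in range(40):
            segment = ["mid-RCA", "prox-LAD"][i % 2]
            true = float(rng.uniform(0, 100)) if i % 3 else 0.0
            pred = float(np.clip(true + rng.normal(0, 10), 0, 100))
            recs.append(_rec(f"p{i}", segment, pred, true, f"d{i}"))
        agg = ev.aggregate_artery_level(recs)
        res = ev.evaluate_aggregates(agg, bootstrap_iterations=50, seed=0)
        assert set(res.scopes) == {"LCA", "RCA", "combined"}
        comb = res.scopes["combined"]
        assert comb.n_exams == 40
        assert comb.n_severe + comb.n_non_severe == comb.n_exams
        assert comb.n_healthy == sum(1 for r in recs if r.report_pct == 0)
        for m in comb.metrics.values():
            assert m.lo <= m.value <= m.hi or (m.lo == m.hi)
        assert "auroc" in comb.metrics and "mae" in comb.metrics
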
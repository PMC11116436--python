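"""Evaluation protocol: aggregation, metrics, bootstrap CIs, DeLong test.

Predicted and reported stenosis percentages are first aggregated to the
artery level — the mean over all videos of the same (patient, day, segment) —
and then scored per artery side and combined.  Classification of severe
(report >= 70%) versus non-severe stenoses is summarized by AUROC (Mann-
Whitney formulation, ties counting one half), AUPRC (step integration of the
precision-recall curve), and thresholded sensitivity / specificity / PPV /
F1; regression against the report percentage by MAE and Pearson's r.

Confidence intervals subsample 80% of the evaluation rows without
replacement, 1000 times, and take the 2.5th/97.5th percentiles.  Paired AUROC
differences are tested with DeLong's method via placement values; AUPRC
differences use a paired bootstrap (DeLong's variance theory is specific to
the AUROC).
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exclusion import optimize_threshold_youden
from .severity import DEFAULT_BINARIZATION_THRESHOLD, GT_SEVERE_THRESHOLD_PCT
from .types import StenosisRecord

BOOTSTRAP_FRACTION = 0.8
BOOTSTRAP_ITERATIONS = 1000


def aggregate_artery_level(records: Sequence[StenosisRecord]) -> pd.DataFrame:
    """Mean predicted / reported severity per (patient, day, segment).

    Videos of the same coronary segment acquired on the same day are averaged,
    pooling multiple angiographic views into one artery-level row.
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "study_date": r.study_date,
            "segment_id": r.segment_id,
            "artery_side": r.artery_side,
            "predicted_pct": r.predicted_pct,
            "report_pct": r.report_pct,
        }
        for r in records
        if r.segment_id is not None and r.predicted_pct is not None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "study_date", "segment_id", "artery_side",
                     "predicted_pct", "report_pct"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["patient_id", "study_date", "segment_id"], as_index=False)
        .agg(
            artery_side=("artery_side", "first"),
            predicted_pct=("predicted_pct", "mean"),
            report_pct=("report_pct", "mean"),
        )
    )


# ---------------------------------------------------------------- metrics

def auroc(preds: Sequence[float], labels: Sequence[bool]) -> float:
    """AUROC via the Mann-Whitney statistic; ties count one half."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(preds)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(preds: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall curve by step integration.

    Equals sum over thresholds of (recall step) * precision, scanning
    predictions from the highest score down — the average-precision
    formulation.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("AUPRC undefined: both classes must be present")
    order = np.argsort(-preds, kind="stable")
    sorted_labels = labels[order]
    sorted_preds = preds[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # evaluate only at distinct thresholds (last index of each tied block)
    distinct = np.r_[sorted_preds[1:] != sorted_preds[:-1], True]
    precision, recall = precision[distinct], recall[distinct]
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


@dataclass
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    f1: float


def threshold_metrics(
    preds: Sequence[float], labels: Sequence[bool], threshold: float
) -> ThresholdMetrics:
    """Sensitivity, specificity, PPV and F1 under the >= decision rule.

    Zero denominators yield 0 for the affected metric.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = preds >= threshold
    tp = int(np.count_nonzero(pos & labels))
    fp = int(np.count_nonzero(pos & ~labels))
    fn = int(np.count_nonzero(~pos & labels))
    tn = int(np.count_nonzero(~pos & ~labels))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return ThresholdMetrics(sens, spec, ppv, f1)


def regression_metrics(preds: Sequence[float], truths: Sequence[float]) -> tuple[float, float]:
    """(MAE, Pearson r) on the 0-100 percentage scale."""
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape or preds.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    mae = float(np.mean(np.abs(preds - truths)))
    if preds.std() == 0 or truths.std() == 0:
        raise ValueError("Pearson r undefined: zero variance")
    r = float(stats.pearsonr(preds, truths).statistic)
    return mae, r


def youden_binarization_threshold(
    preds: Sequence[float] | None = None, labels: Sequence[bool] | None = None
) -> float:
    """Operating point from Youden's J over 100 grid points on [0, 1].

    Without validation data the published operating point 0.23 is returned.
    """
    if preds is None or labels is None:
        return DEFAULT_BINARIZATION_THRESHOLD
    return optimize_threshold_youden(preds, labels)


# ---------------------------------------------------------------- bootstrap

def bootstrap_ci(
    metric: Callable[[np.ndarray], float],
    data: np.ndarray,
    fraction: float = BOOTSTRAP_FRACTION,
    iterations: int = BOOTSTRAP_ITERATIONS,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
) -> tuple[float, float]:
    """Percentile CI of a metric over repeated subsamples of the rows.

    By default each iteration draws ``fraction`` of the rows *without*
    replacement (subsampling); a classical with-replacement bootstrap is
    available via ``replace=True``.  Iterations on which the metric raises
    are skipped; more than 10% failures is an error.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < 5:
        raise ValueError("need at least 5 rows to bootstrap")
    k = max(1, int(round(fraction * n)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(iterations):
        idx = rng.choice(n, size=k, replace=replace)
        try:
            values.append(metric(data[idx]))
        except (ValueError, ZeroDivisionError):
            failures += 1
    if failures > 0.1 * iterations:
        raise ValueError(f"metric failed on {failures}/{iterations} subsamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------- DeLong

def _placements(preds: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative), plus AUC."""
    pos = preds[labels]
    neg = preds[~labels]
    # psi(x, y) = 1 if x > y, 0.5 if equal, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_test(
    preds_a: Sequence[float], preds_b: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """DeLong's test for two correlated AUROCs; returns (z, two-sided p)."""
    preds_a = np.asarray(preds_a, dtype=float)
    preds_b = np.asarray(preds_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if preds_a.shape != preds_b.shape or preds_a.shape != labels.shape:
        raise ValueError("paired predictions and labels must share one length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    v10a, v01a, auc_a = _placements(preds_a, labels)
    v10b, v01b, auc_b = _placements(preds_b, labels)
    if np.array_equal(preds_a, preds_b):
        return 0.0, 1.0
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]))  # 2x2 covariance over positives
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        raise ValueError("degenerate DeLong variance")
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def paired_bootstrap_test(
    preds_a: Sequence[float],
    preds_b: Sequence[float],
    labels: Sequence[bool],
    metric: Callable[[np.ndarray, np.ndarray], float] = lambda p, y: auprc(p, y),
    iterations: int = BOOTSTRAP_ITERATIONS,
    seed: int = 0,
) -> float:
    """Two-sided paired-bootstrap p for a metric difference (e.g. AUPRC)."""
    preds_a = np.asarray(preds_a, dtype=float)
    preds_b = np.asarray(preds_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    n = labels.size
    deltas = []
    for _ in range(iterations):
        idx = rng.choice(n, size=n, replace=True)
        try:
            deltas.append(metric(preds_a[idx], labels[idx]) - metric(preds_b[idx], labels[idx]))
        except ValueError:
            continue
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise ValueError("metric failed on every resample")
    p_one = min(np.mean(deltas <= 0), np.mean(deltas >= 0))
    return float(min(1.0, 2.0 * p_one))


# ---------------------------------------------------------------- results

@dataclass
class MetricWithCI:
    value: float
    lo: float
    hi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return self.value, self.lo, self.hi


@dataclass
class ScopeResult:
    scope: str
    n_exams: int
    n_severe: int
    n_non_severe: int
    n_healthy: int
    threshold: float
    metrics: dict[str, MetricWithCI] = field(default_factory=dict)


@dataclass
class EvalResult:
    scopes: dict[str, ScopeResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            name: {
                "counts": {
                    "exams": s.n_exams,
                    "severe": s.n_severe,
                    "non_severe": s.n_non_severe,
                    "healthy": s.n_healthy,
                },
                "threshold": s.threshold,
                "metrics": {k: m.as_tuple() for k, m in s.metrics.items()},
            }
            for name, s in self.scopes.items()
        }

    def format_table(self) -> str:
        lines = []
        for name, s in self.scopes.items():
            lines.append(f"== {name} ==")
            lines.append(
                f"exams {s.n_exams}  severe {s.n_severe}  "
                f"non-severe {s.n_non_severe}  healthy {s.n_healthy}"
            )
            for k, m in s.metrics.items():
                lines.append(f"  {k:12s} {m.value:8.4f}  ({m.lo:.4f}-{m.hi:.4f})")
        return "\n".join(lines)


def evaluate_aggregates(
    aggregates: pd.DataFrame,
    binarization_threshold: float = DEFAULT_BINARIZATION_THRESHOLD,
    severe_threshold_pct: float = GT_SEVERE_THRESHOLD_PCT,
    bootstrap_iterations: int = BOOTSTRAP_ITERATIONS,
    bootstrap_fraction: float = BOOTSTRAP_FRACTION,
    seed: int = 0,
) -> EvalResult:
    """Full artery-level evaluation per scope (LCA, RCA, combined).

    Labels are report_pct >= ``severe_threshold_pct`` (70 for visual reports,
    50 for QCA); predictions are compared on the raw [0, 1] scale against
    ``binarization_threshold`` for the thresholded metrics.  Every metric
    carries a subsampled-percentile 95% CI.
    """
    result = EvalResult()
    for scope in ("LCA", "RCA", "combined"):
        df = aggregates if scope == "combined" else aggregates[aggregates.artery_side == scope]
        df = df.dropna(subset=["predicted_pct", "report_pct"])
        if len(df) == 0:
            continue
        preds_raw = df.predicted_pct.to_numpy() / 100.0
        reports = df.report_pct.to_numpy()
        labels = reports >= severe_threshold_pct
        sr = ScopeResult(
            scope=scope,
            n_exams=len(df),
            n_severe=int(labels.sum()),
            n_non_severe=int((~labels).sum()),
            n_healthy=int((reports == 0).sum()),
            threshold=binarization_threshold,
        )
        data = np.column_stack([preds_raw, reports])
        rng = np.random.default_rng(seed)

        def add(name: str, fn: Callable[[np.ndarray], float]) -> None:
            try:
                value = fn(data)
            except ValueError:
                return
            try:
                lo, hi = bootstrap_ci(
                    fn, data, fraction=bootstrap_fraction,
                    iterations=bootstrap_iterations, seed=rng,
                )
            except ValueError:
                lo = hi = value
            sr.metrics[name] = MetricWithCI(value, lo, hi)

        thr = binarization_threshold
        sev = severe_threshold_pct
        add("auroc", lambda d: auroc(d[:, 0], d[:, 1] >= sev))
        add("auprc", lambda d: auprc(d[:, 0], d[:, 1] >= sev))
        add("sensitivity", lambda d: threshold_metrics(d[:, 0], d[:, 1] >= sev, thr).sensitivity)
        add("specificity", lambda d: threshold_metrics(d[:, 0], d[:, 1] >= sev, thr).specificity)
        add("ppv", lambda d: threshold_metrics(d[:, 0], d[:, 1] >= sev, thr).ppv)
        add("f1", lambda d: threshold_metrics(d[:, 0], d[:, 1] >= sev, thr).f1)
        add("mae", lambda d: regression_metrics(d[:, 0] * 100.0, d[:, 1])[0])
        add("pearson_r", lambda d: regression_metrics(d[:, 0] * 100.0, d[:, 1])[1])
        result.scopes[scope] = sr
    return result
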
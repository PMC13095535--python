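"""Classification metrics and model evaluation reports.

The report carries the thresholded confusion counts with the derived
accuracy, F1, sensitivity (recall on cases) and specificity (recall on
controls), plus the ranking metrics: AUC as the trapezoidal area under the
ROC curve and average precision as precision-weighted recall increments
(the step-wise area under the precision-recall curve). With a single-class
truth vector the ranking metrics are undefined and flagged as such rather
than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import CohortTable, TemporalSignals
from .networks import ModelBundle
from .training import featurize, predict_baseline, predict_critic


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    f1: float
    sensitivity: float
    specificity: float
    auc: float | None
    avg_prec: float | None
    threshold: float
    roc_points: list = field(default_factory=list, repr=False)
    pr_points: list = field(default_factory=list, repr=False)
    undefined_rank_metrics: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _roc_pr_points(p: np.ndarray, y: np.ndarray):
    """ROC and PR coordinates swept over the distinct score thresholds."""
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(ps)), len(ps) - 1]
    tps = np.cumsum(ys)[distinct].astype(float)
    fps = (distinct + 1 - tps).astype(float)
    P, N = ys.sum(), len(ys) - ys.sum()
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    precision = np.r_[1.0, tps / (tps + fps)]
    recall = np.r_[0.0, tps / P]
    return fpr, tpr, precision, recall


def compute_metrics(p: np.ndarray, y: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` plus AUC / average precision."""
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != y.size:
        raise ValueError("p and y must have equal length")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")

    yhat = (p >= threshold).astype(int)
    tp = int(((yhat == 1) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    n = len(y)
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    if y.min() == y.max():   # single-class truth: ranking metrics undefined
        return MetricsReport(tp, tn, fp, fn, acc, f1, sens, spec,
                             None, None, threshold,
                             undefined_rank_metrics=True)

    fpr, tpr, precision, recall = _roc_pr_points(p, y)
    auc = float(np.trapezoid(tpr, fpr))
    avg_prec = float(np.sum(np.diff(recall) * precision[1:]))
    return MetricsReport(tp, tn, fp, fn, acc, f1, sens, spec, auc, avg_prec,
                         threshold,
                         roc_points=np.c_[fpr, tpr].tolist(),
                         pr_points=np.c_[recall, precision].tolist())


def evaluate(bundle: ModelBundle, cohort: CohortTable,
             signals: TemporalSignals,
             threshold: float = 0.5) -> dict[str, MetricsReport]:
    """Deterministic test-set report for both the Critic and the baseline.

    The Actor runs in threshold mode (select iff probability >= 0.5) and the
    Critic with dropout disabled, so repeated evaluation is identical.
    """
    X_d = featurize(bundle, cohort, signals)
    p_crit, _, _ = predict_critic(bundle, X_d, mask_mode="threshold")
    p_base = predict_baseline(bundle, X_d, signals.X_v)
    return {
        "critic": compute_metrics(p_crit, cohort.y, threshold),
        "baseline": compute_metrics(p_base, cohort.y, threshold),
    }
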
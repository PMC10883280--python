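"""Benchmark statistics: ROC/PR curves, optimal cutoffs, fragmentation summary.

Positive and random reference predictions are compared per metric; lower-is-
better metrics (iPAE) are handled by orientation.  The "optimal" cutoff
maximizes Youden's J = TPR - FPR (ties resolved toward the more stringent
threshold).  The fragmentation summary aggregates per-model confidence calls
to per-PPI sensitivity (positive pairs with a confident *and* accurate model,
motif RMSD <= 5 A) and false-positive rate (random pairs with any confident
model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_curve, auc

logger = logging.getLogger("fragscore")

Orientation = Literal["higher_is_better", "lower_is_better"]


@dataclass
class ScoredSet:
    """Metric values with positive/random labels for one benchmark metric."""

    values: np.ndarray
    labels: np.ndarray  # "positive" / "random"
    metric_name: str = ""
    orientation: Orientation = "higher_is_better"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must have the same shape")

    @property
    def y_true(self) -> np.ndarray:
        return (self.labels == "positive").astype(int)

    @property
    def oriented_values(self) -> np.ndarray:
        if self.orientation == "lower_is_better":
            return -self.values
        return self.values


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # in original metric units
    auroc: float
    metric_name: str = ""
    orientation: Orientation = "higher_is_better"


@dataclass
class CutoffReport:
    metric_name: str
    auroc: float
    auprc: float
    optimal_cutoff: float
    tpr_at_cutoff: float
    fpr_at_cutoff: float
    precision_at_cutoff: float
    orientation: Orientation = "higher_is_better"
    #: PR curve uses step-wise interpolation (average precision), no linear
    #: interpolation between operating points.
    pr_interpolation: str = "step"


def roc_auc(scored: ScoredSet) -> RocCurve:
    """ROC curve and AUROC with orientation handling; ties share a threshold."""
    y = scored.y_true
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both positive and random labels for a ROC curve")
    fpr, tpr, thr = roc_curve(y, scored.oriented_values, drop_intermediate=False)
    auroc = auc(fpr, tpr)
    if scored.orientation == "lower_is_better":
        thr = -thr
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auroc=float(auroc),
                    metric_name=scored.metric_name,
                    orientation=scored.orientation)


def auprc(scored: ScoredSet) -> float:
    """Area under the precision-recall curve (step-wise, average precision)."""
    return float(average_precision_score(scored.y_true, scored.oriented_values))


def optimal_cutoff(curve: RocCurve) -> float:
    """Threshold maximizing Youden's J = TPR - FPR.

    Ties are resolved toward the more stringent threshold (larger for
    higher-is-better metrics, smaller for lower-is-better ones).
    """
    j = curve.tpr - curve.fpr
    best = j.max()
    candidates = curve.thresholds[j == best]
    finite = candidates[np.isfinite(candidates)]
    pool = finite if len(finite) else candidates
    if curve.orientation == "lower_is_better":
        return float(pool.min())
    return float(pool.max())


def cutoff_report(scored: ScoredSet) -> CutoffReport:
    """AUROC, AUPRC and the Youden-optimal operating point for one metric."""
    curve = roc_auc(scored)
    threshold = optimal_cutoff(curve)
    y = scored.y_true
    if scored.orientation == "lower_is_better":
        called = scored.values <= threshold
    else:
        called = scored.values >= threshold
    tp = int(np.sum(called & (y == 1)))
    fp = int(np.sum(called & (y == 0)))
    tpr = tp / max(1, int(y.sum()))
    fpr = fp / max(1, int((1 - y).sum()))
    precision = tp / max(1, tp + fp)
    return CutoffReport(
        metric_name=scored.metric_name,
        auroc=curve.auroc,
        auprc=auprc(scored),
        optimal_cutoff=threshold,
        tpr_at_cutoff=tpr,
        fpr_at_cutoff=fpr,
        precision_at_cutoff=precision,
        orientation=scored.orientation,
    )


@dataclass
class FragmentationSummary:
    per_ppi: pd.DataFrame
    sensitivity: float | None
    fpr: float | None


def fragmentation_summary(per_model_metrics: pd.DataFrame,
                          group_column: str = "ppi_id",
                          label_column: str = "label",
                          confident_column: str = "confident",
                          rmsd_column: str = "motif_rmsd",
                          accuracy_rmsd: float = 5.0) -> FragmentationSummary:
    """Aggregate per-model confidence calls to per-PPI summary statistics.

    Each row is one model with its PPI id, dataset label ("positive" /
    "random") and confident flag; an optional motif-RMSD column enables the
    accuracy condition.  Sensitivity = fraction of positive PPIs with at
    least one confident and accurate model (motif RMSD <= 5 A; without RMSD
    data, any confident model counts).  FPR = fraction of random PPIs with at
    least one confident model.  Empty groups are excluded with a warning.
    """
    df = per_model_metrics
    required = {group_column, label_column, confident_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("empty metrics table; nothing to summarize")
        return FragmentationSummary(per_ppi=pd.DataFrame(), sensitivity=None,
                                    fpr=None)
    has_rmsd = rmsd_column in df.columns

    rows = []
    for (ppi, label), group in df.groupby([group_column, label_column],
                                          sort=True):
        confident = group[confident_column].astype(bool)
        any_conf = bool(confident.any())
        if has_rmsd:
            accurate = confident & (group[rmsd_column] <= accuracy_rmsd)
            any_conf_acc = bool(accurate.any())
        else:
            any_conf_acc = any_conf
        rows.append({group_column: ppi, label_column: label,
                     "n_models": len(group),
                     "any_confident": any_conf,
                     "any_confident_accurate": any_conf_acc})
    per_ppi = pd.DataFrame(rows)

    pos = per_ppi[per_ppi[label_column] == "positive"]
    neg = per_ppi[per_ppi[label_column] == "random"]
    sensitivity = (float(pos["any_confident_accurate"].mean())
                   if len(pos) else None)
    fpr = float(neg["any_confident"].mean()) if len(neg) else None
    return FragmentationSummary(per_ppi=per_ppi, sensitivity=sensitivity,
                                fpr=fpr)
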
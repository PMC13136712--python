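"""Imbalance-aware evaluation.

With ~97% of off-target sites inactive, AUROC is dominated by true
negatives and paints an optimistic picture; the primary classification
metric here is therefore the area under the precision-recall curve (AUPR),
estimated in the average-precision form

    AUPR = sum_i (R_i - R_{i-1}) * P_i

over the distinct score thresholds (ties grouped into a single step; no
linear interpolation). Regression is summarized by Pearson/Spearman
correlations restricted to active sites and by RMSE on the raw count scale
(back-transformed from the log scale for the KO task) or directly on
z-scores for the BE task.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from featkit.preprocess import inverse_log_transform


@dataclasses.dataclass
class PRCurve:
    """Precision-recall curve over all distinct score thresholds, ordered
    from the highest threshold down (recall nondecreasing)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float


def _check_binary(labels: np.ndarray, scores: np.ndarray) -> None:
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.sum() == 0:
        raise ValueError("no positive labels: precision-recall undefined")


def pr_curve(labels, scores) -> PRCurve:
    """Precision-recall curve and average-precision AUPR.

    Equal scores are grouped into one threshold step, so the curve (and the
    AUPR) is invariant to the ordering of tied samples.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _check_binary(labels, scores)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # last index of each tie group
    boundary = np.nonzero(np.diff(sorted_scores))[0]
    group_end = np.concatenate([boundary, [len(sorted_scores) - 1]])
    tp = np.cumsum(sorted_labels)[group_end]
    n_pred = group_end + 1.0
    n_pos = labels.sum()
    precision = tp / n_pred
    recall = tp / n_pos
    aupr = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return PRCurve(
        thresholds=sorted_scores[group_end],
        precision=precision,
        recall=recall,
        aupr=aupr,
    )


def auroc(labels, scores) -> float:
    """Rank-based AUROC (Mann-Whitney U statistic, ties at half credit)."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _check_binary(labels, scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_neg == 0:
        raise ValueError("no negative labels: AUROC undefined")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1.0].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_report(labels, scores, threshold: float = 0.5) -> dict:
    """Thresholded confusion-matrix metrics plus AUPR and rank AUROC.

    When no sample is predicted positive, precision and F1 are reported as
    0 with ``no_positive_predictions`` set.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    curve = pr_curve(labels, scores)
    pred = (scores > threshold).astype(float)
    tp = float(np.sum((pred == 1) & (labels == 1)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    tn = float(np.sum((pred == 0) & (labels == 0)))
    no_pos_pred = (tp + fp) == 0
    precision = 0.0 if no_pos_pred else tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return {
        "aupr": curve.aupr,
        "f1": f1,
        "accuracy": (tp + tn) / len(labels),
        "precision": precision,
        "recall": recall,
        "auroc": auroc(labels, scores),
        "no_positive_predictions": bool(no_pos_pred),
    }


def regression_report(
    y_true,
    y_pred_transformed,
    labels=None,
    task: str = "KO",
) -> dict:
    """Regression metrics in the conventional mean±SD reporting shape.

    KO: ``y_true`` are raw read counts, ``y_pred_transformed`` log-scale
    predictions; RMSE is computed on the raw count scale after
    back-transform and correlations on active-labeled rows only.
    BE: both vectors are z-scores and all rows are used.
    Correlations need at least 3 usable rows, else they are reported as NaN
    with ``correlation_defined`` false.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred_transformed, dtype=float)
    if task == "KO":
        y_pred_scale = inverse_log_transform(y_pred)
        if labels is None:
            raise ValueError("KO regression metrics need activity labels")
        mask = np.asarray(labels, dtype=float) == 1.0
    else:
        y_pred_scale = y_pred
        mask = np.ones(len(y_true), dtype=bool)
    rmse = float(np.sqrt(np.mean((y_true - y_pred_scale) ** 2)))
    out = {"rmse": rmse, "n_active": int(mask.sum())}
    if mask.sum() >= 3 and np.std(y_true[mask]) > 0 and np.std(y_pred_scale[mask]) > 0:
        out["pearson"] = float(stats.pearsonr(y_true[mask], y_pred_scale[mask])[0])
        out["spearman"] = float(stats.spearmanr(y_true[mask], y_pred_scale[mask])[0])
        out["correlation_defined"] = True
    else:
        out["pearson"] = math.nan
        out["spearman"] = math.nan
        out["correlation_defined"] = False
    return out


@dataclasses.dataclass
class TailErrorReport:
    """Largest-error flags and per-stratum mean signed error for BE
    regression (signed error = predicted - true; positive mean in the
    z < -2 stratum exposes regression to the mean)."""

    flagged: np.ndarray  # boolean mask over samples
    strata: pd.DataFrame  # stratum, n, mean_signed_error, mean_abs_error


_STRATA = (
    ("z < -4", -math.inf, -4.0),
    ("-4 <= z < -2", -4.0, -2.0),
    ("-2 <= z <= 2", -2.0, 2.0),
    ("z > 2", 2.0, math.inf),
)


def tail_error_analysis(
    true_z, predicted_z, worst_fraction: float = 0.10
) -> TailErrorReport:
    """Flag the ``worst_fraction`` largest absolute errors and stratify the
    signed error (predicted - true) by the true z-score."""
    true_z = np.asarray(true_z, dtype=float)
    predicted_z = np.asarray(predicted_z, dtype=float)
    err = predicted_z - true_z
    n_flag = math.ceil(worst_fraction * len(err))
    flagged = np.zeros(len(err), dtype=bool)
    if n_flag:
        flagged[np.argsort(-np.abs(err), kind="stable")[:n_flag]] = True
    rows = []
    for name, lo, hi in _STRATA:
        if name == "-2 <= z <= 2":
            mask = (true_z >= lo) & (true_z <= hi)
        elif lo == -math.inf:
            mask = true_z < hi
        elif hi == math.inf:
            mask = true_z > lo
        else:
            mask = (true_z >= lo) & (true_z < hi)
        rows.append(
            {
                "stratum": name,
                "n": int(mask.sum()),
                "mean_signed_error": float(err[mask].mean()) if mask.any() else math.nan,
                "mean_abs_error": float(np.abs(err[mask]).mean()) if mask.any() else math.nan,
            }
        )
    return TailErrorReport(flagged=flagged, strata=pd.DataFrame(rows))


def aggregate_metrics(per_fold: list[dict]) -> dict:
    """Mean +/- SD of every shared numeric metric over folds."""
    keys = [
        k
        for k in per_fold[0]
        if all(isinstance(fold.get(k), (int, float)) and not isinstance(fold.get(k), bool) for fold in per_fold)
    ]
    out = {}
    for key in keys:
        vals = np.array([fold[key] for fold in per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        sd = 0.0 if np.ptp(vals) == 0 else float(vals.std(ddof=0))
        out[key] = {"mean": float(vals.mean()), "sd": sd}
    return out


def format_mean_sd(entry: dict, digits: int = 3) -> str:
    """Render an aggregate entry in the conventional ``0.612±0.165`` style."""
    return f"{entry['mean']:.{digits}f}±{entry['sd']:.{digits}f}"
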
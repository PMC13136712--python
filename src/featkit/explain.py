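"""Model explainability: TreeSHAP attributions and accumulated local effects.

Attributions are exact TreeSHAP values computed by the tree ensemble itself
on its additive raw-margin scale (log-odds for classification), where the
local-accuracy identity — attributions plus base value equal the raw
prediction — holds exactly. Global importance is the mean absolute
attribution, the ordering used by conventional SHAP summary plots;
positional roll-ups aggregate all features sharing a ``pos{p}`` prefix.

ALE (accumulated local effects) estimates a feature's marginal effect from
*local* finite differences within narrow bins of the feature, so unlike
partial dependence it stays meaningful when features are correlated — the
relevant case here, since the mismatch-count "distance" feature is a
deterministic function of the sequence features.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np
import pandas as pd
import xgboost as xgb

from featkit.core_io import FeatureMatrix
from featkit.modeling import TrainedModel

_POS_PREFIX = re.compile(r"^(?:guide_|target_)?pos(\d+)(?:_|$)")


def _intercept_margin(booster: xgb.Booster) -> float:
    """Model intercept on the raw-margin scale (logit of base_score for
    logistic models, base_score itself otherwise)."""
    import json

    config = json.loads(booster.save_config())["learner"]
    base_score = float(config["learner_model_param"]["base_score"])
    objective = config["objective"]["name"]
    if objective.startswith("binary:logistic"):
        base_score = min(max(base_score, 1e-12), 1 - 1e-12)
        return float(np.log(base_score / (1.0 - base_score)))
    return base_score


@dataclasses.dataclass
class AttributionReport:
    """Per-sample TreeSHAP attributions with summary roll-ups."""

    feature_names: list[str]
    phi: np.ndarray  # (n_samples, n_features)
    base_value: float
    margin: np.ndarray  # raw-margin predictions, double-precision accumulated
    feature_values: np.ndarray  # (n_samples, n_features), for summary export
    ranking: list[str]  # by mean |phi|, descending
    positional_rollup: dict[int, float]  # position -> summed mean |phi|

    @property
    def mean_abs_phi(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)


def shap_attributions(
    model: TrainedModel, features: FeatureMatrix
) -> AttributionReport:
    """Exact TreeSHAP attributions on the raw-margin scale.

    The local-accuracy identity (sum of attributions + base value == raw
    prediction) is verified for every sample before returning.
    """
    if list(features.feature_names) != model.feature_names:
        raise ValueError("feature schema mismatch between model and matrix")
    booster = model.estimator.get_booster()
    n_trees = booster.num_boosted_rounds()
    # the ensemble predicts in single precision; accumulating per-tree-chunk
    # contributions in double precision keeps the additivity identity tight
    # even for large ensembles (TreeSHAP values are additive across trees).
    # A zero base margin keeps per-chunk magnitudes small; the model
    # intercept is added back once, in double precision.
    dmat = xgb.DMatrix(
        features.values, base_margin=np.zeros(features.n_samples)
    )
    intercept = _intercept_margin(booster)
    for chunk in (8, 1):  # retry per-tree if round-off is still too coarse
        phi = np.zeros((features.n_samples, features.n_features))
        base = np.zeros(features.n_samples)
        margin = np.zeros(features.n_samples)
        for start in range(0, n_trees, chunk):
            part = booster[start : min(start + chunk, n_trees)]
            contribs = part.predict(dmat, pred_contribs=True).astype(np.float64)
            phi += contribs[:, :-1]
            base += contribs[:, -1]
            margin += part.predict(dmat, output_margin=True).astype(np.float64)
        base += intercept
        margin += intercept
        total = phi.sum(axis=1) + base
        scale = np.maximum(np.abs(margin), 1.0)
        if np.all(np.abs(total - margin) / scale < 1e-6):
            break
    else:
        raise AssertionError("TreeSHAP local-accuracy identity violated")
    mean_abs = np.abs(phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    ranking = [features.feature_names[i] for i in order]
    rollup: dict[int, float] = {}
    for name, value in zip(features.feature_names, mean_abs):
        match = _POS_PREFIX.match(name)
        if match:
            pos = int(match.group(1))
            rollup[pos] = rollup.get(pos, 0.0) + float(value)
    return AttributionReport(
        feature_names=list(features.feature_names),
        phi=phi,
        base_value=float(base[0]),
        margin=margin,
        feature_values=features.values,
        ranking=ranking,
        positional_rollup=dict(sorted(rollup.items())),
    )


@dataclasses.dataclass
class ALECurve:
    """First-order accumulated local effect of one feature.

    ``grid`` has K+1 edges; ``effects`` the centered accumulated effect at
    each edge; ``n_per_bin`` the samples attributed to each of the K bins.
    The sample-weighted mean of the effects is zero.
    """

    feature: str
    grid: np.ndarray
    effects: np.ndarray
    n_per_bin: np.ndarray


def ale_curve(
    model: TrainedModel,
    features: FeatureMatrix,
    feature_name: str,
    n_bins: int = 20,
) -> ALECurve:
    """First-order ALE of ``feature_name`` on the raw-margin scale.

    Integer-valued features (such as the mismatch-count "distance") get one
    bin per observed integer value; continuous features get quantile bins
    (at most ``n_bins``). Samples in bin k contribute the local difference
    f(x with x_j = z_k) - f(x with x_j = z_{k-1}); differences are
    accumulated over bins and centered to zero weighted mean.
    """
    if feature_name not in features.feature_names:
        raise ValueError(f"unknown feature {feature_name!r}")
    j = features.feature_names.index(feature_name)
    col = features.values[:, j]
    uniq = np.unique(col)
    if len(uniq) < 2:
        raise ValueError(f"feature {feature_name!r} is constant; ALE undefined")
    integer_valued = np.allclose(uniq, np.round(uniq)) and len(uniq) <= max(
        n_bins, 50
    )
    if integer_valued:
        grid = uniq.astype(float)
    else:
        qs = np.linspace(0.0, 1.0, n_bins + 1)
        grid = np.unique(np.quantile(col, qs))
    # assign each sample to a bin: (grid[k-1], grid[k]] with the minimum in bin 1
    bin_of = np.clip(np.searchsorted(grid, col, side="left"), 1, len(grid) - 1)
    n_bins_actual = len(grid) - 1
    local_means = np.zeros(n_bins_actual)
    n_per_bin = np.zeros(n_bins_actual, dtype=int)
    for k in range(1, len(grid)):
        mask = bin_of == k
        n_per_bin[k - 1] = int(mask.sum())
        if not mask.any():
            continue
        x_hi = features.values[mask].copy()
        x_lo = features.values[mask].copy()
        x_hi[:, j] = grid[k]
        x_lo[:, j] = grid[k - 1]
        diffs = model.raw_margin(x_hi) - model.raw_margin(x_lo)
        local_means[k - 1] = float(diffs.mean())
    accumulated = np.concatenate([[0.0], np.cumsum(local_means)])
    # center so the sample-weighted mean effect (each sample evaluated at
    # the right edge of its bin) is zero
    center = float(np.mean(accumulated[bin_of]))
    return ALECurve(
        feature=feature_name,
        grid=grid,
        effects=accumulated - center,
        n_per_bin=n_per_bin,
    )


def summary_export(report: AttributionReport, top_k: int = 20) -> pd.DataFrame:
    """Long-format beeswarm data (sample, feature, feature_value, phi) for
    the ``top_k`` features by mean |phi|, in ranking order."""
    k = min(top_k, len(report.feature_names))
    frames = []
    for name in report.ranking[:k]:
        j = report.feature_names.index(name)
        frames.append(
            pd.DataFrame(
                {
                    "sample": np.arange(report.phi.shape[0]),
                    "feature": name,
                    "feature_value": report.feature_values[:, j],
                    "phi": report.phi[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
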
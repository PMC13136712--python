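"""Guide-grouped cross-validation and weighted gradient-boosted-tree models.

All records of a guide share sequence context, so random sample-level splits
leak information; the KO evaluation therefore groups folds by guide
(leave-one-group-out, or k mutually exclusive guide sets). The BE screen has
one record per guide and uses standard k-fold CV. Models are XGBoost
ensembles (logistic loss for classification, squared error on the
transformed target for regression) trained with per-sample class weights.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import xgboost as xgb

from featkit.core_io import DatasetTable, FeatureMatrix, PairedSiteRecord
from featkit.encoders import EncoderSpec, encode_dataset
from featkit.metrics import (
    aggregate_metrics,
    classification_report,
    regression_report,
)
from featkit.preprocess import (
    binary_labels,
    compute_class_weights,
    label_be_by_zscore,
    label_ko_by_count,
    log_transform,
    sample_weights,
)

Scheme = Literal["leave_one_group_out", "leave_k_groups_out", "kfold"]


@dataclasses.dataclass
class FoldPlan:
    """Cross-validation fold assignment.

    ``folds`` holds per-fold (train, test) sample-index arrays;
    ``test_groups`` the guide ids held out per fold (grouped schemes).
    Test sets are mutually exclusive and jointly exhaustive.
    """

    scheme: Scheme
    folds: list[tuple[np.ndarray, np.ndarray]]
    test_groups: list[list[str]] | None = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_folds(
    groups: list[str],
    scheme: Scheme = "leave_one_group_out",
    k: int | None = None,
    seed: int = 0,
) -> FoldPlan:
    """Build a :class:`FoldPlan` over per-record group labels.

    Grouped schemes permute the distinct groups with the seed and chunk
    them contiguously into folds; ``leave_one_group_out`` is the k =
    n_groups special case. ``kfold`` ignores groups and splits samples.
    """
    groups = list(groups)
    n = len(groups)
    rng = np.random.default_rng(seed)
    if scheme == "kfold":
        if k is None or k < 2:
            raise ValueError("kfold requires k >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds {n} samples")
        perm = rng.permutation(n)
        chunks = np.array_split(perm, k)
        folds = [
            (np.sort(np.setdiff1d(perm, test)), np.sort(test)) for test in chunks
        ]
        return FoldPlan(scheme=scheme, folds=folds)

    unique = list(dict.fromkeys(groups))
    if len(unique) < 2:
        raise ValueError("grouped CV requires at least 2 groups")
    if scheme == "leave_one_group_out":
        k = len(unique)
    elif scheme == "leave_k_groups_out":
        if k is None or k < 2:
            raise ValueError("leave_k_groups_out requires a fold count k >= 2")
        if k > len(unique):
            raise ValueError(f"k={k} folds exceed {len(unique)} groups")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    order = [unique[i] for i in rng.permutation(len(unique))]
    group_chunks = [list(c) for c in np.array_split(np.array(order, dtype=object), k)]
    group_arr = np.array(groups, dtype=object)
    folds = []
    for chunk in group_chunks:
        test_mask = np.isin(group_arr, chunk)
        folds.append((np.nonzero(~test_mask)[0], np.nonzero(test_mask)[0]))
    return FoldPlan(scheme=scheme, folds=folds, test_groups=group_chunks)


def assert_no_group_leakage(plan: FoldPlan, groups: list[str]) -> None:
    """Raise if any guide contributes to both train and test of a fold."""
    group_arr = np.array(groups, dtype=object)
    for i, (train_idx, test_idx) in enumerate(plan.folds):
        if np.intersect1d(train_idx, test_idx).size:
            raise AssertionError(f"fold {i}: overlapping sample indices")
        if plan.scheme != "kfold":
            shared = set(group_arr[train_idx]) & set(group_arr[test_idx])
            if shared:
                raise AssertionError(f"fold {i}: guide leakage {sorted(shared)[:5]}")


@dataclasses.dataclass
class ModelSpec:
    """Hyperparameters of one boosted-tree model."""

    task: Literal["classification", "regression"] = "classification"
    learning_rate: float = 0.1
    max_depth: int = 6
    n_trees: int = 300
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0
    subsample: float = 1.0
    colsample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclasses.dataclass
class TrainedModel:
    """A fitted ensemble plus the schema it was trained with."""

    spec: ModelSpec
    estimator: xgb.XGBModel
    feature_names: list[str]
    metadata: dict = dataclasses.field(default_factory=dict)

    def raw_margin(self, values: np.ndarray) -> np.ndarray:
        """Predictions on the additive (raw-margin) scale: log-odds for
        classification, the plain output for regression."""
        dmat = xgb.DMatrix(np.asarray(values, dtype=float))
        return self.estimator.get_booster().predict(dmat, output_margin=True)


def _make_estimator(spec: ModelSpec) -> xgb.XGBModel:
    common = dict(
        n_estimators=spec.n_trees,
        learning_rate=spec.learning_rate,
        max_depth=spec.max_depth,
        reg_lambda=spec.reg_lambda,
        reg_alpha=spec.reg_alpha,
        subsample=spec.subsample,
        colsample_bytree=spec.colsample,
        random_state=spec.seed,
        n_jobs=1,
        tree_method="hist",
    )
    if spec.task == "classification":
        return xgb.XGBClassifier(objective="binary:logistic", **common)
    return xgb.XGBRegressor(objective="reg:squarederror", **common)


def train(
    features: FeatureMatrix,
    targets,
    weights=None,
    spec: ModelSpec | None = None,
) -> TrainedModel:
    """Fit a boosted-tree model on a feature matrix.

    Classification targets must be binary with both classes present;
    regression targets are on the transformed scale (log counts or
    z-scores). Deterministic given ``spec.seed`` (single-threaded).
    """
    spec = spec or ModelSpec()
    y = np.asarray(targets, dtype=float)
    if features.n_samples != len(y):
        raise ValueError("features and targets disagree on sample count")
    if not np.all(np.isfinite(features.values)):
        raise ValueError("features contain NaN or infinite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets contain NaN or infinite values")
    if spec.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification target has a single class")
    est = _make_estimator(spec)
    est.fit(features.values, y, sample_weight=weights)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=list(features.feature_names),
        metadata={"encoding_id": features.encoding_id, "weighted": weights is not None},
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Scores for ``features``: active-class probability (classification)
    or transformed-scale prediction (regression).

    The feature names must match training exactly, in order — columns are
    never silently reordered.
    """
    if list(features.feature_names) != model.feature_names:
        raise ValueError(
            "feature schema mismatch: expected "
            f"{model.feature_names[:3]}...({len(model.feature_names)}), got "
            f"{list(features.feature_names)[:3]}...({features.n_features})"
        )
    if model.spec.task == "classification":
        return model.estimator.predict_proba(features.values)[:, 1]
    return model.estimator.predict(features.values)


DEFAULT_SEARCH_SPACE = {
    "learning_rate": ("loguniform", 0.01, 0.3),
    "max_depth": ("int", 3, 10),
    "n_trees": ("int", 100, 1000),
    "reg_lambda": ("loguniform", 1e-3, 10.0),
    "reg_alpha": ("loguniform", 1e-3, 10.0),
    "subsample": ("uniform", 0.6, 1.0),
    "colsample": ("uniform", 0.6, 1.0),
}


def _sample_spec(rng: np.random.Generator, space: dict, task: str, seed: int) -> ModelSpec:
    kwargs = {}
    for name, rule in space.items():
        if isinstance(rule, (list, tuple)) and rule and rule[0] == "loguniform":
            kwargs[name] = float(np.exp(rng.uniform(np.log(rule[1]), np.log(rule[2]))))
        elif isinstance(rule, (list, tuple)) and rule and rule[0] == "uniform":
            kwargs[name] = float(rng.uniform(rule[1], rule[2]))
        elif isinstance(rule, (list, tuple)) and rule and rule[0] == "int":
            kwargs[name] = int(rng.integers(rule[1], rule[2] + 1))
        else:  # explicit list of choices
            kwargs[name] = rule[int(rng.integers(len(rule)))]
    return ModelSpec(task=task, seed=seed, **kwargs)


def _cv_score(features, y, weights, plan, spec) -> float:
    scores = []
    for train_idx, test_idx in plan.folds:
        sub_train = FeatureMatrix(
            features.encoding_id,
            list(features.feature_names),
            features.values[train_idx],
            features.has_distance,
        )
        sub_test = FeatureMatrix(
            features.encoding_id,
            list(features.feature_names),
            features.values[test_idx],
            features.has_distance,
        )
        w = None if weights is None else np.asarray(weights)[train_idx]
        model = train(sub_train, y[train_idx], w, spec)
        pred = predict(model, sub_test)
        if spec.task == "classification":
            from featkit.metrics import pr_curve

            scores.append(pr_curve(y[test_idx], pred).aupr)
        else:
            from scipy import stats as _st

            scores.append(float(_st.pearsonr(y[test_idx], pred)[0]))
    return float(np.mean(scores))


def random_search(
    features: FeatureMatrix,
    targets,
    weights,
    folds: FoldPlan,
    space: dict | None = None,
    n_iter: int = 50,
    seed: int = 0,
    task: str = "classification",
) -> tuple[ModelSpec, pd.DataFrame]:
    """Randomized hyperparameter search over ``space``.

    Each candidate is scored by its mean cross-validated metric on
    ``folds`` (AUPR for classification, Pearson r for regression); the best
    candidate is returned with the full score table. Reproducible given
    ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    y = np.asarray(targets, dtype=float)
    rows, specs, errors = [], [], []
    for it in range(n_iter):
        spec = _sample_spec(rng, space, task, seed)
        try:
            score = _cv_score(features, y, weights, folds, spec)
        except Exception as exc:  # aggregate and keep searching
            errors.append(f"candidate {it}: {exc}")
            continue
        specs.append(spec)
        rows.append({"candidate": it, "cv_score": score, **dataclasses.asdict(spec)})
    if not rows:
        raise RuntimeError(
            "all search candidates failed:\n" + "\n".join(errors)
        )
    table = pd.DataFrame(rows)
    best = specs[int(table["cv_score"].idxmax())]
    return best, table


@dataclasses.dataclass
class ExperimentResult:
    """Per-fold held-out predictions, metrics and fitted models."""

    task: str
    encoding: EncoderSpec
    predictions: pd.DataFrame  # index, guide_id, fold, y_true, label, score
    per_fold: list[dict]
    aggregate: dict
    fold_plan: FoldPlan
    models: list[TrainedModel]


def run_experiment(
    table: DatasetTable,
    encoding: EncoderSpec,
    task: str,
    folds: FoldPlan,
    spec: ModelSpec | None = None,
    ko_threshold: float = 100.0,
    be_cutoff: float = -2.0,
) -> ExperimentResult:
    """Encode -> weight -> train -> predict across a fold plan.

    Unlabeled tables are labeled with the default rules first. Class
    weights are recomputed on each training fold. Every record is predicted
    exactly once, by the fold that holds it out.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    if any(lab is None for lab in table.labels):
        table = (
            label_ko_by_count(table, ko_threshold)
            if table.task == "KO"
            else label_be_by_zscore(table, be_cutoff)
        )
    spec = spec or ModelSpec(task=task)
    if spec.task != task:
        spec = dataclasses.replace(spec, task=task)
    features = encode_dataset(table, encoding)
    y_bin = binary_labels(table)
    if table.task == "KO":
        raw = np.array([r.read_count for r in table.records])
        y_reg = log_transform(raw)
    else:
        raw = np.array([r.zscore for r in table.records])
        y_reg = raw
    y = y_bin if task == "classification" else y_reg
    groups = table.guide_ids
    assert_no_group_leakage(folds, groups)

    per_fold, models, pred_frames = [], [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds.folds):
        train_table = table.replace_records([table.records[i] for i in train_idx])
        scheme = compute_class_weights(train_table)
        weights = sample_weights(train_table, scheme)
        sub_train = FeatureMatrix(
            features.encoding_id,
            list(features.feature_names),
            features.values[train_idx],
            features.has_distance,
        )
        sub_test = FeatureMatrix(
            features.encoding_id,
            list(features.feature_names),
            features.values[test_idx],
            features.has_distance,
        )
        model = train(sub_train, y[train_idx], weights, spec)
        scores = predict(model, sub_test)
        models.append(model)
        pred_frames.append(
            pd.DataFrame(
                {
                    "index": test_idx,
                    "guide_id": [groups[i] for i in test_idx],
                    "fold": fold_id,
                    "y_true": raw[test_idx],
                    "label": y_bin[test_idx],
                    "score": scores,
                }
            )
        )
        if task == "classification":
            per_fold.append(classification_report(y_bin[test_idx], scores))
        else:
            per_fold.append(
                regression_report(
                    raw[test_idx],
                    scores,
                    labels=y_bin[test_idx],
                    task=table.task,
                )
            )
    predictions = pd.concat(pred_frames, ignore_index=True)
    return ExperimentResult(
        task=task,
        encoding=encoding,
        predictions=predictions,
        per_fold=per_fold,
        aggregate=aggregate_metrics(per_fold),
        fold_plan=folds,
        models=models,
    )


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist the ensemble (native JSON model file) plus a sidecar with
    the schema, spec and metadata."""
    path = Path(path)
    model.estimator.get_booster().save_model(str(path))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "spec": dataclasses.asdict(model.spec),
                "feature_names": model.feature_names,
                "metadata": model.metadata,
            },
            indent=2,
        )
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    spec = ModelSpec(**meta["spec"])
    est = _make_estimator(spec)
    est.load_model(str(path))  # sklearn wrapper restores its own attributes
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_names=meta["feature_names"],
        metadata=meta.get("metadata", {}),
    )
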
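"""Labeling, target transformation and class weighting.

Off-target datasets are extremely imbalanced (roughly 97% inactive sites),
so two standard corrections are applied before training: read counts are
log-transformed for regression, and classification samples are weighted so
the active and inactive classes carry equal total mass:

    w_active   = n_inactive / (n_active + n_inactive)
    w_inactive = n_active   / (n_active + n_inactive)

Labeling rules are strict inequalities: a KO site is active when its read
count exceeds the threshold (default 100); a BE guide is active when its
z-score lies below the cutoff (default -2.0).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from featkit.core_io import ACTIVE, INACTIVE, DatasetTable

DEFAULT_KO_THRESHOLD = 100.0
DEFAULT_BE_CUTOFF = -2.0


@dataclasses.dataclass(frozen=True)
class WeightScheme:
    """Per-class sample weights equalizing total class mass."""

    n_active: int
    n_inactive: int

    @property
    def w_active(self) -> float:
        return self.n_inactive / (self.n_active + self.n_inactive)

    @property
    def w_inactive(self) -> float:
        return self.n_active / (self.n_active + self.n_inactive)


def label_ko_by_count(
    table: DatasetTable, threshold: float = DEFAULT_KO_THRESHOLD
) -> DatasetTable:
    """Label KO records: active iff read_count > threshold (strictly).

    A count exactly at the threshold is inactive.
    """
    if table.task != "KO":
        raise ValueError("count labeling applies to KO tables")
    for rec in table.records:
        if rec.read_count < 0:
            raise ValueError(f"negative read count for {rec.guide_id!r}")
    records = [
        dataclasses.replace(
            r, label=ACTIVE if r.read_count > threshold else INACTIVE
        )
        for r in table.records
    ]
    return table.replace_records(records)


def label_be_by_zscore(
    table: DatasetTable, cutoff: float = DEFAULT_BE_CUTOFF
) -> DatasetTable:
    """Label BE records: active iff zscore < cutoff (strictly).

    A z-score exactly at the cutoff is inactive.
    """
    if table.task != "BE":
        raise ValueError("z-score labeling applies to BE tables")
    records = [
        dataclasses.replace(r, label=ACTIVE if r.zscore < cutoff else INACTIVE)
        for r in table.records
    ]
    return table.replace_records(records)


def log_transform(y, base: float = math.e):
    """y' = log(y + 1); stabilizes heavy-tailed read counts for regression.

    Accepts scalars or arrays; natural log by default.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires non-negative counts")
    out = np.log1p(arr) / math.log(base)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def inverse_log_transform(y_prime, base: float = math.e):
    """Inverse of :func:`log_transform`: y = base**y' - 1."""
    arr = np.asarray(y_prime, dtype=float)
    out = np.expm1(arr * math.log(base))
    return float(out) if np.isscalar(y_prime) or arr.ndim == 0 else out


def binary_labels(table: DatasetTable) -> np.ndarray:
    """0/1 vector (1 = active) from a fully labeled table."""
    labels = table.labels
    if any(lab is None for lab in labels):
        raise ValueError("table contains unlabeled records")
    return np.array([1.0 if lab == ACTIVE else 0.0 for lab in labels])


def compute_class_weights(table: DatasetTable) -> WeightScheme:
    """Class weights from a fully labeled table; both classes must occur."""
    y = binary_labels(table)
    n_active = int(y.sum())
    n_inactive = int(len(y) - n_active)
    if n_active == 0:
        raise ValueError("no active records: class weights undefined")
    if n_inactive == 0:
        raise ValueError("no inactive records: class weights undefined")
    return WeightScheme(n_active=n_active, n_inactive=n_inactive)


def sample_weights(table: DatasetTable, scheme: WeightScheme | None = None) -> np.ndarray:
    """Per-record weight vector: active rows get w_active, inactive rows
    w_inactive, so both classes contribute equal total weight."""
    scheme = scheme or compute_class_weights(table)
    y = binary_labels(table)
    return np.where(y == 1.0, scheme.w_active, scheme.w_inactive)
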
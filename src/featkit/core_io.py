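"""Domain types, sequence validation and tabular / FASTA I/O.

Conventions used throughout the package:

* Sequences are uppercase strings over ``{A, C, G, T}`` plus the alignment
  gap ``-`` and the ambiguity code ``N``.
* Position indexing is 1-based. Position 1 is PAM-distal; for the default
  23-nt layout (20-nt protospacer + 3-nt PAM) positions 21-23 are the PAM,
  so "PAM-proximal" means positions near 20.
* The knockout (KO) task uses paired, aligned gRNA / off-target records with
  a cleavage read count; the base-editing (BE) task uses single gRNA records
  with a proliferation z-score.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Sequence
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

DNA_BASES = ("A", "C", "G", "T")
GAP = "-"
AMBIGUOUS = "N"
VALID_SYMBOLS = frozenset(DNA_BASES) | {GAP, AMBIGUOUS}

#: Default aligned length: 20-nt protospacer followed by the 3-nt PAM.
DEFAULT_LENGTH = 23

ACTIVE = "active"
INACTIVE = "inactive"

Task = Literal["KO", "BE"]


class SchemaError(ValueError):
    """A required column is missing or a file's layout is not understood."""


class SequenceValidationError(ValueError):
    """A sequence or record violates a domain invariant."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


def validate_sequence(
    symbols: str, *, allow_gap: bool = True, allow_n: bool = True
) -> str:
    """Canonicalize ``symbols`` to uppercase and check the alphabet.

    Parameters
    ----------
    symbols:
        Raw sequence string.
    allow_gap, allow_n:
        Whether the alignment gap ``-`` / ambiguity code ``N`` are permitted.

    Returns
    -------
    str
        The validated, uppercased sequence.

    Raises
    ------
    SequenceValidationError
        If any symbol falls outside the permitted alphabet or the sequence
        is empty.
    """
    if not isinstance(symbols, str) or len(symbols) == 0:
        raise SequenceValidationError("sequence must be a non-empty string")
    seq = symbols.upper()
    allowed = set(DNA_BASES)
    if allow_gap:
        allowed.add(GAP)
    if allow_n:
        allowed.add(AMBIGUOUS)
    bad = sorted(set(seq) - allowed)
    if bad:
        raise SequenceValidationError(
            f"invalid symbol(s) {bad} in sequence {seq!r}; "
            f"allowed: {sorted(allowed)}"
        )
    return seq


@dataclasses.dataclass(frozen=True)
class PairedSiteRecord:
    """One aligned gRNA / off-target pair with its cleavage read count.

    ``guide_seq`` and ``target_seq`` must have the same aligned length and a
    gap may never face a gap. ``label`` is ``"active"``/``"inactive"`` once
    assigned (see :func:`featkit.preprocess.label_ko_by_count`) or ``None``.
    """

    guide_id: str
    guide_seq: str
    target_seq: str
    read_count: float
    label: str | None = None

    def __post_init__(self) -> None:
        guide = validate_sequence(self.guide_seq)
        target = validate_sequence(self.target_seq)
        object.__setattr__(self, "guide_seq", guide)
        object.__setattr__(self, "target_seq", target)
        object.__setattr__(self, "read_count", float(self.read_count))
        if len(guide) != len(target):
            raise SequenceValidationError(
                f"guide/target length mismatch for {self.guide_id!r}: "
                f"{len(guide)} vs {len(target)}"
            )
        for i, (g, t) in enumerate(zip(guide, target), start=1):
            if g == GAP and t == GAP:
                raise SequenceValidationError(
                    f"gap aligned to gap at position {i} in {self.guide_id!r}"
                )
        if not np.isfinite(self.read_count) or self.read_count < 0:
            raise SequenceValidationError(
                f"read_count must be a finite non-negative number, "
                f"got {self.read_count!r}"
            )
        if self.label is not None and self.label not in (ACTIVE, INACTIVE):
            raise SequenceValidationError(f"invalid label {self.label!r}")

    @property
    def is_gapped(self) -> bool:
        return GAP in self.guide_seq or GAP in self.target_seq


@dataclasses.dataclass(frozen=True)
class BEScreenRecord:
    """One gRNA from a base-editing screen with its proliferation z-score."""

    guide_id: str
    guide_seq: str
    zscore: float
    label: str | None = None

    def __post_init__(self) -> None:
        seq = validate_sequence(self.guide_seq, allow_gap=False)
        object.__setattr__(self, "guide_seq", seq)
        object.__setattr__(self, "zscore", float(self.zscore))
        if not np.isfinite(self.zscore):
            raise SequenceValidationError(
                f"z-score must be finite, got {self.zscore!r} "
                f"for {self.guide_id!r}"
            )
        if self.label is not None and self.label not in (ACTIVE, INACTIVE):
            raise SequenceValidationError(f"invalid label {self.label!r}")


_RECORD_TYPES = {"KO": PairedSiteRecord, "BE": BEScreenRecord}
_KO_COLUMNS = ["guide_id", "guide_seq", "target_seq", "read_count"]
_BE_COLUMNS = ["guide_id", "guide_seq", "zscore"]


@dataclasses.dataclass
class DatasetTable:
    """A task-homogeneous list of records plus free-form provenance."""

    task: Task
    records: list[PairedSiteRecord] | list[BEScreenRecord]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in _RECORD_TYPES:
            raise ValueError(f"unknown task {self.task!r}; expected KO or BE")
        expected = _RECORD_TYPES[self.task]
        for rec in self.records:
            if not isinstance(rec, expected):
                raise TypeError(
                    f"{self.task} table holds {expected.__name__}, "
                    f"got {type(rec).__name__}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetTable):
            return NotImplemented
        return self.task == other.task and self.records == other.records

    @property
    def guide_ids(self) -> list[str]:
        return [rec.guide_id for rec in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [rec.label for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        cols = _KO_COLUMNS if self.task == "KO" else _BE_COLUMNS
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        data["label"] = ["" if r.label is None else r.label for r in self.records]
        return pd.DataFrame(data)

    def replace_records(self, records: Sequence) -> "DatasetTable":
        return DatasetTable(self.task, list(records), dict(self.provenance))


@dataclasses.dataclass
class FeatureMatrix:
    """A named numeric feature table produced by an encoder.

    ``values`` is an ``(n_samples, n_features)`` float array; feature names
    are unique and ordered. When ``has_distance`` is true the final column is
    the explicit mismatch-count feature and is named ``"distance"``.
    """

    encoding_id: str
    feature_names: list[str]
    values: np.ndarray
    has_distance: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.has_distance and (
            not self.feature_names or self.feature_names[-1] != "distance"
        ):
            raise ValueError("distance column must be last and named 'distance'")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def _sniff_frame(path: Path) -> pd.DataFrame:
    """Read a delimited text table, accepting tab or comma separators."""
    with open(path) as fh:
        header = fh.readline()
    if header == "":
        raise EmptyInputError(f"{path} is empty")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(
        path, sep=sep, dtype={"guide_id": str}, float_precision="round_trip"
    )


def read_dataset(path: str | Path, task: Task) -> DatasetTable:
    """Read a KO or BE dataset from a TSV/CSV file.

    Required columns — KO: ``guide_id, guide_seq, target_seq, read_count``;
    BE: ``guide_id, guide_seq, zscore``. An optional ``label`` column with
    values ``active``/``inactive`` (blank for unset) is honoured. Rows that
    violate a sequence invariant are reported together by 1-based data-row
    number.
    """
    path = Path(path)
    if task not in _RECORD_TYPES:
        raise ValueError(f"unknown task {task!r}; expected KO or BE")
    frame = _sniff_frame(path)
    required = _KO_COLUMNS if task == "KO" else _BE_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path} has a header but no data rows")

    has_label = "label" in frame.columns
    records = []
    failures: list[str] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        label = None
        if has_label:
            raw = getattr(row, "label")
            if not (raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == ""):
                label = str(raw)
        try:
            if task == "KO":
                records.append(
                    PairedSiteRecord(
                        guide_id=str(row.guide_id),
                        guide_seq=str(row.guide_seq),
                        target_seq=str(row.target_seq),
                        read_count=float(row.read_count),
                        label=label,
                    )
                )
            else:
                records.append(
                    BEScreenRecord(
                        guide_id=str(row.guide_id),
                        guide_seq=str(row.guide_seq),
                        zscore=float(row.zscore),
                        label=label,
                    )
                )
        except (SequenceValidationError, ValueError) as exc:
            failures.append(f"row {row_number}: {exc}")
    if failures:
        raise SequenceValidationError(
            f"{path}: {len(failures)} invalid row(s):\n" + "\n".join(failures)
        )
    return DatasetTable(task, records, provenance={"source": str(path)})


def _format_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_dataset(table: DatasetTable, path: str | Path) -> Path:
    """Write ``table`` as a TSV such that :func:`read_dataset` restores it
    field-for-field. Gaps in aligned sequences are preserved verbatim."""
    path = Path(path)
    frame = table.to_frame()
    if table.task == "KO":
        frame["read_count"] = [_format_count(x) for x in frame["read_count"]]
    else:
        frame["zscore"] = [repr(float(z)) for z in frame["zscore"]]
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_guides_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA guide list as ``(guide_id, sequence)`` pairs in file
    order. Sequences are uppercased and validated; duplicate IDs are an
    error."""
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SchemaError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = validate_sequence(str(rec.seq), allow_gap=False, allow_n=True)
        out.append((rec.id, seq))
    return out
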
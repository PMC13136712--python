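"""Sequence feature encodings for guide-activity models.

Two families are provided. *Alignment-based* encodings consume a gRNA /
off-target pair and expose the mismatch pattern explicitly:

========  =========================================================  dims (L=23)
NPM       per-position one-hot over the 16 (guide, target) base          368
          pairs — records exactly which substitution occurred
BULGES    NPM extended with a gap channel on both axes (5x5 grid         575
          per position) so indels in the alignment are representable
LEP       per-position integer label 0-15 for the (guide, target)         23
          base pair
MM        per-position binary mismatch indicator                          23
8XL       one-hot(guide) concatenated with one-hot(off-target)           184
========  =========================================================  ===========

*Sequence-content* encodings consume a single sequence and, for the paired
task, combine guide and target one-hots with a bitwise OR (mismatched
positions then carry two set bits):

========  =========================================================  dims (L=23)
OH        4-channel positional one-hot (OR-paired for KO)                 92
OH5C      5-channel variant with an extra channel for gap/N              115
KMER      overlapping k-mer counts, k=3 by default                    64 (63*)
========  =========================================================  ===========

(*) ``kmer_compact=True`` drops the lexicographically last k-mer
(``TTT`` at k=3), the standard fix for the compositional collinearity of a
closed count vector, giving the commonly printed 63-feature variant.

All encoders derive their dimensionality from the aligned length, so short
toy sequences are first-class. Feature names use 1-based positions with
position 1 PAM-distal.
"""

from __future__ import annotations

import dataclasses
import itertools
import shutil
import subprocess

import numpy as np

from featkit.core_io import (
    AMBIGUOUS,
    DNA_BASES,
    GAP,
    BEScreenRecord,
    DatasetTable,
    FeatureMatrix,
    PairedSiteRecord,
    SequenceValidationError,
)

ENCODING_IDS = ("NPM", "BULGES", "LEP", "MM", "8XL", "OH", "OH5C", "KMER")

#: Encodings that require an aligned pair (KO task only).
ALIGNMENT_BASED = ("NPM", "BULGES", "LEP", "MM", "8XL")

_BULGE_ALPHABET = DNA_BASES + (GAP,)
_PAIR_ORDER = list(itertools.product(DNA_BASES, DNA_BASES))  # AA, AC, ..., TT


class GappedInputError(SequenceValidationError):
    """A gap-free encoder received a gapped alignment (use BULGES instead)."""


class UnsupportedSymbolError(SequenceValidationError):
    """An encoder received a symbol outside its alphabet (e.g. 'N')."""


@dataclasses.dataclass
class EncoderSpec:
    """Configuration of one encoding run.

    ``k`` applies to KMER only; ``kmer_compact`` selects the 63-feature
    vocabulary (drops the lexicographically last k-mer).
    """

    encoding_id: str
    k: int = 3
    with_distance: bool = False
    kmer_compact: bool = False

    def __post_init__(self) -> None:
        self.encoding_id = self.encoding_id.upper()
        if self.encoding_id not in ENCODING_IDS:
            raise ValueError(
                f"unknown encoding {self.encoding_id!r}; one of {ENCODING_IDS}"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _check_gap_free(record: PairedSiteRecord | BEScreenRecord, encoder: str) -> None:
    seqs = (
        (record.guide_seq, record.target_seq)
        if isinstance(record, PairedSiteRecord)
        else (record.guide_seq,)
    )
    for seq in seqs:
        if GAP in seq:
            raise GappedInputError(
                f"{encoder} requires gap-free sequences "
                f"(guide {record.guide_id!r}); use the BULGES encoding "
                f"for gapped alignments"
            )


def _check_no_n(record: PairedSiteRecord | BEScreenRecord, encoder: str) -> None:
    seqs = (
        (record.guide_seq, record.target_seq)
        if isinstance(record, PairedSiteRecord)
        else (record.guide_seq,)
    )
    for seq in seqs:
        if AMBIGUOUS in seq:
            raise UnsupportedSymbolError(
                f"{encoder} does not represent 'N' (guide {record.guide_id!r}); "
                f"use OH5C or resolve the ambiguity"
            )


def npm_feature_names(length: int) -> list[str]:
    return [
        f"pos{p}_{r}{d}"
        for p in range(1, length + 1)
        for r in DNA_BASES
        for d in DNA_BASES
    ]


def encode_npm(pair: PairedSiteRecord) -> np.ndarray:
    """Nucleotide-to-position mapping: per position, a one-hot cell over the
    16 (guide base, target base) combinations. 16·L features (368 at L=23)."""
    _check_gap_free(pair, "NPM")
    _check_no_n(pair, "NPM")
    length = len(pair.guide_seq)
    vec = np.zeros(16 * length)
    for p, (g, t) in enumerate(zip(pair.guide_seq, pair.target_seq)):
        vec[16 * p + 4 * DNA_BASES.index(g) + DNA_BASES.index(t)] = 1.0
    return vec


def bulges_feature_names(length: int) -> list[str]:
    return [
        f"pos{p}_{r}{d}"
        for p in range(1, length + 1)
        for r in _BULGE_ALPHABET
        for d in _BULGE_ALPHABET
    ]


def encode_bulges(pair: PairedSiteRecord) -> np.ndarray:
    """NPM over the 5-symbol alphabet {A,C,G,T,-}: a target gap sets cell
    (guide base, '-'), a guide gap sets ('-', target base). 25·L features."""
    _check_no_n(pair, "BULGES")
    length = len(pair.guide_seq)
    vec = np.zeros(25 * length)
    for p, (g, t) in enumerate(zip(pair.guide_seq, pair.target_seq)):
        # gap-vs-gap is excluded by the record invariant
        vec[25 * p + 5 * _BULGE_ALPHABET.index(g) + _BULGE_ALPHABET.index(t)] = 1.0
    return vec


def lep_feature_names(length: int) -> list[str]:
    return [f"pos{p}" for p in range(1, length + 1)]


def encode_lep(pair: PairedSiteRecord) -> np.ndarray:
    """Label-encoding pairwise: the lexicographic index (AA=0 ... TT=15) of
    the (guide, target) base pair at each position. L features."""
    _check_gap_free(pair, "LEP")
    _check_no_n(pair, "LEP")
    return np.array(
        [
            float(_PAIR_ORDER.index((g, t)))
            for g, t in zip(pair.guide_seq, pair.target_seq)
        ]
    )


def decode_lep(vec: np.ndarray) -> tuple[str, str]:
    """Inverse of :func:`encode_lep`; returns (guide_seq, target_seq)."""
    pairs = [_PAIR_ORDER[int(v)] for v in vec]
    return "".join(g for g, _ in pairs), "".join(t for _, t in pairs)


def encode_mm(pair: PairedSiteRecord) -> np.ndarray:
    """Binary per-position mismatch indicator; a gap column counts as a
    mismatch. Sums to :func:`compute_distance`."""
    return np.array(
        [float(g != t) for g, t in zip(pair.guide_seq, pair.target_seq)]
    )


def _onehot(seq: str) -> np.ndarray:
    vec = np.zeros(4 * len(seq))
    for p, base in enumerate(seq):
        vec[4 * p + DNA_BASES.index(base)] = 1.0
    return vec


def xl8_feature_names(length: int) -> list[str]:
    return [
        f"{side}_pos{p}_{b}"
        for side in ("guide", "target")
        for p in range(1, length + 1)
        for b in DNA_BASES
    ]


def encode_8xl(pair: PairedSiteRecord) -> np.ndarray:
    """One-hot of the guide concatenated with one-hot of the off-target:
    8·L features (184 at L=23)."""
    _check_gap_free(pair, "8XL")
    _check_no_n(pair, "8XL")
    return np.concatenate([_onehot(pair.guide_seq), _onehot(pair.target_seq)])


def onehot_feature_names(length: int) -> list[str]:
    return [f"pos{p}_{b}" for p in range(1, length + 1) for b in DNA_BASES]


def encode_onehot(record: PairedSiteRecord | BEScreenRecord) -> np.ndarray:
    """Positional one-hot, 4·L features (92 at L=23).

    For a single sequence this is the standard one-hot. For a pair the guide
    and target one-hots are combined with a bitwise OR, so matched positions
    carry one set bit and mismatched positions two, at unchanged
    dimensionality.
    """
    _check_gap_free(record, "OH")
    _check_no_n(record, "OH")
    if isinstance(record, PairedSiteRecord):
        return np.maximum(_onehot(record.guide_seq), _onehot(record.target_seq))
    return _onehot(record.guide_seq)


_OH5C_CHANNELS = DNA_BASES + ("X",)


def oh5c_feature_names(length: int) -> list[str]:
    return [f"pos{p}_{c}" for p in range(1, length + 1) for c in _OH5C_CHANNELS]


def _onehot5(seq: str) -> np.ndarray:
    vec = np.zeros(5 * len(seq))
    for p, base in enumerate(seq):
        channel = 4 if base in (GAP, AMBIGUOUS) else DNA_BASES.index(base)
        vec[5 * p + channel] = 1.0
    return vec


def encode_oh5c(record: PairedSiteRecord | BEScreenRecord) -> np.ndarray:
    """Five-channel one-hot {A,C,G,T,X} where X fires for '-' or 'N';
    pairs are OR-combined as in :func:`encode_onehot`. 5·L features."""
    if isinstance(record, PairedSiteRecord):
        return np.maximum(_onehot5(record.guide_seq), _onehot5(record.target_seq))
    return _onehot5(record.guide_seq)


def kmer_vocabulary(k: int = 3, compact: bool = False) -> list[str]:
    vocab = ["".join(p) for p in itertools.product(DNA_BASES, repeat=k)]
    return vocab[:-1] if compact else vocab


def kmer_feature_names(k: int = 3, compact: bool = False) -> list[str]:
    return [f"kmer_{m}" for m in kmer_vocabulary(k, compact)]


def encode_kmer(seq: str, spec: EncoderSpec | None = None) -> np.ndarray:
    """Counts of overlapping k-mers over the 4^k vocabulary (64 at k=3;
    63 with ``kmer_compact``, which drops the last k-mer TTT)."""
    spec = spec or EncoderSpec("KMER")
    k = spec.k
    if GAP in seq or AMBIGUOUS in seq:
        raise UnsupportedSymbolError("KMER requires gap-free sequences without 'N'")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    vocab = kmer_vocabulary(k, spec.kmer_compact)
    index = {m: i for i, m in enumerate(vocab)}
    vec = np.zeros(len(vocab))
    for i in range(len(seq) - k + 1):
        j = index.get(seq[i : i + k])
        if j is not None:
            vec[j] += 1.0
    return vec


def compute_distance(pair: PairedSiteRecord) -> int:
    """Hamming-style distance: the number of aligned positions whose symbols
    differ; a gap facing a base counts as one edit."""
    return sum(g != t for g, t in zip(pair.guide_seq, pair.target_seq))


def append_distance(
    matrix: FeatureMatrix, pairs: list[PairedSiteRecord]
) -> FeatureMatrix:
    """Append the explicit mismatch-count column (named ``distance``) as the
    final feature. Appending twice is an error."""
    if matrix.has_distance:
        raise ValueError("matrix already carries a distance column")
    if matrix.n_samples != len(pairs):
        raise ValueError(
            f"matrix has {matrix.n_samples} rows but {len(pairs)} pairs given"
        )
    dist = np.array([[float(compute_distance(p))] for p in pairs])
    return FeatureMatrix(
        encoding_id=matrix.encoding_id,
        feature_names=list(matrix.feature_names) + ["distance"],
        values=np.hstack([matrix.values, dist]),
        has_distance=True,
    )


_PAIR_ENCODERS = {
    "NPM": (encode_npm, npm_feature_names),
    "BULGES": (encode_bulges, bulges_feature_names),
    "LEP": (encode_lep, lep_feature_names),
    "MM": (encode_mm, lep_feature_names),
    "8XL": (encode_8xl, xl8_feature_names),
    "OH": (encode_onehot, onehot_feature_names),
    "OH5C": (encode_oh5c, oh5c_feature_names),
}


def encode_dataset(table: DatasetTable, spec: EncoderSpec) -> FeatureMatrix:
    """Encode every record of ``table`` into a :class:`FeatureMatrix`.

    Alignment-based encodings require a KO table. KMER encodes the
    off-target sequence for KO (the compositional context of the cleavage
    site) and the gRNA for BE. ``spec.with_distance`` appends the mismatch
    count (KO only).
    """
    if len(table) == 0:
        raise ValueError("cannot encode an empty table")
    if spec.encoding_id in ALIGNMENT_BASED and table.task != "KO":
        raise ValueError(
            f"{spec.encoding_id} is alignment-based and needs paired (KO) records"
        )
    records = list(table.records)
    if spec.encoding_id == "KMER":
        seqs = [
            r.target_seq if isinstance(r, PairedSiteRecord) else r.guide_seq
            for r in records
        ]
        rows = [encode_kmer(s, spec) for s in seqs]
        names = kmer_feature_names(spec.k, spec.kmer_compact)
    else:
        encode, name_fn = _PAIR_ENCODERS[spec.encoding_id]
        lengths = {len(r.guide_seq) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"records have mixed aligned lengths {sorted(lengths)}"
            )
        rows = [encode(r) for r in records]
        names = name_fn(lengths.pop())
    matrix = FeatureMatrix(spec.encoding_id, names, np.vstack(rows))
    if spec.with_distance:
        if table.task != "KO":
            raise ValueError("distance feature applies to paired (KO) records only")
        matrix = append_distance(matrix, records)
    return matrix


# --- engineered biophysical descriptors -------------------------------------

class FoldingError(RuntimeError):
    """The external folding tool ran but its output could not be parsed."""


def gc_content(seq: str) -> float:
    """GC percentage of a gap-free sequence, in [0, 100]."""
    if not seq:
        raise ValueError("empty sequence")
    if GAP in seq:
        raise ValueError("gc_content requires a gap-free sequence")
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def melting_temperature(seq: str) -> float:
    """Wallace-rule melting temperature 2·(A+T) + 4·(G+C) in °C, the
    standard estimate for short oligos."""
    from Bio.SeqUtils import MeltingTemp

    if not seq:
        raise ValueError("empty sequence")
    if GAP in seq or AMBIGUOUS in seq:
        raise ValueError("melting_temperature requires an unambiguous sequence")
    return float(MeltingTemp.Tm_Wallace(seq))


def folding_energy(seq: str, *, executable: str = "RNAfold") -> float | None:
    """Minimum free energy (kcal/mol) of the sequence's RNA secondary
    structure, computed with an external folding tool.

    Returns ``None`` when the tool is not on PATH (the feature column is
    then simply omitted downstream); raises :class:`FoldingError` when the
    tool runs but produces unparseable output.
    """
    if shutil.which(executable) is None:
        return None
    proc = subprocess.run(
        [executable, "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=False,
    )
    if proc.returncode != 0:
        raise FoldingError(f"{executable} failed: {proc.stderr.strip()}")
    # second output line looks like: "(((...))) ( -1.20)"
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    for line in lines:
        if "(" in line and line.rstrip().endswith(")"):
            inner = line[line.rfind("(") + 1 : line.rfind(")")].strip()
            try:
                return float(inner)
            except ValueError:
                continue
    raise FoldingError(f"could not parse MFE from {executable} output")


def biophysical_features(table: DatasetTable) -> FeatureMatrix:
    """GC content, Wallace Tm and (when a folding tool is available) the
    RNA-fold minimum free energy of each guide sequence."""
    seqs = [r.guide_seq for r in table.records]
    cols = {
        "gc_content": [gc_content(s) for s in seqs],
        "melting_temperature": [melting_temperature(s) for s in seqs],
    }
    if shutil.which("RNAfold") is not None:
        cols["folding_energy"] = [folding_energy(s) for s in seqs]
    values = np.column_stack([np.asarray(v, dtype=float) for v in cols.values()])
    return FeatureMatrix("BIOPHYS", list(cols.keys()), values)
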
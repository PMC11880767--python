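"""Dataset representation: enzyme–substrate–kcat records.

Covers reading the delimited table format, global-alignment sequence
identity, similarity-based deduplication (keep the longest sequence among
>90%-identical enzymes sharing a substrate), seeded train/validation/test
splitting, and stratification of a test set by maximum identity to the
training set.

kcat is stored in s⁻¹ and modelled throughout on the log10 scale: targets,
loss and RMSE all live in log10 units, and raw rates are recovered as
``10**log_kcat`` at the API boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .errors import (
    EmptyDatasetError,
    FormatError,
    KcatError,
    SplitError,
    StratificationError,
)

__all__ = [
    "EnzymeType",
    "KcatRecord",
    "DatasetSplit",
    "SimilarityBin",
    "ReadReport",
    "read_dataset",
    "write_dataset",
    "pairwise_identity",
    "deduplicate",
    "split_dataset",
    "stratify_by_similarity",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "record_id",
    "sequence",
    "smiles",
    "kcat",
    "structure_path",
    "enzyme_type",
    "ec_class",
    "organism",
]

_REQUIRED_COLUMNS = ("sequence", "smiles", "kcat")


class EnzymeType(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"
    UNKNOWN = "unknown"


@dataclass
class KcatRecord:
    """One enzyme–substrate pair with its turnover number.

    Parameters
    ----------
    record_id : str
        Opaque stable identifier.
    sequence : str
        Amino-acid sequence (uppercase; 20 canonical letters plus X).
    smiles : str
        Substrate SMILES.
    kcat : float
        Turnover number in s⁻¹; must be positive.
    log_kcat : float
        log10(kcat / s⁻¹); derived automatically when omitted.
    """

    record_id: str
    sequence: str
    smiles: str
    kcat: float
    log_kcat: float | None = None
    structure_path: str | None = None
    enzyme_type: EnzymeType = EnzymeType.UNKNOWN
    ec_class: int | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise KcatError(f"record {self.record_id!r}: empty sequence")
        if not (self.kcat > 0) or not math.isfinite(self.kcat):
            raise KcatError(
                f"record {self.record_id!r}: kcat must be positive and finite, "
                f"got {self.kcat!r}"
            )
        if self.log_kcat is None:
            self.log_kcat = math.log10(self.kcat)
        if isinstance(self.enzyme_type, str):
            self.enzyme_type = EnzymeType(self.enzyme_type)
        if self.ec_class is not None:
            self.ec_class = int(self.ec_class)
            if not 1 <= self.ec_class <= 7:
                raise KcatError(
                    f"record {self.record_id!r}: ec_class must be 1–7, got {self.ec_class}"
                )


@dataclass
class ReadReport:
    """Per-row account of rejected dataset rows."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of record ids."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int
    ratios: tuple[float, float, float]

    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("train", "validation", "test"):
            for rid in getattr(self, name):
                out[rid] = name
        return out


@dataclass
class SimilarityBin:
    """Test records grouped by max identity to the training set."""

    label: str  # one of "0-50%", "50-90%", "90-100%"
    record_ids: list[str]


def _infer_separator(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dataset(path: str | Path) -> tuple[list[KcatRecord], ReadReport]:
    """Read a delimited enzyme–substrate–kcat table.

    Returns the accepted records together with a :class:`ReadReport` listing
    every rejected row (non-positive or non-numeric kcat, empty sequence)
    and why it was rejected. Record ids are taken from the ``record_id``
    column when present, else generated deterministically from row position.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"dataset file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=_infer_separator(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"dataset file is empty: {path}") from None
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"required column {column!r} missing from {path}")
    if len(frame) == 0:
        raise EmptyDatasetError(f"dataset has a header but no rows: {path}")

    report = ReadReport(n_rows=len(frame))
    records: list[KcatRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        data = {col: getattr(row, col, None) for col in frame.columns}

        def _opt(col: str):
            value = data.get(col)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            value = str(value).strip()
            return value or None

        record_id = _opt("record_id") or f"r{i:05d}"
        try:
            kcat = float(data["kcat"])
        except (TypeError, ValueError):
            report.rejected.append((i, f"non-numeric kcat {data['kcat']!r}"))
            continue
        if not (kcat > 0) or not math.isfinite(kcat):
            report.rejected.append((i, f"non-positive kcat {kcat!r}"))
            continue
        sequence = (_opt("sequence") or "").upper()
        if not sequence:
            report.rejected.append((i, "empty sequence"))
            continue
        records.append(
            KcatRecord(
                record_id=record_id,
                sequence=sequence,
                smiles=_opt("smiles") or "",
                kcat=kcat,
                structure_path=_opt("structure_path"),
                enzyme_type=EnzymeType(_opt("enzyme_type") or "unknown"),
                ec_class=_opt("ec_class"),
                organism=_opt("organism"),
            )
        )
    report.n_accepted = len(records)
    return records, report


def write_dataset(records: Iterable[KcatRecord], path: str | Path) -> None:
    """Write records in the canonical TSV/CSV dialect (inverse of read_dataset)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "sequence": r.sequence,
                "smiles": r.smiles,
                "kcat": repr(r.kcat),
                "structure_path": r.structure_path or "",
                "enzyme_type": r.enzyme_type.value,
                "ec_class": "" if r.ec_class is None else r.ec_class,
                "organism": r.organism or "",
            }
        )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(
        path, sep=_infer_separator(path), index=False
    )


# ---------------------------------------------------------------------------
# sequence identity
# ---------------------------------------------------------------------------

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match=1, mismatch=0, small linear gap penalty: the
    # score therefore counts matches while discouraging needless gaps
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -0.1
        aligner.extend_gap_score = -0.1
        _ALIGNER = aligner
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity = matched columns / alignment length (gap columns included in
    the denominator). The pair is ordered canonically before aligning so the
    function is exactly symmetric even when several alignments are co-optimal.
    """
    if not seq_a or not seq_b:
        raise KcatError("pairwise_identity requires non-empty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    alignment = next(iter(_aligner().align(seq_a, seq_b)))
    identities = alignment.counts().identities
    return identities / alignment.length


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _canonical_smiles(smiles: str) -> str:
    try:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            return Chem.MolToSmiles(mol)
    except Exception:  # pragma: no cover - rdkit always importable here
        pass
    return smiles


def deduplicate(
    records: Sequence[KcatRecord],
    identity_threshold: float = 0.9,
) -> tuple[list[KcatRecord], list[KcatRecord]]:
    """Remove near-duplicate enzymes measured on the same substrate.

    Within each group of records sharing an (canonicalised) substrate,
    sequences are clustered by single linkage at pairwise identity strictly
    greater than `identity_threshold`; from each cluster only the record
    with the longest sequence survives (ties broken by lexicographically
    smallest record_id). Records with distinct substrates are never merged.

    Returns ``(kept, removed)`` preserving the input order within each list.
    """
    groups: dict[str, list[int]] = {}
    for i, record in enumerate(records):
        groups.setdefault(_canonical_smiles(record.smiles), []).append(i)

    kept_idx: set[int] = set()
    identity_cache: dict[tuple[str, str], float] = {}

    def identity(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in identity_cache:
            identity_cache[key] = pairwise_identity(*key)
        return identity_cache[key]

    for indices in groups.values():
        # single-linkage clusters via union-find
        parent = {i: i for i in indices}

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a_pos, i in enumerate(indices):
            for j in indices[a_pos + 1 :]:
                if identity(records[i].sequence, records[j].sequence) > identity_threshold:
                    parent[find(i)] = find(j)

        clusters: dict[int, list[int]] = {}
        for i in indices:
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            best = min(
                members,
                key=lambda i: (-len(records[i].sequence), records[i].record_id),
            )
            kept_idx.add(best)

    kept = [r for i, r in enumerate(records) if i in kept_idx]
    removed = [r for i, r in enumerate(records) if i not in kept_idx]
    return kept, removed


# ---------------------------------------------------------------------------
# splitting and stratification
# ---------------------------------------------------------------------------

def split_dataset(
    records: Sequence[KcatRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded uniform random train/validation/test partition.

    Validation and test sizes are the floored ratio targets; the remainder
    goes to train, so e.g. 11 records at (0.8, 0.1, 0.1) split as (9, 1, 1).
    """
    if len(records) < 3:
        raise SplitError(f"need at least 3 records to split, got {len(records)}")
    if any(r <= 0 for r in ratios):
        raise SplitError(f"ratios must be positive, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios must sum to 1, got {ratios}")

    ids = sorted(r.record_id for r in records)
    if len(set(ids)) != len(ids):
        raise SplitError("record_ids must be unique to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]

    n = len(ids)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
        ratios=tuple(ratios),
    )


_BIN_LABELS = ("0-50%", "50-90%", "90-100%")


def max_identity_to_train(
    test_records: Sequence[KcatRecord], train_records: Sequence[KcatRecord]
) -> dict[str, float]:
    """Maximum pairwise identity of each test record against the train set."""
    if not train_records:
        raise StratificationError("train set is empty")
    train_seqs = sorted({r.sequence for r in train_records})
    cache: dict[str, float] = {}
    out: dict[str, float] = {}
    for record in test_records:
        if record.sequence not in cache:
            cache[record.sequence] = max(
                pairwise_identity(record.sequence, t) for t in train_seqs
            )
        out[record.record_id] = cache[record.sequence]
    return out


def similarity_bin_label(identity: float) -> str:
    """Bin label for a max-identity score: [0,0.5), [0.5,0.9), [0.9,1.0]."""
    if identity < 0.5:
        return _BIN_LABELS[0]
    if identity < 0.9:
        return _BIN_LABELS[1]
    return _BIN_LABELS[2]


def stratify_by_similarity(
    test_records: Sequence[KcatRecord], train_records: Sequence[KcatRecord]
) -> list[SimilarityBin]:
    """Partition test records into 0–50% / 50–90% / 90–100% identity bins.

    Each test record is scored by its maximum global-alignment identity to
    any training sequence; bins are right-open except the last, which is
    closed at 1.0, so every score lands in exactly one bin.
    """
    scores = max_identity_to_train(test_records, train_records)
    bins = {label: [] for label in _BIN_LABELS}
    for record in test_records:
        bins[similarity_bin_label(scores[record.record_id])].append(record.record_id)
    return [SimilarityBin(label=label, record_ids=bins[label]) for label in _BIN_LABELS]
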
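"""Overlapping n-gram tokenization of amino-acid sequences.

A sequence of length L becomes L − n + 1 overlapping windows of n letters,
each mapped to an integer id from a vocabulary built on the training set;
windows unseen at vocabulary-build time map to a reserved UNK id. Ambiguous
or non-canonical letters (B, Z, U, O, J) are normalised to X before
windowing, bounding the alphabet at 21 symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import TokenizationError

__all__ = [
    "AMINO_ACIDS",
    "UNK_TOKEN",
    "NGramVocab",
    "NGramSequence",
    "normalize_sequence",
    "build_vocab",
    "tokenize",
    "residue_type_ids",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20; X is the 21st bucket
_NON_CANONICAL = str.maketrans({c: "X" for c in "BZUOJ"})
UNK_TOKEN = "<UNK>"


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map non-canonical letters (B, Z, U, O, J) to X."""
    seq = sequence.upper().translate(_NON_CANONICAL)
    return "".join(c if c in AMINO_ACIDS else "X" for c in seq)


@dataclass
class NGramVocab:
    """n-gram string → contiguous integer id, with a reserved UNK."""

    n: int
    token_to_id: dict[str, int]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK_TOKEN]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"#n={self.n}\n")
            for token, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                handle.write(f"{token}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path) -> "NGramVocab":
        token_to_id: dict[str, int] = {}
        n = 1
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#n="):
                    n = int(line[3:])
                    continue
                token, idx = line.split("\t")
                token_to_id[token] = int(idx)
        return cls(n=n, token_to_id=token_to_id)


@dataclass
class NGramSequence:
    """Token ids of the L − n + 1 overlapping windows of one sequence."""

    token_ids: np.ndarray
    source_length: int

    def __len__(self) -> int:
        return len(self.token_ids)


def _windows(sequence: str, n: int, record_id: str | None = None) -> list[str]:
    if len(sequence) < n:
        name = f" (record {record_id})" if record_id else ""
        raise TokenizationError(
            f"sequence of length {len(sequence)} is shorter than n-gram size {n}{name}"
        )
    return [sequence[i : i + n] for i in range(len(sequence) - n + 1)]


def build_vocab(sequences: Iterable[str], n: int = 3) -> NGramVocab:
    """Collect every distinct n-gram in `sequences` into a vocabulary.

    Ids are assigned in lexicographic token order (so the mapping does not
    depend on input order), with UNK appended last.
    """
    grams: set[str] = set()
    for seq in sequences:
        grams.update(_windows(normalize_sequence(seq), n))
    token_to_id = {token: i for i, token in enumerate(sorted(grams))}
    token_to_id[UNK_TOKEN] = len(token_to_id)
    return NGramVocab(n=n, token_to_id=token_to_id)


def tokenize(sequence: str, vocab: NGramVocab, record_id: str | None = None) -> NGramSequence:
    """Map a sequence to its window token ids; unseen windows become UNK."""
    seq = normalize_sequence(sequence)
    ids = [
        vocab.token_to_id.get(w, vocab.unk_id)
        for w in _windows(seq, vocab.n, record_id)
    ]
    return NGramSequence(token_ids=np.array(ids, dtype=np.intp), source_length=len(seq))


_RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}


def residue_type_ids(sequence: str) -> np.ndarray:
    """Per-residue type ids over the 21-letter alphabet (X last)."""
    seq = normalize_sequence(sequence)
    return np.array([_RESIDUE_INDEX[c] for c in seq], dtype=np.intp)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (header, sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
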
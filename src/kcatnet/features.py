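"""Record featurization: from KcatRecords to model-ready arrays.

Featurization is done once per dataset and cached on the record: n-gram
token ids, residue-type ids, the contact map with its precomputed
symmetric-normalised propagator (the propagator depends only on the graph,
so it is shared across every training epoch), and the substrate molecular
graph with its propagator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .network import ModelConfig
from .nn import normalized_propagator
from .records import KcatRecord
from .sequence import NGramVocab, build_vocab, residue_type_ids, tokenize
from .structure import ContactMap, ProteinStructure, build_contact_map, parse_structure
from .substrate import AtomEnvVocab, build_env_vocab, smiles_to_graph

__all__ = ["FeaturizedRecord", "build_vocabularies", "featurize_records"]


@dataclass
class FeaturizedRecord:
    """All model inputs for one enzyme–substrate pair."""

    record_id: str
    target: float  # log10 kcat
    atom_token_ids: np.ndarray
    substrate_adjacency: np.ndarray
    substrate_propagator: np.ndarray
    token_ids: np.ndarray | None = None
    residue_type_ids: np.ndarray | None = None
    contact_adjacency: np.ndarray | None = None
    protein_propagator: np.ndarray | None = None

    @property
    def n_residues(self) -> int | None:
        if self.contact_adjacency is None:
            return None
        return self.contact_adjacency.shape[0]


def build_vocabularies(
    records: Sequence[KcatRecord], config: ModelConfig
) -> tuple[NGramVocab, AtomEnvVocab]:
    """Build the n-gram and atom-environment vocabularies from training records."""
    seq_vocab = build_vocab((r.sequence for r in records), n=config.ngram_n)
    env_vocab = build_env_vocab({r.smiles for r in records}, radius=config.env_radius)
    return seq_vocab, env_vocab


def _resolve_structure(
    record: KcatRecord,
    structures: Mapping[str, ProteinStructure] | None,
    base_dir: Path | None,
    cache: dict[str, ProteinStructure],
) -> ProteinStructure:
    if structures is not None and record.record_id in structures:
        return structures[record.record_id]
    if record.structure_path is None:
        raise InputError(
            f"record {record.record_id!r} has no structure (path or in-memory)"
        )
    path = Path(record.structure_path)
    if not path.is_absolute() and base_dir is not None:
        path = base_dir / path
    key = str(path)
    if key not in cache:
        cache[key] = parse_structure(path)
    return cache[key]


def featurize_records(
    records: Sequence[KcatRecord],
    seq_vocab: NGramVocab | None,
    env_vocab: AtomEnvVocab,
    config: ModelConfig,
    structures: Mapping[str, ProteinStructure] | None = None,
    base_dir: str | Path | None = None,
) -> list[FeaturizedRecord]:
    """Featurize records for the configured input mode.

    Structures come either from the `structures` mapping (record_id →
    ProteinStructure) or are parsed from each record's ``structure_path``
    (relative paths resolved against `base_dir`). A record whose sequence
    length differs from its structure's Cα count is a hard error: silent
    truncation would corrupt residue-level interpretation.
    """
    base_dir = Path(base_dir) if base_dir is not None else None
    structure_cache: dict[str, ProteinStructure] = {}
    mol_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    out: list[FeaturizedRecord] = []
    for record in records:
        if record.smiles not in mol_cache:
            graph = smiles_to_graph(record.smiles, env_vocab)
            mol_cache[record.smiles] = (
                graph.atom_token_ids,
                graph.adjacency,
                normalized_propagator(graph.adjacency),
            )
        atom_ids, mol_adj, mol_prop = mol_cache[record.smiles]
        feat = FeaturizedRecord(
            record_id=record.record_id,
            target=record.log_kcat,
            atom_token_ids=atom_ids,
            substrate_adjacency=mol_adj,
            substrate_propagator=mol_prop,
        )
        if config.uses_sequence:
            feat.token_ids = tokenize(record.sequence, seq_vocab, record.record_id).token_ids
        if config.uses_structure:
            structure = _resolve_structure(record, structures, base_dir, structure_cache)
            if len(structure) != len(record.sequence):
                raise InputError(
                    f"record {record.record_id!r}: sequence length "
                    f"{len(record.sequence)} does not match structure Cα count "
                    f"{len(structure)}"
                )
            contact = build_contact_map(structure, threshold=config.contact_threshold)
            adjacency = contact.adjacency.astype(np.int8)
            if not config.keep_sequential_contacts:
                n = adjacency.shape[0]
                mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
                adjacency = np.where(mask, 0, adjacency).astype(np.int8)
            feat.residue_type_ids = residue_type_ids(record.sequence)
            feat.contact_adjacency = adjacency
            feat.protein_propagator = normalized_propagator(adjacency)
        out.append(feat)
    return out
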
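"""Substrate featurization: SMILES → molecular graph.

A substrate is represented by its heavy-atom graph: per-atom tokens encoding
the atom's chemical environment out to a configurable radius r, plus the
binary bond adjacency matrix. Environment keys are built by iterated
neighbourhood composition (Weisfeiler–Lehman style): at r=0 the key is the
atom type, and each further round combines an atom's key with the sorted
multiset of its neighbours' keys. RDKit does the parsing, canonicalisation
and bond bookkeeping; graphs are always built from the canonical SMILES so
different spellings of one molecule yield identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import ChemistryParseError

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors are raised instead

__all__ = [
    "MoleculeGraph",
    "AtomEnvVocab",
    "atom_environment_keys",
    "build_env_vocab",
    "smiles_to_graph",
    "heavy_atom_count",
]

UNK_ENV = "<UNK>"


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryParseError(smiles)
    if mol.GetNumAtoms() == 0:
        raise ChemistryParseError(smiles, f"no heavy atoms in SMILES {smiles!r}")
    # rebuild from canonical SMILES so atom order is spelling-independent
    canonical = Chem.MolToSmiles(mol)
    return Chem.MolFromSmiles(canonical)


def atom_environment_keys(mol: Chem.Mol, radius: int) -> list[str]:
    """Canonical r-radius environment key for every heavy atom.

    Round 0 keys are atom types (element symbol, formal charge, aromaticity);
    each subsequent round composes an atom's key with the sorted keys of its
    bonded neighbours, so two atoms share a key iff their bonded
    neighbourhoods agree out to `radius` bonds.
    """
    keys = [
        f"{a.GetSymbol()}{a.GetFormalCharge():+d}{'ar' if a.GetIsAromatic() else ''}"
        for a in mol.GetAtoms()
    ]
    neighbors = [
        sorted(n.GetIdx() for n in atom.GetNeighbors()) for atom in mol.GetAtoms()
    ]
    for _ in range(radius):
        keys = [
            keys[i] + "(" + ",".join(sorted(keys[j] for j in neighbors[i])) + ")"
            for i in range(len(keys))
        ]
    return keys


@dataclass
class AtomEnvVocab:
    """Atom-environment key → contiguous integer id, with reserved UNK."""

    radius: int
    env_to_id: dict[str, int]

    @property
    def unk_id(self) -> int:
        return self.env_to_id[UNK_ENV]

    def __len__(self) -> int:
        return len(self.env_to_id)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"#radius={self.radius}\n")
            for key, idx in sorted(self.env_to_id.items(), key=lambda kv: kv[1]):
                handle.write(f"{key}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path) -> "AtomEnvVocab":
        env_to_id: dict[str, int] = {}
        radius = 0
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#radius="):
                    radius = int(line.split("=")[1])
                    continue
                key, idx = line.split("\t")
                env_to_id[key] = int(idx)
        return cls(radius=radius, env_to_id=env_to_id)


@dataclass
class MoleculeGraph:
    """Heavy-atom token ids plus binary bond adjacency."""

    atom_token_ids: np.ndarray
    adjacency: np.ndarray  # M x M, {0,1}, zero diagonal
    radius: int
    smiles_canonical: str

    @property
    def n_atoms(self) -> int:
        return len(self.atom_token_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_env_vocab(smiles_list: Iterable[str], radius: int = 2) -> AtomEnvVocab:
    """Vocabulary of every atom environment observed in `smiles_list`."""
    keys: set[str] = set()
    for smiles in smiles_list:
        keys.update(atom_environment_keys(_parse(smiles), radius))
    env_to_id = {key: i for i, key in enumerate(sorted(keys))}
    env_to_id[UNK_ENV] = len(env_to_id)
    return AtomEnvVocab(radius=radius, env_to_id=env_to_id)


def smiles_to_graph(smiles: str, vocab: AtomEnvVocab) -> MoleculeGraph:
    """Parse SMILES into a heavy-atom molecular graph.

    Hydrogens stay implicit; bond orders collapse to binary adjacency;
    environments absent from the vocabulary map to UNK.
    """
    mol = _parse(smiles)
    keys = atom_environment_keys(mol, vocab.radius)
    token_ids = np.array(
        [vocab.env_to_id.get(k, vocab.unk_id) for k in keys], dtype=np.intp
    )
    adjacency = np.asarray(Chem.GetAdjacencyMatrix(mol), dtype=np.int8)
    return MoleculeGraph(
        atom_token_ids=token_ids,
        adjacency=adjacency,
        radius=vocab.radius,
        smiles_canonical=Chem.MolToSmiles(mol),
    )


def heavy_atom_count(smiles: str) -> int:
    """Number of heavy (non-hydrogen) atoms in a SMILES string."""
    return _parse(smiles).GetNumAtoms()
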
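"""Protein structures as Cα traces and their contact-map graphs.

A protein 3D-structure enters the model only through the positions of its
alpha-carbons: two residues are connected in the contact map when their
Cα–Cα Euclidean distance is strictly below a threshold (default 10 Å). The
contact map stores no self-loops; the GCN adds them during normalisation
(Ã = A + I), keeping the geometric object and the model convention apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, StructureParseError

__all__ = [
    "ProteinStructure",
    "ContactMap",
    "parse_structure",
    "build_contact_map",
    "write_structure",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}


@dataclass
class ProteinStructure:
    """Per-residue Cα coordinates plus the one-letter sequence."""

    residue_ids: list[int]
    sequence: str
    ca_coords: np.ndarray  # N x 3, Å
    chain_id: str = "A"
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise StructureParseError(
                f"ca_coords must be N x 3, got shape {self.ca_coords.shape}"
            )
        n = len(self.sequence)
        if self.ca_coords.shape[0] != n or len(self.residue_ids) != n:
            raise StructureParseError(
                "sequence, residue_ids and ca_coords must have equal length "
                f"(got {n}, {len(self.residue_ids)}, {self.ca_coords.shape[0]})"
            )
        if not np.all(np.isfinite(self.ca_coords)):
            raise StructureParseError("non-finite Cα coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """Symmetric binary residue–residue adjacency at a distance threshold."""

    adjacency: np.ndarray  # N x N, {0,1}
    threshold: float
    self_loops_included: bool = False

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_contacts(self) -> int:
        off_diag = self.adjacency.sum() - np.trace(self.adjacency)
        return int(off_diag) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int]]:
        """Contacts as 1-based (i, j) pairs with i < j."""
        i_idx, j_idx = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i) + 1, int(j) + 1) for i, j in zip(i_idx, j_idx)]

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for i, j in self.edge_list():
                handle.write(f"{i}\t{j}\n")

    def write_dense(self, path: str | Path) -> None:
        np.savetxt(path, self.adjacency, fmt="%d", delimiter="\t")


def parse_structure(path: str | Path, chain: str | None = None) -> ProteinStructure:
    """Read a PDB or mmCIF file into a Cα trace.

    The first model is used; within it, `chain` selects a chain by name and
    otherwise the first chain containing a Cα atom is taken. Residues are
    ordered by author residue number; residues without a Cα atom are dropped
    with a warning. Per-residue B-factors of the Cα atoms are exposed as
    `plddt`, the usual carrier for predicted-structure confidence.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in {path}")
    model = st[0]

    if chain is not None:
        if model.find_chain(chain) is None:
            raise StructureParseError(f"chain {chain!r} not found in {path}")
        candidate_chains = [model[chain]]
    else:
        candidate_chains = list(model)

    for ch in candidate_chains:
        residues = sorted(ch, key=lambda r: (r.seqid.num, r.seqid.icode))
        ids, letters, coords, bfac, dropped = [], [], [], [], []
        for res in residues:
            ca = res.find_atom("CA", "*")
            if ca is None:
                dropped.append(res.seqid.num)
                continue
            ids.append(res.seqid.num)
            letters.append(THREE_TO_ONE.get(res.name.upper(), "X"))
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            bfac.append(ca.b_iso)
        if not coords:
            continue
        if dropped:
            warnings.warn(
                f"{path.name} chain {ch.name}: dropped {len(dropped)} residue(s) "
                f"without a Cα atom (residue numbers {dropped})",
                stacklevel=2,
            )
        return ProteinStructure(
            residue_ids=ids,
            sequence="".join(letters),
            ca_coords=np.array(coords, dtype=float),
            chain_id=ch.name,
            plddt=np.array(bfac, dtype=float),
        )

    if chain is not None:
        raise EmptyStructureError(f"chain {chain!r} in {path} has no Cα atoms")
    raise EmptyStructureError(f"no protein chain with Cα atoms in {path}")


def build_contact_map(structure: ProteinStructure, threshold: float = 10.0) -> ContactMap:
    """Binary contact map: edge iff Cα–Cα distance strictly below `threshold` Å.

    The inequality is strict (a pair at exactly the threshold has no edge),
    the matrix is symmetric, and the diagonal is zero.
    """
    if threshold <= 0:
        raise StructureParseError(f"threshold must be positive, got {threshold}")
    coords = structure.ca_coords
    deltas = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((deltas**2).sum(axis=-1))
    adjacency = (distances < threshold).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return ContactMap(adjacency=adjacency, threshold=threshold)


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a Cα-only structure as PDB or mmCIF (by file extension)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    ch = gemmi.Chain(structure.chain_id or "A")
    plddt = structure.plddt if structure.plddt is not None else np.zeros(len(structure))
    for rid, letter, xyz, b in zip(
        structure.residue_ids, structure.sequence, structure.ca_coords, plddt
    ):
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(letter, "UNK")
        res.seqid = gemmi.SeqId(int(rid), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        atom.b_iso = float(b)
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
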